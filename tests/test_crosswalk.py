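import numpy as np
import pandas as pd
import pytest

from nitroscape.crosswalk import (
    CrosswalkTable,
    build_crosswalk,
    economic_to_pft,
    economic_to_predicts,
)
from nitroscape.grid import generate_grid
from nitroscape.intensity import IntensityShareModel, PastureShareModel
from nitroscape.landuse import EconomicLandUseMap
from nitroscape.scenarios import ScenarioConfig, generate_scenario_pair


@pytest.fixture(scope="module")
def tiny_grid():
    return generate_grid((50.0, 52.0, 0.0, 2.0), 1.0)


def _uniform_map(grid, fractions):
    arrays = {
        cat: np.full(grid.shape, frac) for cat, frac in fractions.items()
    }
    return EconomicLandUseMap.from_arrays(arrays, grid)


class TestBuildCrosswalk:
    @pytest.mark.parametrize(
        "alias, source", [("aropaj", "aropaj"), ("abandonment", "aropaj"),
                          ("nlu", "nlu"), ("extensification", "nlu")]
    )
    def test_source_aliases(self, alias, source):
        assert build_crosswalk(alias).source == source

    def test_category_examples(self):
        table = build_crosswalk("aropaj")
        assert table.predicts["Maize"] == [("annual", 1.0, "yield")]
        assert table.pft["Maize"] == [("c4_summer_crop", 1.0)]
        assert table.predicts["Fallow"] == [("annual", 1.0, "minimal")]
        assert table.pft["Fallow"] == [("c3_natural_grass", 1.0)]
        assert table.predicts["Forest"] == [
            ("primary", 0.5, "none"),
            ("secondary", 0.5, "none"),
        ]
        nlu = build_crosswalk("nlu")
        assert nlu.predicts["Other"] == [
            ("annual", 0.8, "yield"),
            ("perennial", 0.2, "yield"),
        ]
        assert nlu.predicts["Pasture"] == [
            ("pasture", 0.8, "pasture"),
            ("rangeland", 0.2, "none"),
        ]
        assert dict(nlu.pft["Pasture"]) == {
            "c3_natural_grass": 0.9,
            "c4_natural_grass": 0.1,
        }

    def test_primary_split_override(self):
        table = build_crosswalk("aropaj", primary_split=0.4)
        assert dict(
            (t, f) for t, f, _ in table.predicts["Forest"]
        ) == {"primary": 0.4, "secondary": 0.6}

    def test_invalid_primary_split(self):
        with pytest.raises(ValueError):
            build_crosswalk("aropaj", primary_split=1.5)

    def test_split_fractions_must_close(self):
        with pytest.raises(ValueError, match="sum"):
            CrosswalkTable(
                source="custom",
                predicts={"Forest": [("primary", 0.5, "none"),
                                     ("secondary", 0.4, "none")]},
                pft={"Forest": [("forest", 1.0)]},
            )

    def test_unknown_rule_and_pft_rejected(self):
        with pytest.raises(ValueError, match="rule"):
            CrosswalkTable(
                source="custom",
                predicts={"X": [("annual", 1.0, "quadratic")]},
                pft={"X": [("forest", 1.0)]},
            )
        with pytest.raises(ValueError, match="PFT"):
            CrosswalkTable(
                source="custom",
                predicts={"X": [("annual", 1.0, "yield")]},
                pft={"X": [("kudzu", 1.0)]},
            )

    def test_roundtrip_through_dataframe(self):
        table = build_crosswalk("nlu")
        again = build_crosswalk(table.to_dataframe())
        assert again.predicts == table.predicts
        assert again.pft == table.pft


class TestEconomicToPredicts:
    def test_forest_split_with_override(self, tiny_grid):
        table = build_crosswalk("aropaj", primary_split=0.4)
        lu = _uniform_map(tiny_grid, {"Forest": 0.5, "Urban": 0.5})
        layer = economic_to_predicts(lu, table, IntensityShareModel())
        np.testing.assert_allclose(layer.fraction("primary"), 0.2)
        np.testing.assert_allclose(layer.fraction("secondary"), 0.3)
        np.testing.assert_allclose(layer.fraction("urban"), 0.5)

    def test_fallow_is_minimal_intensity_annual(self, tiny_grid):
        table = build_crosswalk("aropaj")
        lu = _uniform_map(tiny_grid, {"Fallow": 1.0})
        layer = economic_to_predicts(lu, table, IntensityShareModel())
        np.testing.assert_allclose(layer.fraction("annual_minimal"), 1.0)
        np.testing.assert_allclose(layer.fraction("annual_light"), 0.0)

    def test_crop_split_matches_share_model(self, tiny_grid):
        table = build_crosswalk("aropaj")
        lu = _uniform_map(tiny_grid, {"Maize": 1.0})
        y = np.full(tiny_grid.shape, 4.5)
        model = IntensityShareModel()
        layer = economic_to_predicts(lu, table, model, yield_map=y)
        minimal, light, intense = model.shares(4.5)
        np.testing.assert_allclose(layer.fraction("annual_minimal"), minimal)
        np.testing.assert_allclose(layer.fraction("annual_light"), light)
        np.testing.assert_allclose(layer.fraction("annual_intense"), intense)

    def test_pasture_split_matches_stocking_model(self, tiny_grid):
        table = build_crosswalk("nlu")
        lu = _uniform_map(tiny_grid, {"Pasture": 1.0})
        model = PastureShareModel()
        layer = economic_to_predicts(
            lu, table, IntensityShareModel(), pasture_model=model,
            ruminant_density=1.0,
        )
        # 0.8 of pasture split 50/50 at the cutpoint; 0.2 goes to rangeland
        np.testing.assert_allclose(layer.fraction("pasture_light"), 0.4)
        np.testing.assert_allclose(layer.fraction("pasture_intense"), 0.4)
        np.testing.assert_allclose(layer.fraction("rangeland"), 0.2)

    def test_crops_without_yield_map_rejected(self, tiny_grid):
        table = build_crosswalk("aropaj")
        lu = _uniform_map(tiny_grid, {"Maize": 1.0})
        with pytest.raises(ValueError, match="yield_map"):
            economic_to_predicts(lu, table, IntensityShareModel())

    def test_unknown_category_rejected(self, tiny_grid):
        table = build_crosswalk("aropaj")
        lu = _uniform_map(tiny_grid, {"Moon base": 1.0})
        with pytest.raises(KeyError, match="Moon base"):
            economic_to_predicts(lu, table, IntensityShareModel())


class TestMassConservation:
    @pytest.mark.parametrize("archetype", ["abandonment", "extensification"])
    def test_total_area_preserved_through_both_crosswalks(
        self, small_grid, archetype
    ):
        config = ScenarioConfig(archetype=archetype, seed=11)
        lu, _ = generate_scenario_pair(small_grid, config)
        table = build_crosswalk(archetype)
        y = np.full(small_grid.shape, 4.0)
        pred = economic_to_predicts(lu, table, IntensityShareModel(), y)
        pft = economic_to_pft(lu, table)
        pred.validate()
        pft.validate()
        total = lu.total_area_ha()
        assert pred.total_area_ha() == pytest.approx(total, rel=1e-12)
        assert pft.total_area_ha() == pytest.approx(total, rel=1e-12)

    def test_per_category_area_conserved(self, tiny_grid):
        table = build_crosswalk("nlu")
        lu = _uniform_map(
            tiny_grid, {"Wheat": 0.3, "Pasture": 0.4, "Forest": 0.2, "Other": 0.1}
        )
        y = np.full(tiny_grid.shape, 5.0)
        pred = economic_to_predicts(lu, table, IntensityShareModel(), y)
        area = tiny_grid.cell_area_2d()
        # pasture's biodiversity targets carry exactly pasture's area
        pasture_targets = (
            pred.fraction("pasture_light")
            + pred.fraction("pasture_intense")
            + pred.fraction("rangeland")
        )
        np.testing.assert_allclose(
            (pasture_targets * area).sum(), (lu.fraction("Pasture") * area).sum()
        )

    def test_empty_map_passes_through(self, tiny_grid):
        table = build_crosswalk("aropaj")
        lu = EconomicLandUseMap.from_arrays({}, tiny_grid)
        pft = economic_to_pft(lu, table)
        assert pft.categories == []
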