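import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from nitroscape.biodiversity import (
    SIMILARITY_ADJUSTMENT,
    BiodiversityCoefficients,
    coarsen_class,
    compute_bii,
    default_coefficients,
    fit_coefficients,
    project_biodiversity,
    project_compositional_similarity,
    project_relative_abundance,
    project_relative_sr,
    similarity_to_data_scale,
    simulate_sites,
)
from nitroscape.grid import generate_grid
from nitroscape.landuse import PredictsLandUseLayer


@pytest.fixture(scope="module")
def tiny_grid():
    return generate_grid((50.0, 52.0, 0.0, 2.0), 1.0)


def _layer(grid, fractions):
    return PredictsLandUseLayer.from_arrays(
        {cls: np.full(grid.shape, f) for cls, f in fractions.items()}, grid
    )


def _coeffs(**rows):
    """Coefficient table from model-scale values; primary is the reference."""
    base = {
        "primary": {"sr_coef": 0.0, "abundance_coef": 1.0,
                    "similarity_coef": logit(0.5 * 0.98 + 0.01)},
    }
    base.update(rows)
    return BiodiversityCoefficients(pd.DataFrame.from_dict(base, orient="index"))


class TestTransforms:
    def test_similarity_logit_zero_is_half(self):
        assert similarity_to_data_scale(0.0) == pytest.approx(0.5)

    def test_similarity_adjustment_roundtrip(self):
        s = np.array([0.0, 0.25, 0.95, 1.0])
        x = logit(s * (1 - 2 * SIMILARITY_ADJUSTMENT) + SIMILARITY_ADJUSTMENT)
        np.testing.assert_allclose(similarity_to_data_scale(x), s, atol=1e-12)

    def test_coarsening_keeps_only_perennial_intensity(self):
        assert coarsen_class("perennial_light") == "perennial_light"
        assert coarsen_class("annual_intense") == "annual"
        assert coarsen_class("nfixing_minimal") == "nfixing"
        assert coarsen_class("pasture_light") == "pasture"
        assert coarsen_class("primary") == "primary"


class TestProjection:
    def test_all_primary_scores_100_everywhere(self, tiny_grid, coefficients):
        layer = _layer(tiny_grid, {"primary": 1.0})
        maps = project_biodiversity(layer, coefficients)
        for m in (maps.sr, maps.abundance, maps.similarity, maps.bii):
            np.testing.assert_allclose(m, 100.0)

    def test_sr_log_scale_example(self, tiny_grid):
        coeffs = _coeffs(
            cropland={"sr_coef": -0.5, "abundance_coef": 1.0,
                      "similarity_coef": logit(0.5 * 0.98 + 0.01)}
        )
        layer = _layer(tiny_grid, {"cropland": 1.0})
        np.testing.assert_allclose(
            project_relative_sr(layer, coeffs), 100 * np.exp(-0.5)
        )

    def test_sr_mixed_cell_is_fraction_weighted(self, tiny_grid):
        coeffs = _coeffs(
            cropland={"sr_coef": -0.5, "abundance_coef": 1.0,
                      "similarity_coef": logit(0.5 * 0.98 + 0.01)}
        )
        layer = _layer(tiny_grid, {"primary": 0.5, "cropland": 0.5})
        expected = 100 * (0.5 + 0.5 * np.exp(-0.5))  # ≈ 80.33
        np.testing.assert_allclose(project_relative_sr(layer, coeffs), expected)
        assert expected == pytest.approx(80.326533, abs=1e-5)

    def test_abundance_sqrt_scale_example(self, tiny_grid):
        coeffs = _coeffs(
            cropland={"sr_coef": 0.0, "abundance_coef": 0.8,
                      "similarity_coef": logit(0.5 * 0.98 + 0.01)}
        )
        layer = _layer(tiny_grid, {"cropland": 1.0})
        np.testing.assert_allclose(
            project_relative_abundance(layer, coeffs), 64.0
        )

    def test_similarity_relative_to_primary(self, tiny_grid):
        coeffs = _coeffs(
            cropland={"sr_coef": 0.0, "abundance_coef": 1.0,
                      "similarity_coef": 0.0}  # data scale 0.5, same as primary
        )
        layer = _layer(tiny_grid, {"cropland": 1.0})
        np.testing.assert_allclose(
            project_compositional_similarity(layer, coeffs), 100.0
        )

    def test_bii_product_example(self):
        ab = np.array([[80.0]])
        sim = np.array([[75.0]])
        np.testing.assert_allclose(compute_bii(ab, sim), 60.0)

    def test_bii_shape_mismatch(self):
        with pytest.raises(ValueError):
            compute_bii(np.zeros((2, 2)), np.zeros((3, 2)))

    def test_projection_is_affine_in_fractions(self, tiny_grid, coefficients, rng):
        """Weighting pure-class projections reproduces the mixed projection."""
        classes = ["primary", "annual_intense", "pasture_light", "urban"]
        w = rng.dirichlet(np.ones(len(classes)), size=tiny_grid.shape)
        layer = PredictsLandUseLayer.from_arrays(
            {cls: w[..., k] for k, cls in enumerate(classes)}, tiny_grid
        )
        maps = project_biodiversity(layer, coefficients)
        expected = np.zeros(tiny_grid.shape)
        for k, cls in enumerate(classes):
            pure = _layer(tiny_grid, {cls: 1.0})
            expected += w[..., k] * project_relative_sr(pure, coefficients)
        np.testing.assert_allclose(maps.sr, expected, atol=1e-9)

    def test_pasture_to_cropland_lowers_sr(self, tiny_grid, coefficients):
        """Default coefficients: converting pasture to intense cropland
        reduces projected species richness."""
        before = _layer(tiny_grid, {"pasture_light": 1.0})
        after = _layer(tiny_grid, {"annual_intense": 1.0})
        sr_before = project_relative_sr(before, coefficients)
        sr_after = project_relative_sr(after, coefficients)
        assert np.all(sr_after < sr_before)

    def test_missing_coefficient_raises(self, tiny_grid):
        coeffs = _coeffs()
        layer = _layer(tiny_grid, {"rangeland": 1.0})
        with pytest.raises(KeyError, match="rangeland"):
            project_relative_sr(layer, coeffs)


class TestCoefficients:
    def test_primary_required(self):
        with pytest.raises(ValueError, match="primary"):
            BiodiversityCoefficients(
                pd.DataFrame.from_dict(
                    {"secondary": {"sr_coef": 0, "abundance_coef": 1,
                                   "similarity_coef": 0}},
                    orient="index",
                )
            )

    def test_csv_roundtrip(self, tmp_path, coefficients):
        path = tmp_path / "coeffs.csv"
        coefficients.to_csv(path)
        again = BiodiversityCoefficients.from_csv(path)
        for cls in ("primary", "annual_intense", "pasture_light"):
            assert again.relative_sr(cls) == pytest.approx(
                coefficients.relative_sr(cls)
            )
            assert again.relative_similarity(cls) == pytest.approx(
                coefficients.relative_similarity(cls)
            )

    def test_default_orderings(self, coefficients):
        # natural classes richer than cropland; urban lowest
        assert coefficients.relative_sr("primary") == pytest.approx(1.0)
        assert (
            coefficients.relative_sr("secondary")
            > coefficients.relative_sr("annual_light")
            > coefficients.relative_sr("urban")
        )
        # similarity shared within coarsened classes
        assert coefficients.relative_similarity(
            "annual_minimal"
        ) == coefficients.relative_similarity("annual_intense")
        assert coefficients.relative_similarity(
            "perennial_minimal"
        ) != coefficients.relative_similarity("perennial_intense")


class TestFitRecovery:
    def test_fitted_coefficients_recover_truth(self, coefficients):
        sites = simulate_sites(coefficients, n_per_class=400, seed=42)
        fitted = fit_coefficients(sites)
        for cls in ("secondary", "annual_intense", "pasture_light", "urban"):
            assert fitted.relative_sr(cls) == pytest.approx(
                coefficients.relative_sr(cls), rel=0.05
            )
            assert fitted.relative_abundance(cls) == pytest.approx(
                coefficients.relative_abundance(cls), rel=0.05
            )
            assert fitted.relative_similarity(cls) == pytest.approx(
                coefficients.relative_similarity(cls), rel=0.15
            )
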