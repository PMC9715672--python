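"""End-to-end orchestration: generate → crosswalk → project → difference →
breakdown → quadrants.

The chain is strictly one-way: each stage consumes the previous stage's
outputs and never mutates them. A single integer seed makes the whole run
reproducible; all tables carry the seed and configuration in their
provenance metadata when written to disk.

Land-use groups for the per-land-use breakdown:

* cropland — crop PFTs / annual, perennial and N-fixing biodiversity classes;
* grassland — natural-grass PFTs / pasture and rangeland classes;
* forest — the forest PFT / primary and secondary vegetation classes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .accounting import (
    RegionMask,
    SignificanceMask,
    aggregate,
    make_region_mask,
    scenario_difference,
    significance_mask,
)
from .biodiversity import (
    BiodiversityCoefficients,
    BiodiversityMaps,
    default_coefficients,
    project_biodiversity,
)
from .crosswalk import build_crosswalk, economic_to_pft, economic_to_predicts
from .fields import CarbonFields, generate_carbon_fields, scenario_time_series
from .grid import DEFAULT_DOMAIN, GridDefinition, generate_grid
from .intensity import IntensityShareModel, PastureShareModel
from .landuse import EconomicLandUseMap, PftLayer, PredictsLandUseLayer
from .lmdi import breakdown_by_landuse
from .quadrants import QuadrantSummary, classify_quadrants, quadrant_report
from .scenarios import ScenarioConfig, generate_scenario_pair, yield_map

PFT_GROUPS = {
    "cropland": ("c3_winter_crop", "c3_summer_crop", "c4_summer_crop"),
    "grassland": ("c3_natural_grass", "c4_natural_grass"),
    "forest": ("forest",),
}

PREDICTS_GROUPS = {
    "cropland": tuple(
        f"{g}_{i}"
        for g in ("annual", "perennial", "nfixing")
        for i in ("minimal", "light", "intense")
    ),
    "grassland": ("pasture_light", "pasture_intense", "rangeland"),
    "forest": ("primary", "secondary"),
}

#: Stocking density (head ha⁻¹) in the Baseline and its proportional drop
#: under a full halving: lower livestock production extensifies pasture.
BASE_STOCKING_DENSITY = 1.0
STOCKING_DROP = 0.1


@dataclass
class PipelineConfig:
    """Configuration of one full run (both scenario archetypes)."""

    domain: tuple[float, float, float, float] = DEFAULT_DOMAIN
    resolution: float = 0.5
    seed: int = 0
    n_years: int = 150
    last_years: int = 50
    alpha: float = 0.05
    quadrant_tolerance: float = 0.0
    n_lat_blocks: int = 3
    n_lon_blocks: int = 4
    scenario_overrides: dict = field(default_factory=dict)
    coefficient_file: str | None = None
    crosswalk_file: str | None = None
    output_dir: str | None = None

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as f:
            raw = json.load(f) if path.suffix == ".json" else yaml.safe_load(f)
        cfg = cls(**{k: v for k, v in raw.items()})
        if isinstance(cfg.domain, list):
            cfg.domain = tuple(cfg.domain)
        for key in ("coefficient_file", "crosswalk_file"):
            value = getattr(cfg, key)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"{key} does not exist: {value}")
        return cfg

    def scenario_config(self, archetype: str) -> ScenarioConfig:
        return ScenarioConfig(
            archetype=archetype, seed=self.seed, **self.scenario_overrides
        )


@dataclass
class FamilyResult:
    """Everything the pipeline computes for one scenario archetype."""

    archetype: str
    grid: GridDefinition
    landuse_baseline: EconomicLandUseMap
    landuse_policy: EconomicLandUseMap
    predicts_baseline: PredictsLandUseLayer
    predicts_policy: PredictsLandUseLayer
    pft_baseline: PftLayer
    pft_policy: PftLayer
    bio_baseline: BiodiversityMaps
    bio_policy: BiodiversityMaps
    carbon_baseline: CarbonFields
    carbon_policy: CarbonFields
    delta_maps: dict[str, np.ndarray]  # per-cell Δ: soil_c, npp, biomass_c, sr, bii
    regional_totals: pd.DataFrame  # region × indicator differences
    breakdown: dict[str, pd.DataFrame]  # indicator -> LMDI table
    quadrants: dict[str, QuadrantSummary]
    significance: dict[str, SignificanceMask]
    regions: RegionMask


def _pft_group_levels(
    fields: CarbonFields, pft_layer: PftLayer, indicator: str, grid: GridDefinition
) -> dict[str, tuple[float, float]]:
    """(level in MtC, area in Mha) per land-use group for a carbon indicator."""
    area = grid.cell_area_2d()
    out = {}
    for group, pfts in PFT_GROUPS.items():
        level = 0.0
        group_area = 0.0
        for pft in pfts:
            f = pft_layer.fraction(pft)
            level += float((f * fields.density(indicator, pft) * area).sum()) * 1e-6
            group_area += float((f * area).sum()) * 1e-6  # ha → Mha
        out[group] = (level, group_area)
    return out


def _sr_group_levels(
    layer: PredictsLandUseLayer,
    coefficients: BiodiversityCoefficients,
    grid: GridDefinition,
) -> dict[str, tuple[float, float]]:
    """(richness-weighted area, area) in Mha per group for species richness.

    The level is Σ cells area·f_class·relative_SR_class: an 'intact-
    equivalent' area, so the per-land-use changes sum to the overall
    area-weighted SR change exactly (the projection is linear in fractions).
    """
    area = grid.cell_area_2d()
    out = {}
    for group, classes in PREDICTS_GROUPS.items():
        level = 0.0
        group_area = 0.0
        for cls in classes:
            f = layer.fraction(cls)
            level += float(
                (f * coefficients.relative_sr(cls) * area).sum()
            ) * 1e-6
            group_area += float((f * area).sum()) * 1e-6
        out[group] = (level, group_area)
    return out


def _levels_frame(
    baseline: dict[str, tuple[float, float]],
    policy: dict[str, tuple[float, float]],
) -> pd.DataFrame:
    rows = {
        group: {
            "E_baseline": baseline[group][0],
            "E_policy": policy[group][0],
            "A_baseline": baseline[group][1],
            "A_policy": policy[group][1],
        }
        for group in baseline
    }
    return pd.DataFrame.from_dict(rows, orient="index")


def run_family(
    archetype: str,
    config: PipelineConfig,
    coefficients: BiodiversityCoefficients | None = None,
    share_model: IntensityShareModel | None = None,
    pasture_model: PastureShareModel | None = None,
) -> FamilyResult:
    """Run the full chain for one scenario archetype."""
    grid = generate_grid(config.domain, config.resolution)
    scen = config.scenario_config(archetype)
    coefficients = coefficients or (
        BiodiversityCoefficients.from_csv(config.coefficient_file)
        if config.coefficient_file
        else default_coefficients()
    )
    share_model = share_model or IntensityShareModel()
    pasture_model = pasture_model or PastureShareModel()
    table = build_crosswalk(config.crosswalk_file or archetype)

    # land-use maps and crosswalked layers
    lu_b, lu_p = generate_scenario_pair(grid, scen)
    y_b = yield_map(grid, scen, scen.n_baseline)
    y_p = yield_map(grid, scen, scen.n_policy)
    dens_b = BASE_STOCKING_DENSITY
    dens_p = BASE_STOCKING_DENSITY * (1 - STOCKING_DROP * scen.policy_strength)
    pred_b = economic_to_predicts(lu_b, table, share_model, y_b, pasture_model, dens_b)
    pred_p = economic_to_predicts(lu_p, table, share_model, y_p, pasture_model, dens_p)
    pft_b = economic_to_pft(lu_b, table)
    pft_p = economic_to_pft(lu_p, table)

    # biodiversity projection
    bio_b = project_biodiversity(pred_b, coefficients, label="Baseline")
    bio_p = project_biodiversity(pred_p, coefficients, label="Halving-N")

    # carbon fields and equilibrium differences
    cf_b = generate_carbon_fields(grid, scen, scen.n_baseline, label="Baseline")
    cf_p = generate_carbon_fields(grid, scen, scen.n_policy, label="Halving-N")
    delta_eq = scenario_difference(cf_p, cf_b, pft_p, pft_b)

    # transient series for soil carbon and NPP; the reported Δ maps are the
    # means over the last `last_years` annual differences
    rng = np.random.default_rng([scen.seed, 29])
    delta_maps: dict[str, np.ndarray] = {"biomass_c": delta_eq["biomass_c"]}
    significance: dict[str, SignificanceMask] = {}
    for indicator, tau in (("soil_c", scen.soil_tau), ("npp", scen.npp_tau)):
        total_b = cf_b.cell_total(indicator, pft_b)
        total_p_eq = cf_p.cell_total(indicator, pft_p)
        series_b, series_p = scenario_time_series(
            total_b, total_p_eq, tau, config.n_years, rng
        )
        diffs = (series_p - series_b)[-config.last_years :]
        delta_maps[indicator] = diffs.mean(axis=0)
        significance[indicator] = significance_mask(diffs, config.alpha)
    delta_maps["sr"] = bio_p.sr - bio_b.sr
    delta_maps["bii"] = bio_p.bii - bio_b.bii

    # regional totals (Table-3 layout: carbon in MtC, biodiversity in %)
    regions = make_region_mask(grid, config.n_lat_blocks, config.n_lon_blocks)
    table3 = {}
    for indicator in ("npp", "soil_c", "biomass_c"):
        table3[f"delta_{indicator}_MtC"] = aggregate(
            delta_maps[indicator], grid, regions
        )
    area = grid.cell_area_2d()
    for indicator in ("bii", "sr"):
        weighted = {}
        for k, name in enumerate(regions.names):
            m = regions.labels == k
            weighted[name] = float(
                (delta_maps[indicator][m] * area[m]).sum() / area[m].sum()
            )
        weighted["EU"] = float((delta_maps[indicator] * area).sum() / area.sum())
        table3[f"delta_{indicator}_pct"] = pd.Series(weighted)
    regional_totals = pd.DataFrame(table3)

    # LMDI breakdown by land use for soil carbon, NPP and species richness
    breakdown: dict[str, pd.DataFrame] = {}
    for indicator in ("soil_c", "npp"):
        frame = _levels_frame(
            _pft_group_levels(cf_b, pft_b, indicator, grid),
            _pft_group_levels(cf_p, pft_p, indicator, grid),
        )
        breakdown[indicator] = breakdown_by_landuse(frame, indicator)
    frame = _levels_frame(
        _sr_group_levels(pred_b, coefficients, grid),
        _sr_group_levels(pred_p, coefficients, grid),
    )
    breakdown["sr"] = breakdown_by_landuse(frame, "sr")

    # quadrant classification: soil carbon against each biodiversity index
    quadrants = {
        "soil_c_vs_sr": classify_quadrants(
            delta_maps["soil_c"], delta_maps["sr"], config.quadrant_tolerance
        ),
        "soil_c_vs_bii": classify_quadrants(
            delta_maps["soil_c"], delta_maps["bii"], config.quadrant_tolerance
        ),
    }

    return FamilyResult(
        archetype=archetype,
        grid=grid,
        landuse_baseline=lu_b,
        landuse_policy=lu_p,
        predicts_baseline=pred_b,
        predicts_policy=pred_p,
        pft_baseline=pft_b,
        pft_policy=pft_p,
        bio_baseline=bio_b,
        bio_policy=bio_p,
        carbon_baseline=cf_b,
        carbon_policy=cf_p,
        delta_maps=delta_maps,
        regional_totals=regional_totals,
        breakdown=breakdown,
        quadrants=quadrants,
        significance=significance,
        regions=regions,
    )


def run_pipeline(config: PipelineConfig) -> dict[str, FamilyResult]:
    """Run both scenario archetypes; write outputs if an output dir is set."""
    results = {
        archetype: run_family(archetype, config)
        for archetype in ("abandonment", "extensification")
    }
    if config.output_dir:
        write_outputs(results, config)
    return results


def _provenance(config: PipelineConfig) -> str:
    return json.dumps({"seed": config.seed, "resolution": config.resolution})


def write_outputs(results: dict[str, FamilyResult], config: PipelineConfig) -> None:
    """Dump per-family CSV tables and NetCDF maps under the output directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = _provenance(config)
    qsummaries = {}
    for archetype, res in results.items():
        d = out / archetype
        d.mkdir(exist_ok=True)
        with open(d / "regional_totals.csv", "w") as f:
            f.write(f"# provenance: {prov}\n")
            res.regional_totals.to_csv(f, index_label="region")
        for indicator, frame in res.breakdown.items():
            with open(d / f"breakdown_{indicator}.csv", "w") as f:
                f.write(f"# provenance: {prov}\n")
                frame.to_csv(f)
        res.bio_baseline.to_netcdf(d / "biodiversity_baseline.nc")
        res.bio_policy.to_netcdf(d / "biodiversity_policy.nc")
        res.landuse_baseline.to_netcdf(d / "landuse_baseline.nc")
        res.landuse_policy.to_netcdf(d / "landuse_policy.nc")
        for pair, summary in res.quadrants.items():
            qsummaries[(archetype, pair)] = summary
    with open(out / "quadrants.csv", "w") as f:
        f.write(f"# provenance: {prov}\n")
        quadrant_report(qsummaries).to_csv(f, index=False)


def load_reference_levels() -> pd.DataFrame:
    """EU-scale annual-mean indicator levels shipped with the package.

    Domain-wide Baseline / Halving-N levels (BII and SR in %, NPP in
    MtC yr⁻¹, soil and biomass carbon in MtC) for the two scenario
    families, as reported for the full-scale coupled model chain; used as
    inputs to :func:`tables_from_levels`.
    """
    from importlib import resources

    with resources.files("nitroscape.data").joinpath("eu_annual_means.csv").open() as f:
        return pd.read_csv(f)


def tables_from_levels(levels: pd.DataFrame) -> pd.DataFrame:
    """Policy − baseline differences from a per-scenario level table.

    `levels` must carry ``baseline`` and ``halving_n`` columns (any index,
    typically indicator or (family, indicator)). Returns the table with a
    ``difference`` column appended; equal levels give exactly zero.
    """
    for col in ("baseline", "halving_n"):
        if col not in levels.columns:
            raise KeyError(f"levels table lacks the {col!r} column")
    out = levels.copy()
    out["difference"] = out["halving_n"] - out["baseline"]
    return out
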