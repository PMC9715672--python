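"""Scenario differencing, regional aggregation and significance testing.

All comparisons are policy-minus-baseline (Halving-N − Baseline). Cell
densities (tC ha⁻¹, weighted across PFTs) are converted to regional totals
in MtC (or MtC yr⁻¹ for NPP) by multiplying by the spherical cell area; a
set of region masks partitions the domain so that country totals sum
exactly to the domain total.

Statistical significance of a per-cell difference uses a one-sample t-test
on the annual differences with the standard error corrected for temporal
serial correlation through the effective sample size
n_eff = n·(1 − r₁)/(1 + r₁), where r₁ is the lag-1 autocorrelation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fields import INDICATORS, CarbonFields
from .grid import GridDefinition
from .landuse import PftLayer


def scenario_difference(
    fields_policy: CarbonFields,
    fields_baseline: CarbonFields,
    pft_policy: PftLayer,
    pft_baseline: PftLayer,
) -> dict[str, np.ndarray]:
    """Per-cell policy − baseline difference of PFT-weighted totals.

    Returns one Δ map (same units as the densities) per indicator.
    """
    if fields_policy.grid.shape != fields_baseline.grid.shape:
        raise ValueError("scenario fields are on different grids")
    if fields_policy.pfts != fields_baseline.pfts:
        raise ValueError("scenario fields have different PFT sets")
    return {
        ind: fields_policy.cell_total(ind, pft_policy)
        - fields_baseline.cell_total(ind, pft_baseline)
        for ind in INDICATORS
    }


@dataclass
class RegionMask:
    """Integer region labels on the grid plus region names.

    Label −1 marks cells outside every region; labels 0..n−1 index `names`.
    """

    labels: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        if self.labels.max() >= len(self.names):
            raise ValueError("label exceeds the number of region names")


def make_region_mask(
    grid: GridDefinition, n_lat_blocks: int = 3, n_lon_blocks: int = 4
) -> RegionMask:
    """Partition the domain into rectangular blocks standing in for countries.

    Purely synthetic: a deterministic ``n_lat_blocks × n_lon_blocks``
    checkerboard covering every cell, so regional totals always sum to the
    domain total.
    """
    nlat, nlon = grid.shape
    ilat = np.minimum(np.arange(nlat) * n_lat_blocks // nlat, n_lat_blocks - 1)
    ilon = np.minimum(np.arange(nlon) * n_lon_blocks // nlon, n_lon_blocks - 1)
    labels = ilat[:, None] * n_lon_blocks + ilon[None, :]
    names = [f"R{k:02d}" for k in range(n_lat_blocks * n_lon_blocks)]
    return RegionMask(labels=labels, names=names)


def aggregate(
    density_map: np.ndarray,
    grid: GridDefinition,
    regions: RegionMask | None = None,
    domain_name: str = "EU",
) -> pd.Series:
    """Convert a per-cell density map (tC ha⁻¹) to regional totals (MtC).

    total = Σ density · cell_area(ha) · 10⁻⁶. Returns a Series indexed by
    region name with a whole-domain row appended under `domain_name`.
    """
    if density_map.shape != grid.shape:
        raise ValueError("density map does not match the grid")
    contrib = density_map * grid.cell_area_2d() * 1e-6
    out = {}
    if regions is not None:
        if regions.labels.shape != grid.shape:
            raise ValueError("region mask does not match the grid")
        for k, name in enumerate(regions.names):
            out[name] = float(contrib[regions.labels == k].sum())
    out[domain_name] = float(contrib.sum())
    return pd.Series(out)


def lag1_autocorrelation(series: np.ndarray) -> np.ndarray:
    """Lag-1 autocorrelation along the first axis (biased, mean-removed)."""
    x = series - series.mean(axis=0)
    denom = (x**2).sum(axis=0)
    num = (x[1:] * x[:-1]).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r1 = np.where(denom > 0, num / denom, 0.0)
    return r1


@dataclass
class SignificanceMask:
    """Per-cell test outcome for the annual-difference series."""

    significant: np.ndarray
    p_value: np.ndarray
    r1: np.ndarray
    n_years: int
    alpha: float


def significance_mask(
    annual_differences: np.ndarray, alpha: float = 0.05
) -> SignificanceMask:
    """Serial-correlation-corrected one-sample t-test per cell.

    `annual_differences` has shape (n_years, ...). The classical t statistic
    is formed from the series mean and standard deviation, but the standard
    error and degrees of freedom use n_eff = n·(1 − r₁)/(1 + r₁). The raw
    lag-1 autocorrelation estimate is biased low in short series, which
    would leave the test anticonservative, so Kendall's first-order bias
    correction r₁ + (1 + 3r₁)/n is applied to positive estimates before
    clipping to [0, 0.99]; non-positive estimates are clipped to 0 (no
    anti-correction), so with r₁ ≤ 0 this is exactly the classical
    one-sample t-test.
    """
    d = np.asarray(annual_differences, dtype=float)
    n = d.shape[0]
    if n < 3:
        raise ValueError("need at least 3 annual differences per cell")
    mean = d.mean(axis=0)
    var = d.var(axis=0, ddof=1)
    r1_raw = lag1_autocorrelation(d)
    r1 = np.where(r1_raw > 0, r1_raw + (1 + 3 * r1_raw) / n, 0.0)
    r1 = np.clip(r1, 0.0, 0.99)
    # the sample variance of a positively autocorrelated series is also
    # biased low; undo the first-order bias before forming the t statistic
    var = var / np.clip(1 - 2 * r1 / ((1 - r1) * (n - 1)), 0.1, 1.0)
    sd = np.sqrt(var)
    n_eff = n * (1 - r1) / (1 + r1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = mean / (sd / np.sqrt(n_eff))
    df = np.maximum(n_eff - 1, 1.0)
    p = 2 * stats.t.sf(np.abs(tstat), df)
    # zero-variance, nonzero-mean series are significant at any level
    p = np.where((sd == 0) & (mean != 0), 0.0, p)
    p = np.where((sd == 0) & (mean == 0), 1.0, p)
    return SignificanceMask(
        significant=p < alpha, p_value=p, r1=r1, n_years=n, alpha=alpha
    )
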