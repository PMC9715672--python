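"""Synthetic per-PFT ecosystem carbon fields and their dynamics.

Emulates the outputs of a process-based land-surface model at the level the
analysis needs: per-cell, per-PFT densities of NPP (tC ha⁻¹ yr⁻¹), soil
carbon and biomass carbon (tC ha⁻¹), drawn from configured PFT means with
spatially autocorrelated noise, plus a first-order relaxation of cell
totals toward a new equilibrium after land-use change.

The spatial noise field is shared between scenarios (it represents site
quality, not policy): scenario differences enter only through PFT fractions
and through the nitrogen dependence of the crop means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr

from .crosswalk import PFT_CLASSES
from .grid import GridDefinition
from .landuse import PftLayer
from .random_fields import gaussian_random_field
from .scenarios import ScenarioConfig, nitrogen_yield_response

INDICATORS = ("npp", "soil_c", "biomass_c")

CROP_PFTS = ("c3_winter_crop", "c3_summer_crop", "c4_summer_crop")

#: Default equilibrium mean densities per PFT. Grassland and forest soils
#: hold more carbon than cropland soils; bare soil holds little of anything.
#: NPP in tC ha⁻¹ yr⁻¹, soil and biomass carbon in tC ha⁻¹. Crop means are
#: the values at the baseline N rate and scale with the relative yield.
DEFAULT_CARBON_MEANS: dict[str, dict[str, float]] = {
    "npp": {
        "c3_winter_crop": 5.2,
        "c3_summer_crop": 5.2,
        "c4_summer_crop": 5.8,
        "c3_natural_grass": 7.0,
        "c4_natural_grass": 7.0,
        "forest": 6.5,
        "bare_soil": 0.5,
    },
    "soil_c": {
        "c3_winter_crop": 80.0,
        "c3_summer_crop": 80.0,
        "c4_summer_crop": 80.0,
        "c3_natural_grass": 120.0,
        "c4_natural_grass": 120.0,
        "forest": 150.0,
        "bare_soil": 30.0,
    },
    "biomass_c": {
        "c3_winter_crop": 4.5,
        "c3_summer_crop": 4.5,
        "c4_summer_crop": 5.0,
        "c3_natural_grass": 10.0,
        "c4_natural_grass": 10.0,
        "forest": 120.0,
        "bare_soil": 1.0,
    },
}

#: Share of a crop PFT's mean density that scales with relative yield; the
#: remainder is yield-independent. The nitrogen effect on ecosystem carbon
#: is deliberately weak per unit area (fertilization raises photosynthetic
#: capacity but realized NPP and soil stocks are co-limited by climate and
#: soil), so land-conversion effects dominate the scenario differences.
N_SENSITIVITY = {"npp": 0.15, "soil_c": 0.15, "biomass_c": 0.3}


@dataclass
class CarbonFields:
    """Per-cell, per-PFT carbon densities for one scenario.

    `densities` has dims (pft, lat, lon) and variables ``npp``, ``soil_c``,
    ``biomass_c``.
    """

    densities: xr.Dataset
    grid: GridDefinition
    label: str = ""

    @property
    def pfts(self) -> list[str]:
        return [str(p) for p in self.densities["pft"].values]

    def density(self, indicator: str, pft: str) -> np.ndarray:
        return self.densities[indicator].sel(pft=pft).values

    def cell_total(self, indicator: str, pft_layer: PftLayer) -> np.ndarray:
        """PFT-fraction-weighted cell total density, Σᵢ fᵢ·densityᵢ."""
        if pft_layer.grid.shape != self.grid.shape:
            raise ValueError("PFT layer and carbon fields are on different grids")
        out = np.zeros(self.grid.shape)
        for pft in self.pfts:
            out += pft_layer.fraction(pft) * self.density(indicator, pft)
        return out

    def to_netcdf(self, path) -> None:
        ds = self.densities.copy()
        ds.attrs["label"] = self.label
        ds.to_netcdf(path, engine="scipy")


def generate_carbon_fields(
    grid: GridDefinition,
    config: ScenarioConfig,
    n_rate: float | None = None,
    means: dict[str, dict[str, float]] | None = None,
    noise_amplitude: float = 0.15,
    label: str = "",
) -> CarbonFields:
    """Draw equilibrium carbon-density fields for a scenario's N rate.

    Each PFT's density is ``mean · (1 + amplitude · G)`` with G a unit
    Gaussian random field (correlation length from `config`), floored at 5%
    of the mean so densities stay positive. Crop-PFT means are scaled by
    the Michaelis–Menten relative yield at `n_rate` (default: the baseline
    rate), damped by the indicator's nitrogen sensitivity.
    """
    means = DEFAULT_CARBON_MEANS if means is None else means
    for indicator, by_pft in means.items():
        for pft, m in by_pft.items():
            if m < 0:
                raise ValueError(f"negative mean density for {indicator}/{pft}")
    n_rate = config.n_baseline if n_rate is None else n_rate
    rel_yield = nitrogen_yield_response(n_rate, config.yield_params) / (
        nitrogen_yield_response(config.n_baseline, config.yield_params)
    )

    rng = np.random.default_rng([config.seed, 13])
    data = {}
    for indicator in INDICATORS:
        stack = np.empty((len(PFT_CLASSES),) + grid.shape)
        for k, pft in enumerate(PFT_CLASSES):
            mean = means[indicator][pft]
            if pft in CROP_PFTS:
                sens = N_SENSITIVITY[indicator]
                mean = mean * ((1 - sens) + sens * rel_yield)
            g = gaussian_random_field(grid.shape, rng, config.correlation_length)
            stack[k] = np.maximum(mean * (1 + noise_amplitude * g), 0.05 * mean)
        data[indicator] = (("pft", "lat", "lon"), stack)
    ds = xr.Dataset(
        data,
        coords={"pft": list(PFT_CLASSES), "lat": grid.lats, "lon": grid.lons},
    )
    return CarbonFields(ds, grid, label=label)


def soil_carbon_relaxation(c_initial, c_equilibrium, tau: float, t_years):
    """First-order relaxation toward a new equilibrium.

    c(t) = c_eq + (c₀ − c_eq)·exp(−t/τ): monotone, reaching the new
    equilibrium asymptotically with e-folding time τ (years).
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    t = np.asarray(t_years, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_years must be non-negative")
    c0 = np.asarray(c_initial, dtype=float)
    ceq = np.asarray(c_equilibrium, dtype=float)
    out = ceq + (c0 - ceq) * np.exp(-t / tau)
    if out.ndim == 0:
        return float(out)
    return out


def scenario_time_series(
    total_baseline: np.ndarray,
    total_policy_eq: np.ndarray,
    tau: float,
    n_years: int,
    rng: np.random.Generator,
    interannual_sd_frac: float = 0.01,
    ar1: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Annual per-cell series for the Baseline and policy scenarios.

    The Baseline sits at its equilibrium; the policy run starts from the
    Baseline state and relaxes toward its own equilibrium with e-folding
    time `tau`. Both carry AR(1) interannual variability (lag-1 correlation
    `ar1`, marginal sd `interannual_sd_frac` of the local Baseline level).
    Returns arrays of shape (n_years, *grid_shape).
    """
    if n_years < 1:
        raise ValueError("n_years must be at least 1")
    t = np.arange(1, n_years + 1, dtype=float)
    mean_b = np.broadcast_to(total_baseline, total_baseline.shape)
    mean_p = soil_carbon_relaxation(
        total_baseline[None, ...], total_policy_eq[None, ...], tau, t[:, None, None]
    )
    sd = interannual_sd_frac * np.abs(total_baseline)

    def _ar1_noise() -> np.ndarray:
        innov_sd = np.sqrt(1 - ar1**2)
        z = np.empty((n_years,) + total_baseline.shape)
        z[0] = rng.standard_normal(total_baseline.shape)
        for k in range(1, n_years):
            z[k] = ar1 * z[k - 1] + innov_sd * rng.standard_normal(
                total_baseline.shape
            )
        return z * sd

    series_b = mean_b[None, ...] + _ar1_noise()
    series_p = mean_p + _ar1_noise()
    return series_b, series_p
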