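"""Synthetic land-use scenario generator.

The policy experiment compares a business-as-usual map (*Baseline*) with a
map under a mineral-nitrogen reduction policy (*Halving-N*, default a 50%
cut). Two scenario archetypes bracket the plausible economic responses:

``abandonment``
    The policy raises input costs enough that part of the cropland drops out
    of cultivation: crop fractions shrink in favour of fallow and pasture.

``extensification``
    Production is maintained by cultivating more land at lower yield:
    pasture is converted to cropland while per-hectare yields fall.

Yields respond to the nitrogen rate through a Michaelis–Menten saturation
curve, the standard concave production function for fertilizer response.

Everything is driven by a single integer seed; identical configuration and
seed reproduce bit-identical maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import GridDefinition
from .landuse import EconomicLandUseMap
from .random_fields import gaussian_random_field

ARCHETYPES = ("abandonment", "extensification")

# Economic-model category sets. The abandonment archetype uses a supply-side
# model nomenclature (with explicit fallow and rangeland); the extensification
# archetype uses a partial-equilibrium nomenclature without them.
ABANDONMENT_CROPS = (
    "Tender wheat",
    "Winter barley",
    "Maize",
    "Rapeseed",
    "Sunflower",
    "Other legumes",
    "Potato",
)
ABANDONMENT_CATEGORIES = ABANDONMENT_CROPS + (
    "Fallow",
    "Pasture",
    "Rangeland",
    "Forest",
    "Urban",
    "Other ecosystem",
)
EXTENSIFICATION_CROPS = ("Wheat", "Maize", "Rapeseed", "Sunflower", "Fieldpea", "Other")
EXTENSIFICATION_CATEGORIES = EXTENSIFICATION_CROPS + ("Pasture", "Forest", "Urban")

# Mean domain-wide shares for the Baseline maps (softmax location parameters
# are their logs). Crops together ~1/3 of land, forest the largest natural
# class — a mid-latitude agricultural mosaic.
_BASE_SHARES = {
    "abandonment": {
        "Tender wheat": 0.10,
        "Winter barley": 0.05,
        "Maize": 0.06,
        "Rapeseed": 0.04,
        "Sunflower": 0.03,
        "Other legumes": 0.03,
        "Potato": 0.02,
        "Fallow": 0.03,
        "Pasture": 0.15,
        "Rangeland": 0.04,
        "Forest": 0.35,
        "Urban": 0.03,
        "Other ecosystem": 0.07,
    },
    "extensification": {
        "Wheat": 0.11,
        "Maize": 0.06,
        "Rapeseed": 0.04,
        "Sunflower": 0.03,
        "Fieldpea": 0.03,
        "Other": 0.04,
        "Pasture": 0.20,
        "Forest": 0.44,
        "Urban": 0.05,
    },
}


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one synthetic scenario pair.

    Attributes
    ----------
    archetype : str
        ``"abandonment"`` or ``"extensification"``.
    n_baseline : float
        Baseline mineral-N application rate, kgN ha⁻¹ (default 150).
    n_policy_fraction : float
        Fraction of the baseline N rate retained under the policy
        (default 0.5, i.e. a halving; 1 means no policy).
    yield_params : tuple
        (y_min, y_max, k_half): asymptotes in tDM ha⁻¹ and half-saturation
        N rate in kgN ha⁻¹ of the Michaelis–Menten yield curve.
    abandon_fraction : float
        Share of each crop fraction abandoned per cell at a full halving
        (abandonment archetype).
    convert_fraction : float
        Share of pasture converted to cropland per cell at a full halving
        (extensification archetype).
    soil_tau : float
        e-folding time (years) of soil-carbon relaxation toward the new
        equilibrium after land-use change.
    npp_tau : float
        e-folding time (years) for NPP; vegetation responds within a few
        years, much faster than soil.
    correlation_length : float
        Spatial correlation length of all noise fields, in grid cells.
    landuse_noise : float
        Log-scale spatial spread of the Baseline category shares.
    yield_noise : float
        Relative spatial spread of the yield multiplier field.
    seed : int
        Master seed; all randomness derives from it.
    """

    archetype: str = "abandonment"
    n_baseline: float = 150.0
    n_policy_fraction: float = 0.5
    yield_params: tuple[float, float, float] = (2.0, 8.0, 100.0)
    abandon_fraction: float = 0.15
    convert_fraction: float = 0.10
    soil_tau: float = 40.0
    npp_tau: float = 2.0
    correlation_length: float = 3.0
    landuse_noise: float = 0.6
    yield_noise: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValueError(
                f"unknown archetype {self.archetype!r}; expected one of {ARCHETYPES}"
            )
        if not 0 < self.n_policy_fraction <= 1:
            raise ValueError("n_policy_fraction must be in (0, 1]")
        y_min, y_max, k_half = self.yield_params
        if not y_min < y_max:
            raise ValueError("yield_params must satisfy y_min < y_max")
        if k_half <= 0:
            raise ValueError("k_half must be positive")
        if self.soil_tau <= 0 or self.npp_tau <= 0:
            raise ValueError("relaxation times must be positive")

    @property
    def n_policy(self) -> float:
        """Policy-scenario N rate, kgN ha⁻¹."""
        return self.n_baseline * self.n_policy_fraction

    @property
    def policy_strength(self) -> float:
        """Land-use response scaled so a 50% cut gives the nominal magnitudes."""
        return (1.0 - self.n_policy_fraction) / 0.5

    @property
    def crop_categories(self) -> tuple[str, ...]:
        return (
            ABANDONMENT_CROPS
            if self.archetype == "abandonment"
            else EXTENSIFICATION_CROPS
        )

    @property
    def categories(self) -> tuple[str, ...]:
        return (
            ABANDONMENT_CATEGORIES
            if self.archetype == "abandonment"
            else EXTENSIFICATION_CATEGORIES
        )


def nitrogen_yield_response(
    n_rate, yield_params: tuple[float, float, float]
):
    """Michaelis–Menten yield response to the nitrogen rate.

    y(n) = y_min + (y_max − y_min) · n / (k_half + n): strictly increasing
    and concave, saturating at y_max, with y(0) = y_min and the midpoint at
    n = k_half.
    """
    n = np.asarray(n_rate, dtype=float)
    if np.any(n < 0):
        raise ValueError("n_rate must be non-negative")
    y_min, y_max, k_half = yield_params
    y = y_min + (y_max - y_min) * n / (k_half + n)
    return float(y) if np.isscalar(n_rate) else y


def generate_scenario_pair(
    grid: GridDefinition, config: ScenarioConfig
) -> tuple[EconomicLandUseMap, EconomicLandUseMap]:
    """Generate the (Baseline, Halving-N) land-use map pair.

    The Baseline map draws one spatially correlated share field per category
    (softmax of noisy log-shares, so each cell closes to 1 exactly). The
    policy map applies the archetype's deterministic reallocation on top, so
    the pair differs only through the policy.
    """
    rng = np.random.default_rng(config.seed)
    shares = _BASE_SHARES[config.archetype]
    cats = config.categories

    logits = np.stack(
        [
            np.log(shares[c])
            + config.landuse_noise
            * gaussian_random_field(grid.shape, rng, config.correlation_length)
            for c in cats
        ]
    )
    logits -= logits.max(axis=0, keepdims=True)
    expl = np.exp(logits)
    fracs = expl / expl.sum(axis=0, keepdims=True)
    baseline = {c: fracs[i].copy() for i, c in enumerate(cats)}

    policy = {c: v.copy() for c, v in baseline.items()}
    s = config.policy_strength
    if s > 0:
        if config.archetype == "abandonment":
            moved_total = np.zeros(grid.shape)
            for c in config.crop_categories:
                moved = s * config.abandon_fraction * policy[c]
                policy[c] -= moved
                moved_total += moved
            # Abandoned cropland reverts half to fallow, half to pasture.
            policy["Fallow"] += 0.5 * moved_total
            policy["Pasture"] += 0.5 * moved_total
        else:
            moved = s * config.convert_fraction * policy["Pasture"]
            policy["Pasture"] -= moved
            crop_sum = sum(policy[c] for c in config.crop_categories)
            n_crops = len(config.crop_categories)
            for c in config.crop_categories:
                with np.errstate(invalid="ignore", divide="ignore"):
                    weight = np.where(crop_sum > 0, policy[c] / crop_sum, 1.0 / n_crops)
                policy[c] += moved * weight

    base_map = EconomicLandUseMap.from_arrays(baseline, grid, label="Baseline")
    pol_map = EconomicLandUseMap.from_arrays(policy, grid, label="Halving-N")
    return base_map, pol_map


def yield_multiplier(grid: GridDefinition, config: ScenarioConfig) -> np.ndarray:
    """Scenario-independent spatial yield multiplier (site quality).

    Drawn from a sub-seed of the master seed so it is shared by the Baseline
    and policy yield maps: only the N rate differs between scenarios.
    """
    rng = np.random.default_rng([config.seed, 7])
    g = gaussian_random_field(grid.shape, rng, config.correlation_length)
    return np.clip(1.0 + config.yield_noise * g, 0.2, None)


def yield_map(
    grid: GridDefinition, config: ScenarioConfig, n_rate: float
) -> np.ndarray:
    """Per-cell crop yield (tDM ha⁻¹) at the given N rate."""
    base = nitrogen_yield_response(n_rate, config.yield_params)
    return base * yield_multiplier(grid, config)
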