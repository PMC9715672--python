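"""Logarithmic-mean (LMDI) decomposition of indicator differences.

For each land use *i*, the difference in an environmental indicator between
the policy and baseline scenarios is split exactly into an **area effect**
and an **intensity effect** using the logarithmic mean
L(a, b) = (a − b)/(ln a − ln b):

    ΔE_i       = E_i^p − E_i^b
    ΔE_i^area  = L(E_i^p, E_i^b) · ln(A_i^p / A_i^b)
    ΔE_i^int   = L(E_i^p, E_i^b) · ln(e_i^p / e_i^b),   e = E / A

Because E = A·e, the two effects add up to ΔE with no residual — the
defining property of the LMDI decomposition. Levels E and areas A must be
positive; the decomposition operates on levels, never on differences.

The intactness index (BII) cannot be decomposed this way: it is itself the
product of two indicators, so an area/intensity split of the product is not
defined. Requesting it raises :class:`BiiNotDecomposableError`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

LEVEL_FLOOR = 1e-9


class BiiNotDecomposableError(ValueError):
    """BII is a product of two indicators and has no area/intensity split."""


def log_mean(a: float, b: float) -> float:
    """Logarithmic mean L(a, b) = (a − b)/(ln a − ln b), with L(a, a) = a.

    Defined for positive arguments; symmetric; lies between min(a, b) and
    max(a, b).
    """
    if a <= 0 or b <= 0:
        raise ValueError(f"log_mean requires positive arguments, got ({a}, {b})")
    if a == b:
        return float(a)
    return (a - b) / (np.log(a) - np.log(b))


@dataclass(frozen=True)
class IndicatorState:
    """Levels and areas of one land use in the two scenarios.

    E_baseline / E_policy are indicator levels (e.g. MtC); A_baseline /
    A_policy are land-use areas (e.g. Mha). Intensities e = E/A are derived.
    """

    land_use: str
    E_baseline: float
    E_policy: float
    A_baseline: float
    A_policy: float

    def __post_init__(self) -> None:
        for name in ("E_baseline", "E_policy", "A_baseline", "A_policy"):
            if getattr(self, name) <= 0:
                raise ValueError(
                    f"{self.land_use}: {name} must be positive after preprocessing"
                )

    @property
    def e_baseline(self) -> float:
        return self.E_baseline / self.A_baseline

    @property
    def e_policy(self) -> float:
        return self.E_policy / self.A_policy


def floor_level(value: float, floor: float = LEVEL_FLOOR) -> float:
    """Raise a non-positive or vanishing level/area to a small positive floor."""
    if value < floor:
        warnings.warn(
            f"level {value!r} below floor {floor}; raised to the floor "
            "before taking logarithms",
            stacklevel=2,
        )
        return floor
    return value


def lmdi_breakdown(state: IndicatorState) -> dict[str, float]:
    """Decompose one land-use's ΔE into area and intensity effects.

    Returns a dict with keys ``dE``, ``dE_area``, ``dE_intensity``;
    ``dE_area + dE_intensity == dE`` exactly (to rounding).
    """
    L = log_mean(state.E_policy, state.E_baseline)
    d_area = L * np.log(state.A_policy / state.A_baseline)
    d_int = L * np.log(state.e_policy / state.e_baseline)
    return {
        "dE": state.E_policy - state.E_baseline,
        "dE_area": float(d_area),
        "dE_intensity": float(d_int),
    }


def breakdown_by_landuse(
    levels: pd.DataFrame,
    indicator: str = "",
    floor: float = LEVEL_FLOOR,
) -> pd.DataFrame:
    """LMDI breakdown for every land use in a levels table.

    Parameters
    ----------
    levels : DataFrame
        Indexed by land use, with columns ``E_baseline``, ``E_policy``,
        ``A_baseline``, ``A_policy``. Levels below `floor` are raised to it
        (with a warning) so the logarithms stay defined. A land use with
        zero area in exactly one scenario is assigned the whole ΔE as area
        effect (the limit of the formula) and flagged.
    indicator : str
        Name recorded in the output; ``"bii"`` raises
        :class:`BiiNotDecomposableError`.

    Returns
    -------
    DataFrame with columns E_baseline, E_policy, A_baseline, A_policy, dE,
    dE_area, dE_intensity, degenerate.
    """
    if indicator.lower() == "bii":
        raise BiiNotDecomposableError(
            "BII is the product of abundance and similarity; its change has "
            "no area/intensity decomposition"
        )
    required = {"E_baseline", "E_policy", "A_baseline", "A_policy"}
    missing = required - set(levels.columns)
    if missing:
        raise ValueError(f"levels table lacks columns {sorted(missing)}")

    rows = []
    for land_use, row in levels.iterrows():
        Ab, Ap = row["A_baseline"], row["A_policy"]
        Eb, Ep = row["E_baseline"], row["E_policy"]
        degenerate = (Ab <= floor) != (Ap <= floor)
        if degenerate:
            # land use present in only one scenario: all change is area effect
            rec = {
                "dE": Ep - Eb,
                "dE_area": Ep - Eb,
                "dE_intensity": 0.0,
            }
        else:
            state = IndicatorState(
                land_use=str(land_use),
                E_baseline=floor_level(Eb, floor),
                E_policy=floor_level(Ep, floor),
                A_baseline=floor_level(Ab, floor),
                A_policy=floor_level(Ap, floor),
            )
            rec = lmdi_breakdown(state)
        rows.append(
            {
                "land_use": str(land_use),
                "E_baseline": Eb,
                "E_policy": Ep,
                "A_baseline": Ab,
                "A_policy": Ap,
                **rec,
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows).set_index("land_use")
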