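"""Win/Loss quadrant classification of joint carbon–biodiversity change.

Each grid cell is placed by the signs of its carbon change (ΔC, y-axis) and
biodiversity change (Δbio, x-axis):

* quadrant I  (W–W): ΔC > 0 and Δbio > 0 — win–win;
* quadrant II (L–W): ΔC < 0 and Δbio > 0;
* quadrant III (L–L): both negative — loss–loss;
* quadrant IV (W–L): ΔC > 0 and Δbio < 0;

cells with |Δ| ≤ tolerance on either axis count as "no change". Percentages
are of all grid points and partition to 100 exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

QUADRANTS = ("I_win_win", "II_loss_win", "III_loss_loss", "IV_win_loss")


@dataclass(frozen=True)
class QuadrantSummary:
    """Percent of grid points per quadrant plus the no-change residual."""

    percentages: dict[str, float]
    n_cells: int

    def __post_init__(self) -> None:
        total = sum(self.percentages.values())
        if self.n_cells and abs(total - 100.0) > 1e-6:
            raise ValueError(f"quadrant percentages sum to {total}, not 100")

    @property
    def modal(self) -> str:
        """The most populated quadrant (ties broken by quadrant order)."""
        keys = QUADRANTS + ("no_change",)
        return max(keys, key=lambda k: self.percentages[k])


def classify_quadrants(
    delta_carbon: np.ndarray,
    delta_bio: np.ndarray,
    tolerance: float = 0.0,
) -> QuadrantSummary:
    """Count grid points per sign quadrant of (Δbio, ΔC).

    The denominator is every grid point of the two (equal-shaped) maps;
    cells within `tolerance` of zero on either axis go to "no change".
    """
    dc = np.asarray(delta_carbon, dtype=float)
    db = np.asarray(delta_bio, dtype=float)
    if dc.shape != db.shape:
        raise ValueError("Δcarbon and Δbiodiversity maps have different shapes")
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    n = dc.size
    if n == 0:
        return QuadrantSummary(
            {**{q: 0.0 for q in QUADRANTS}, "no_change": 0.0}, n_cells=0
        )
    no_change = (np.abs(dc) <= tolerance) | (np.abs(db) <= tolerance)
    counts = {
        "I_win_win": int(np.sum(~no_change & (dc > 0) & (db > 0))),
        "II_loss_win": int(np.sum(~no_change & (dc < 0) & (db > 0))),
        "III_loss_loss": int(np.sum(~no_change & (dc < 0) & (db < 0))),
        "IV_win_loss": int(np.sum(~no_change & (dc > 0) & (db < 0))),
        "no_change": int(np.sum(no_change)),
    }
    return QuadrantSummary(
        {k: 100.0 * v / n for k, v in counts.items()}, n_cells=n
    )


def quadrant_report(
    summaries: dict[tuple[str, str], QuadrantSummary]
) -> pd.DataFrame:
    """Tidy table of quadrant percentages.

    `summaries` maps (scenario_family, indicator_pair) — e.g.
    ("abandonment", "soil_c_vs_sr") — to a :class:`QuadrantSummary`.
    """
    rows = []
    for (family, pair), summary in summaries.items():
        rows.append(
            {
                "scenario_family": family,
                "indicator_pair": pair,
                **summary.percentages,
                "n_cells": summary.n_cells,
            }
        )
    columns = [
        "scenario_family",
        "indicator_pair",
        *QUADRANTS,
        "no_change",
        "n_cells",
    ]
    return pd.DataFrame(rows, columns=columns)
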