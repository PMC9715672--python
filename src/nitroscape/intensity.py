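"""Management-intensity share models.

Cropland is split across {minimal, light, intense} management as a monotone
function of yield; pasture across {light, intense} as a monotone function of
ruminant stocking density. Both use ordered-logistic share functions: with
cutpoints c₁ < c₂ and slope b > 0,

    minimal(y)          = invlogit(c₁ − b·y)
    minimal+light(y)    = invlogit(c₂ − b·y)
    intense(y)          = 1 − invlogit(c₂ − b·y)

so the minimal share falls and the intense share rises monotonically with
yield, shares always sum to 1, and the limits y→0 / y→∞ give all-minimal /
all-intense.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit


@dataclass(frozen=True)
class IntensityShareModel:
    """Three-class (minimal, light, intense) crop-intensity shares vs yield.

    Defaults place the minimal→light transition near 3 tDM ha⁻¹ and the
    light→intense transition near 6 tDM ha⁻¹, spanning the yield range of
    the synthetic Michaelis–Menten response.
    """

    cutpoints: tuple[float, float] = (3.0, 6.0)
    slope: float = 1.0

    def __post_init__(self) -> None:
        c1, c2 = self.cutpoints
        if not c1 < c2:
            raise ValueError("cutpoints must be increasing")
        if self.slope <= 0:
            raise ValueError("slope must be positive")

    def shares(self, yield_value):
        """Return (minimal, light, intense) shares; accepts scalars or arrays."""
        y = np.asarray(yield_value, dtype=float)
        if np.any(y < 0):
            raise ValueError("yield must be non-negative")
        c1, c2 = self.cutpoints
        p1 = expit(c1 - self.slope * y)
        p2 = expit(c2 - self.slope * y)
        return p1, p2 - p1, 1.0 - p2


@dataclass(frozen=True)
class PastureShareModel:
    """Two-class (light, intense) pasture shares vs ruminant stocking density.

    Same ordered-logistic family with a single cutpoint; the intense share
    rises with stocking density (default cutpoint 1 head ha⁻¹).
    """

    cutpoint: float = 1.0
    slope: float = 2.0

    def shares(self, density):
        """Return (light, intense) shares; accepts scalars or arrays."""
        d = np.asarray(density, dtype=float)
        if np.any(d < 0):
            raise ValueError("stocking density must be non-negative")
        intense = expit(self.slope * (d - self.cutpoint))
        return 1.0 - intense, intense
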