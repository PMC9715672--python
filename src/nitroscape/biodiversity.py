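"""Biodiversity projection from land-use × intensity fractions.

Four indicators are projected per grid cell, each expressed as a percentage
of its level in primary vegetation (the intact reference):

* **SR** — species richness, from a Poisson (log-link) model: the relative
  richness of class *i* is ``exp(sr_coef_i − sr_coef_primary)``;
* **abundance** — total abundance, modelled on the square-root scale: the
  relative abundance is ``(abundance_coef_i / abundance_coef_primary)²``;
* **similarity** — compositional similarity to the primary-vegetation
  community (asymmetric Jaccard), modelled on the logit scale with a 0.01
  adjustment: the data-scale value is ``(invlogit(x) − ε) / (1 − 2ε)``;
* **BII** — the intactness index, the product of the relative-abundance and
  relative-similarity maps.

A cell's value is the fraction-weighted mean of class-level relative values
(ratio to primary first, then weighting), so each indicator is affine in
the land-use fraction vector. Similarity coefficients are defined on
coarsened classes: management intensity is distinguished only for perennial
crops.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy.special import expit, logit

from .grid import GridDefinition
from .landuse import PredictsLandUseLayer

SIMILARITY_ADJUSTMENT = 0.01


def similarity_to_data_scale(x, eps: float = SIMILARITY_ADJUSTMENT):
    """Back-transform a logit-scale similarity coefficient to [0, 1].

    Inverse of the adjusted logit ``x = logit(s·(1 − 2ε) + ε)``: the
    symmetric compression convention maps data-scale 0 and 1 to finite
    logits. Clipped to [0, 1].
    """
    s = (expit(np.asarray(x, dtype=float)) - eps) / (1.0 - 2.0 * eps)
    return np.clip(s, 0.0, 1.0)


def coarsen_class(cls: str) -> str:
    """Similarity-model class coarsening: only perennial crops keep intensity."""
    if cls.startswith("perennial_"):
        return cls
    for prefix in ("annual", "nfixing", "pasture"):
        if cls.startswith(prefix + "_"):
            return prefix
    return cls


@dataclass
class BiodiversityCoefficients:
    """Per-class model coefficients, with primary vegetation as reference.

    `table` is indexed by class name with columns ``sr_coef`` (log scale),
    ``abundance_coef`` (square-root scale) and ``similarity_coef`` (logit
    scale, on coarsened class names).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if "primary" not in self.table.index:
            raise ValueError("coefficient table must include the primary class")
        if self.table.loc["primary", "abundance_coef"] <= 0:
            raise ValueError("primary abundance prediction must be positive")
        if similarity_to_data_scale(self.table.loc["primary", "similarity_coef"]) <= 0:
            raise ValueError("primary similarity must be positive on the data scale")

    def _lookup(self, cls: str, column: str) -> float:
        key = coarsen_class(cls) if column == "similarity_coef" else cls
        if key not in self.table.index:
            raise KeyError(f"no {column} for class {cls!r}")
        return float(self.table.loc[key, column])

    def relative_sr(self, cls: str) -> float:
        return float(
            np.exp(self._lookup(cls, "sr_coef") - self._lookup("primary", "sr_coef"))
        )

    def relative_abundance(self, cls: str) -> float:
        return (
            self._lookup(cls, "abundance_coef")
            / self._lookup("primary", "abundance_coef")
        ) ** 2

    def relative_similarity(self, cls: str) -> float:
        s = similarity_to_data_scale(self._lookup(cls, "similarity_coef"))
        s_ref = similarity_to_data_scale(self._lookup("primary", "similarity_coef"))
        return float(s / s_ref)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="class")

    @classmethod
    def from_csv(cls, path) -> "BiodiversityCoefficients":
        return cls(pd.read_csv(path, index_col="class"))


# Data-scale default levels relative to primary vegetation. SR ordering:
# natural classes richest and pasture a high-richness ecosystem; across crop
# intensities the profile is hump-shaped — minimal (fallow-like, near-bare)
# below light, intense below light — with urban lowest overall. Similarity:
# cropland communities resemble the primary baseline community more than
# pasture communities do.
_DEFAULT_LEVELS = {
    # class: (relative SR, relative abundance, similarity on the data scale)
    "primary": (1.00, 1.00, 0.95),
    "secondary": (0.97, 0.90, 0.85),
    "pasture_light": (0.96, 0.82, 0.45),
    "pasture_intense": (0.90, 0.75, 0.45),
    "rangeland": (0.92, 0.72, 0.55),
    "annual_minimal": (0.68, 0.64, 0.85),
    "annual_light": (0.82, 0.56, 0.85),
    "annual_intense": (0.74, 0.42, 0.85),
    "perennial_minimal": (0.85, 0.64, 0.70),
    "perennial_light": (0.78, 0.56, 0.65),
    "perennial_intense": (0.70, 0.49, 0.60),
    "nfixing_minimal": (0.70, 0.61, 0.80),
    "nfixing_light": (0.80, 0.53, 0.80),
    "nfixing_intense": (0.73, 0.46, 0.80),
    "urban": (0.45, 0.36, 0.40),
}


def default_coefficients() -> BiodiversityCoefficients:
    """Synthetic default coefficient set on the model scales.

    Built from data-scale levels obeying the qualitative ordering of field
    estimates (primary ≥ secondary ≥ pasture ≥ cropland for SR); similarity
    coefficients are shared within coarsened classes.
    """
    eps = SIMILARITY_ADJUSTMENT
    rows = {}
    for cls, (rel_sr, rel_ab, sim) in _DEFAULT_LEVELS.items():
        rows[cls] = {
            "sr_coef": np.log(rel_sr),  # primary gets 0
            "abundance_coef": np.sqrt(rel_ab),  # primary gets 1
            "similarity_coef": logit(sim * (1 - 2 * eps) + eps),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    # collapse similarity to coarsened keys (annual/nfixing/pasture rows)
    for cls in list(table.index):
        coarse = coarsen_class(cls)
        if coarse != cls and coarse not in table.index:
            table.loc[coarse] = table.loc[cls]
            table.loc[coarse, ["sr_coef", "abundance_coef"]] = np.nan
    return BiodiversityCoefficients(table)


@dataclass
class BiodiversityMaps:
    """Per-cell indicator maps, percentages of the primary-vegetation level."""

    sr: np.ndarray
    abundance: np.ndarray
    similarity: np.ndarray
    bii: np.ndarray
    grid: GridDefinition
    label: str = ""

    def to_dataset(self) -> xr.Dataset:
        coords = {"lat": self.grid.lats, "lon": self.grid.lons}
        return xr.Dataset(
            {
                "sr_pct": (("lat", "lon"), self.sr),
                "abundance_pct": (("lat", "lon"), self.abundance),
                "similarity_pct": (("lat", "lon"), self.similarity),
                "bii_pct": (("lat", "lon"), self.bii),
            },
            coords=coords,
            attrs={"label": self.label},
        )

    def to_netcdf(self, path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")


def _weighted_map(
    layer: PredictsLandUseLayer, relative: dict[str, float]
) -> np.ndarray:
    out = np.zeros(layer.grid.shape)
    for cls in layer.categories:
        out += layer.fraction(cls) * relative[cls]
    return 100.0 * out


def project_relative_sr(
    layer: PredictsLandUseLayer, coefficients: BiodiversityCoefficients
) -> np.ndarray:
    """Species richness as % of the primary-vegetation level, per cell."""
    rel = {cls: coefficients.relative_sr(cls) for cls in layer.categories}
    return _weighted_map(layer, rel)


def project_relative_abundance(
    layer: PredictsLandUseLayer, coefficients: BiodiversityCoefficients
) -> np.ndarray:
    """Total abundance as % of the primary-vegetation level, per cell."""
    rel = {cls: coefficients.relative_abundance(cls) for cls in layer.categories}
    return _weighted_map(layer, rel)


def project_compositional_similarity(
    layer: PredictsLandUseLayer, coefficients: BiodiversityCoefficients
) -> np.ndarray:
    """Compositional similarity as % of the primary-vegetation level."""
    rel = {cls: coefficients.relative_similarity(cls) for cls in layer.categories}
    return _weighted_map(layer, rel)


def compute_bii(abundance_pct: np.ndarray, similarity_pct: np.ndarray) -> np.ndarray:
    """Intactness index: product of the relative abundance and similarity maps."""
    if abundance_pct.shape != similarity_pct.shape:
        raise ValueError("abundance and similarity maps are on different grids")
    return abundance_pct * similarity_pct / 100.0


def project_biodiversity(
    layer: PredictsLandUseLayer,
    coefficients: BiodiversityCoefficients,
    label: str = "",
) -> BiodiversityMaps:
    """Project all four indicators for one land-use layer."""
    sr = project_relative_sr(layer, coefficients)
    ab = project_relative_abundance(layer, coefficients)
    sim = project_compositional_similarity(layer, coefficients)
    return BiodiversityMaps(
        sr=sr,
        abundance=ab,
        similarity=sim,
        bii=compute_bii(ab, sim),
        grid=layer.grid,
        label=label or layer.label,
    )


# ---------------------------------------------------------------------------
# Coefficient recovery from synthetic site-level data (fixed effects only)

def simulate_sites(
    coefficients: BiodiversityCoefficients,
    n_per_class: int = 200,
    mean_richness: float = 40.0,
    abundance_sd: float = 0.05,
    similarity_sd: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate site-level survey data under the projection model.

    Richness is Poisson with a log-linear class effect; abundance is normal
    on the square-root scale; similarity is normal on the adjusted-logit
    scale. One row per site with columns (class, richness, sqrt_abundance,
    logit_similarity).
    """
    rng = np.random.default_rng(seed)
    classes = [c for c in _DEFAULT_LEVELS if c in coefficients.table.index]
    rows = []
    for cls in classes:
        lam = mean_richness * coefficients.relative_sr(cls)
        richness = rng.poisson(lam, size=n_per_class)
        sqrt_ab = rng.normal(
            np.sqrt(coefficients.relative_abundance(cls)), abundance_sd, n_per_class
        )
        x_sim = rng.normal(
            float(coefficients.table.loc[coarsen_class(cls), "similarity_coef"]),
            similarity_sd,
            n_per_class,
        )
        for r, a, s in zip(richness, sqrt_ab, x_sim):
            rows.append((cls, int(r), float(a), float(s)))
    return pd.DataFrame(
        rows, columns=["class", "richness", "sqrt_abundance", "logit_similarity"]
    )


def fit_coefficients(sites: pd.DataFrame) -> BiodiversityCoefficients:
    """Estimate class coefficients from site-level data by maximum likelihood.

    Poisson GLM (log link) for richness, least squares on the square-root
    scale for abundance and on the adjusted-logit scale for similarity.
    Fixed effects only; grouping structure is out of scope for this helper.
    """
    import statsmodels.api as sm

    classes = sorted(sites["class"].unique())
    design = pd.get_dummies(sites["class"])[classes].to_numpy(dtype=float)

    pois = sm.GLM(
        sites["richness"].to_numpy(), design, family=sm.families.Poisson()
    ).fit()
    sr_raw = dict(zip(classes, pois.params))

    rows = {}
    grouped = sites.groupby("class")
    ab_means = grouped["sqrt_abundance"].mean()
    sim_means = grouped["logit_similarity"].mean()  # LS estimate per class
    ref_sr = sr_raw.get("primary", 0.0)
    for cls in classes:
        rows[cls] = {
            "sr_coef": sr_raw[cls] - ref_sr,
            "abundance_coef": float(ab_means[cls]),
            "similarity_coef": float(sim_means[cls]),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    for cls in classes:  # coarsened similarity rows for projection lookups
        coarse = coarsen_class(cls)
        if coarse not in table.index:
            table.loc[coarse] = table.loc[cls]
            table.loc[coarse, ["sr_coef", "abundance_coef"]] = np.nan
    # similarity columns must be averaged within coarsened groups
    for coarse in {coarsen_class(c) for c in classes}:
        members = [c for c in classes if coarsen_class(c) == coarse]
        table.loc[coarse, "similarity_coef"] = float(
            sim_means[members].mean()
        )
        for cls in members:
            table.loc[cls, "similarity_coef"] = table.loc[coarse, "similarity_coef"]
    return BiodiversityCoefficients(table)
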