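"""Land-use crosswalk between model nomenclatures.

Economic land-use maps name categories the way economic models do (crops by
name, pasture, forest, ...). The biodiversity projection wants
(land-use × intensity) classes; the carbon accounting wants plant functional
types (PFTs). The crosswalk table maps each economic category to one or
more targets in each nomenclature, with split fractions for ambiguous
categories (forest → primary/secondary, "Other" → annual/perennial, grass →
C3/C4) and an intensity rule for classes whose management split is decided
at projection time:

``yield``
    crop-intensity shares from the yield-driven share model;
``minimal``
    forced to minimal intensity (fallow: uncultivated land counted as a
    zero-input annual crop);
``pasture``
    light/intense split from the stocking-density share model;
``none``
    the target class has no intensity dimension.

Mass is conserved exactly: the summed area of a category's targets equals
the category's area in every cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import GridDefinition
from .intensity import IntensityShareModel, PastureShareModel
from .landuse import EconomicLandUseMap, PftLayer, PredictsLandUseLayer

PFT_CLASSES = (
    "c3_winter_crop",
    "c3_summer_crop",
    "c4_summer_crop",
    "c3_natural_grass",
    "c4_natural_grass",
    "forest",
    "bare_soil",
)

CROP_GROUPS = ("annual", "perennial", "nfixing")
INTENSITIES = ("minimal", "light", "intense")

PREDICTS_CLASSES = (
    ("primary",)
    + ("secondary",)
    + tuple(f"{g}_{i}" for g in CROP_GROUPS for i in INTENSITIES)
    + ("pasture_light", "pasture_intense", "rangeland", "urban")
)

_VALID_RULES = {"yield", "minimal", "pasture", "none"}


@dataclass
class CrosswalkTable:
    """Validated category → (biodiversity classes, PFTs) correspondence."""

    source: str
    predicts: dict[str, list[tuple[str, float, str]]]  # cat -> [(target, frac, rule)]
    pft: dict[str, list[tuple[str, float]]]  # cat -> [(pft, frac)]

    def __post_init__(self) -> None:
        for cat, targets in self.predicts.items():
            tot = sum(f for _, f, _ in targets)
            if abs(tot - 1.0) > 1e-9:
                raise ValueError(
                    f"{self.source}:{cat}: biodiversity split fractions sum to {tot}"
                )
            for tgt, _, rule in targets:
                if rule not in _VALID_RULES:
                    raise ValueError(f"{cat}: unknown intensity rule {rule!r}")
        for cat, targets in self.pft.items():
            tot = sum(f for _, f in targets)
            if abs(tot - 1.0) > 1e-9:
                raise ValueError(
                    f"{self.source}:{cat}: PFT split fractions sum to {tot}"
                )
            for pft, _ in targets:
                if pft not in PFT_CLASSES:
                    raise ValueError(f"{cat}: unknown PFT {pft!r}")
        if set(self.predicts) != set(self.pft):
            raise ValueError("category sets differ between the two target maps")

    @property
    def categories(self) -> set[str]:
        return set(self.predicts)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for cat, targets in self.predicts.items():
            for tgt, frac, rule in targets:
                rows.append((self.source, cat, "predicts", tgt, frac, rule))
        for cat, targets in self.pft.items():
            for tgt, frac in targets:
                rows.append((self.source, cat, "pft", tgt, frac, ""))
        return pd.DataFrame(
            rows, columns=["source", "category", "kind", "target", "fraction", "rule"]
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


_SOURCE_ALIASES = {
    "aropaj": "aropaj",
    "abandonment": "aropaj",
    "nlu": "nlu",
    "extensification": "nlu",
}


def _default_table() -> pd.DataFrame:
    with resources.files("nitroscape.data").joinpath("crosswalk_default.csv").open() as f:
        return pd.read_csv(f, keep_default_na=False)


def build_crosswalk(
    table_source="aropaj",
    *,
    primary_split: float | None = None,
) -> CrosswalkTable:
    """Build and validate a :class:`CrosswalkTable`.

    Parameters
    ----------
    table_source : str, path or DataFrame
        ``"aropaj"``/``"abandonment"`` or ``"nlu"``/``"extensification"``
        select the shipped default correspondence; a path or DataFrame
        supplies a custom table in the same long format
        (source, category, kind, target, fraction, rule).
    primary_split : float, optional
        Override the primary share of every primary/secondary split
        (default as shipped, 0.5).
    """
    if isinstance(table_source, pd.DataFrame):
        df, source = table_source.copy(), "custom"
    elif isinstance(table_source, (str, Path)) and str(table_source) in _SOURCE_ALIASES:
        source = _SOURCE_ALIASES[str(table_source)]
        df = _default_table()
        df = df[df["source"] == source].copy()
    else:
        df = pd.read_csv(table_source, keep_default_na=False)
        source = str(df["source"].iloc[0]) if len(df) else "custom"

    if primary_split is not None:
        if not 0 <= primary_split <= 1:
            raise ValueError("primary_split must be in [0, 1]")
        sel = df.get("split_group", pd.Series("", index=df.index)) == "primary_secondary"
        df.loc[sel & (df["target"] == "primary"), "fraction"] = primary_split
        df.loc[sel & (df["target"] == "secondary"), "fraction"] = 1 - primary_split

    predicts: dict[str, list] = {}
    pft: dict[str, list] = {}
    for _, row in df.iterrows():
        cat = row["category"]
        if row["kind"] == "predicts":
            predicts.setdefault(cat, []).append(
                (row["target"], float(row["fraction"]), row["rule"] or "none")
            )
        elif row["kind"] == "pft":
            pft.setdefault(cat, []).append((row["target"], float(row["fraction"])))
        else:
            raise ValueError(f"unknown target kind {row['kind']!r}")
    return CrosswalkTable(source=source, predicts=predicts, pft=pft)


def _check_coverage(landuse: EconomicLandUseMap, table: CrosswalkTable) -> None:
    unknown = set(landuse.categories) - table.categories
    if unknown:
        raise KeyError(f"categories missing from crosswalk: {sorted(unknown)}")


def economic_to_predicts(
    landuse: EconomicLandUseMap,
    table: CrosswalkTable,
    share_model: IntensityShareModel,
    yield_map: np.ndarray | None = None,
    pasture_model: PastureShareModel | None = None,
    ruminant_density: np.ndarray | float = 1.0,
) -> PredictsLandUseLayer:
    """Convert an economic land-use map to (land-use × intensity) fractions.

    Crop classes with the ``yield`` rule are split across intensities by
    `share_model` evaluated at `yield_map`; the ``minimal`` rule (fallow)
    forces minimal intensity; pasture is split light/intense by
    `pasture_model` at the given stocking density.
    """
    _check_coverage(landuse, table)
    grid = landuse.grid
    needs_yield = any(
        rule == "yield"
        for cat in landuse.categories
        for _, _, rule in table.predicts[cat]
        if np.any(landuse.fraction(cat) > 0)
    )
    if needs_yield and yield_map is None:
        raise ValueError("yield_map required: crop categories present")
    pasture_model = pasture_model or PastureShareModel()

    out = {cls: np.zeros(grid.shape) for cls in PREDICTS_CLASSES}
    if yield_map is not None:
        crop_shares = share_model.shares(yield_map)
    past_shares = pasture_model.shares(np.broadcast_to(ruminant_density, grid.shape))

    for cat in landuse.categories:
        frac = landuse.fraction(cat)
        for target, split, rule in table.predicts[cat]:
            contrib = frac * split
            if rule == "yield":
                for intensity, share in zip(INTENSITIES, crop_shares):
                    out[f"{target}_{intensity}"] += contrib * share
            elif rule == "minimal":
                out[f"{target}_minimal"] += contrib
            elif rule == "pasture":
                out["pasture_light"] += contrib * past_shares[0]
                out["pasture_intense"] += contrib * past_shares[1]
            else:
                out[target] += contrib
    layer = PredictsLandUseLayer.from_arrays(out, grid, label=landuse.label)
    return layer


def economic_to_pft(
    landuse: EconomicLandUseMap, table: CrosswalkTable
) -> PftLayer:
    """Convert an economic land-use map to PFT fractions."""
    _check_coverage(landuse, table)
    grid = landuse.grid
    if not landuse.categories:  # vacuous input: empty layer, not an error
        return PftLayer.from_arrays({}, grid, label=landuse.label)
    out = {pft: np.zeros(grid.shape) for pft in PFT_CLASSES}
    for cat in landuse.categories:
        frac = landuse.fraction(cat)
        for pft, split in table.pft[cat]:
            out[pft] += frac * split
    return PftLayer.from_arrays(out, grid, label=landuse.label)
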