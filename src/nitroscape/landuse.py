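"""Per-cell land-use fraction maps.

Three flavours of the same container appear in the pipeline:

* :class:`EconomicLandUseMap` — fractions over economic-model categories
  (crops, fallow, pasture, forest, ...), one map per scenario;
* :class:`PredictsLandUseLayer` — fractions over biodiversity-model
  (land-use × intensity) classes;
* :class:`PftLayer` — fractions over land-surface-model plant functional
  types.

Each holds an :class:`xarray.Dataset` with one variable per category on
(lat, lon) dimensions, and enforces the closure invariant: fractions lie in
[0, 1] and sum to 1 in every cell.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import xarray as xr

from .grid import GridDefinition

CLOSURE_TOL = 1e-9


class FractionMap:
    """A set of per-cell fractions over named categories on a grid."""

    def __init__(self, data: xr.Dataset, grid: GridDefinition, label: str = ""):
        self.data = data
        self.grid = grid
        self.label = label

    @property
    def categories(self) -> list[str]:
        return list(self.data.data_vars)

    def fraction(self, category: str) -> np.ndarray:
        if category not in self.data:
            raise KeyError(f"unknown category {category!r}")
        return self.data[category].values

    def validate(self, tol: float = CLOSURE_TOL) -> None:
        """Raise if any fraction leaves [0, 1] or any cell does not close to 1."""
        total = np.zeros(self.grid.shape)
        for cat in self.categories:
            f = self.fraction(cat)
            if np.any(f < -tol) or np.any(f > 1 + tol):
                raise ValueError(f"fractions for {cat!r} outside [0, 1]")
            total += f
        if self.categories and np.any(np.abs(total - 1.0) > tol):
            raise ValueError(
                f"cell fractions do not sum to 1 (max deviation "
                f"{np.abs(total - 1.0).max():.3e})"
            )

    def total_area_ha(self, categories: Iterable[str] | None = None) -> float:
        """Summed area (ha) of the given categories over the whole domain."""
        cats = self.categories if categories is None else list(categories)
        area = self.grid.cell_area_2d()
        return float(sum((self.fraction(c) * area).sum() for c in cats))

    def to_netcdf(self, path) -> None:
        ds = self.data.copy()
        ds.attrs["label"] = self.label
        ds.to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path, grid: GridDefinition) -> "FractionMap":
        with xr.open_dataset(path, engine="scipy") as ds:
            ds = ds.load()
        return cls(ds, grid, label=str(ds.attrs.get("label", "")))

    @classmethod
    def from_arrays(
        cls,
        fractions: dict[str, np.ndarray],
        grid: GridDefinition,
        label: str = "",
    ) -> "FractionMap":
        data = xr.Dataset(
            {
                name: (("lat", "lon"), np.asarray(arr, dtype=float))
                for name, arr in fractions.items()
            },
            coords={"lat": grid.lats, "lon": grid.lons},
        )
        obj = cls(data, grid, label=label)
        obj.validate()
        return obj


class EconomicLandUseMap(FractionMap):
    """Fractions over economic-model land-use categories, per scenario."""


class PredictsLandUseLayer(FractionMap):
    """Fractions over biodiversity-model (land-use, intensity) classes.

    Variable names follow ``landuse_intensity`` (e.g. ``annual_minimal``,
    ``pasture_light``) or a bare land-use name where no intensity applies
    (``primary``, ``secondary``, ``rangeland``, ``urban``).
    """


class PftLayer(FractionMap):
    """Fractions over plant functional types (crop/grass/forest/bare-soil)."""
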