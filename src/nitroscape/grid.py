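"""Regular latitude–longitude grids with spherical cell areas.

All downstream layers (land-use fractions, carbon densities, biodiversity
indicators) live on a :class:`GridDefinition`: a regular lattice of cell
centers with a per-latitude-band cell area in hectares computed from the
spherical band formula ``R² · Δλ · (sin φ₂ − sin φ₁)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EARTH_RADIUS_M = 6_371_000.0

#: Default analysis window: an EU-like domain spanning 35.25–69.25°N and
#: 9.25°W–34.25°E at half-degree resolution.
DEFAULT_DOMAIN = (35.25, 69.25, -9.25, 34.25)


@dataclass(frozen=True)
class GridDefinition:
    """A regular lat–lon grid.

    Parameters
    ----------
    lat_min, lat_max, lon_min, lon_max : float
        Domain bounds in degrees. ``lat_min < lat_max`` and
        ``lon_min < lon_max``; the resolution must divide both extents.
    resolution : float
        Cell size in degrees (default 0.5).
    """

    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float
    resolution: float = 0.5
    lats: np.ndarray = field(init=False, repr=False, compare=False)
    lons: np.ndarray = field(init=False, repr=False, compare=False)
    cell_area: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError(f"resolution must be positive, got {self.resolution}")
        if self.lat_min >= self.lat_max:
            raise ValueError(
                f"empty latitude range [{self.lat_min}, {self.lat_max}]"
            )
        if self.lon_min >= self.lon_max:
            raise ValueError(
                f"empty longitude range [{self.lon_min}, {self.lon_max}]"
            )
        nlat = (self.lat_max - self.lat_min) / self.resolution
        nlon = (self.lon_max - self.lon_min) / self.resolution
        if abs(nlat - round(nlat)) > 1e-9 or abs(nlon - round(nlon)) > 1e-9:
            raise ValueError("resolution must divide both domain extents")
        nlat, nlon = int(round(nlat)), int(round(nlon))
        half = self.resolution / 2.0
        lats = self.lat_min + half + self.resolution * np.arange(nlat)
        lons = self.lon_min + half + self.resolution * np.arange(nlon)
        object.__setattr__(self, "lats", lats)
        object.__setattr__(self, "lons", lons)
        object.__setattr__(self, "cell_area", _band_areas_ha(lats, self.resolution))

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.lats), len(self.lons)

    @property
    def n_cells(self) -> int:
        return len(self.lats) * len(self.lons)

    def cell_area_2d(self) -> np.ndarray:
        """Cell area in hectares, broadcast to the full (lat, lon) shape."""
        return np.broadcast_to(
            self.cell_area[:, None], self.shape
        ).copy()


def _band_areas_ha(lat_centers: np.ndarray, resolution: float) -> np.ndarray:
    """Area (ha) of one cell in each latitude band.

    Spherical band: A = R² · Δλ · (sin φ₂ − sin φ₁), with Δλ the cell width
    in radians and φ₁, φ₂ the cell's bounding latitudes.
    """
    half = resolution / 2.0
    phi1 = np.radians(lat_centers - half)
    phi2 = np.radians(lat_centers + half)
    dlon = np.radians(resolution)
    area_m2 = EARTH_RADIUS_M**2 * dlon * (np.sin(phi2) - np.sin(phi1))
    return area_m2 / 1e4  # m² → ha


def generate_grid(
    domain: tuple[float, float, float, float] = DEFAULT_DOMAIN,
    resolution: float = 0.5,
) -> GridDefinition:
    """Build a :class:`GridDefinition` from (lat_min, lat_max, lon_min, lon_max)."""
    lat_min, lat_max, lon_min, lon_max = domain
    return GridDefinition(lat_min, lat_max, lon_min, lon_max, resolution)
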