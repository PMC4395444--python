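"""Geographic primitives: great-circle distance and prediction grids.

All coordinates are decimal-degree latitude/longitude on a sphere of
radius 6371 km; no map projection is ever applied. A :class:`SpatialGrid`
is the discrete domain over which occurrence surfaces are estimated and
origin posteriors are evaluated — cell *centers* represent cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyGridError, InvalidInputError

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "EARTH_RADIUS_KM",
    "GeoCoordinate",
    "BoundingBox",
    "SpatialGrid",
    "great_circle_distance",
    "haversine_km",
    "pairwise_distances",
    "build_grid",
]


@dataclass(frozen=True)
class GeoCoordinate:
    """A point on the globe in decimal degrees (WGS84-style lat/lon)."""

    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lat) and math.isfinite(self.lon)):
            raise InvalidInputError(f"non-finite coordinate ({self.lat}, {self.lon})")
        if not -90.0 <= self.lat <= 90.0:
            raise InvalidInputError(f"latitude {self.lat} outside [-90, 90]")
        if not -180.0 <= self.lon <= 180.0:
            raise InvalidInputError(f"longitude {self.lon} outside [-180, 180]")


@dataclass(frozen=True)
class BoundingBox:
    """Latitude/longitude extent (degrees), inclusive of its edges."""

    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float

    def __post_init__(self) -> None:
        if not all(
            math.isfinite(v)
            for v in (self.lat_min, self.lat_max, self.lon_min, self.lon_max)
        ):
            raise InvalidInputError("non-finite bounding box")
        if self.lat_min >= self.lat_max or self.lon_min >= self.lon_max:
            raise InvalidInputError(f"degenerate bounding box {self}")


def haversine_km(
    lat1: np.ndarray | float,
    lon1: np.ndarray | float,
    lat2: np.ndarray | float,
    lon2: np.ndarray | float,
) -> np.ndarray | float:
    """Vectorized great-circle distance in km (haversine, spherical Earth)."""
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    # guard tiny negative / >1 values from rounding
    a = np.clip(a, 0.0, 1.0)
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def great_circle_distance(a: GeoCoordinate, b: GeoCoordinate) -> float:
    """Great-circle distance in km between two coordinates.

    Symmetric, non-negative and zero iff the coordinates coincide (to
    floating tolerance).
    """
    return float(haversine_km(a.lat, a.lon, b.lat, b.lon))


def pairwise_distances(
    lats_a: np.ndarray,
    lons_a: np.ndarray,
    lats_b: np.ndarray,
    lons_b: np.ndarray,
) -> np.ndarray:
    """(len(a), len(b)) matrix of great-circle distances in km."""
    la = np.asarray(lats_a, dtype=float)[:, None]
    lo = np.asarray(lons_a, dtype=float)[:, None]
    lb = np.asarray(lats_b, dtype=float)[None, :]
    ob = np.asarray(lons_b, dtype=float)[None, :]
    return haversine_km(la, lo, lb, ob)


@dataclass
class SpatialGrid:
    """Ordered cell centers of a rectangular lat/lon partition.

    Cells are ordered row-major: south to north, west to east within each
    row. ``cell_height_km``/``cell_width_km`` are evaluated at the domain's
    central latitude and describe a single cell's physical extent.
    """

    lats: np.ndarray
    lons: np.ndarray
    cell_height_km: float
    cell_width_km: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lats = np.asarray(self.lats, dtype=float)
        self.lons = np.asarray(self.lons, dtype=float)
        if self.lats.shape != self.lons.shape or self.lats.ndim != 1:
            raise InvalidInputError("grid lats/lons must be equal-length 1-D arrays")
        if self.lats.size < 1:
            raise EmptyGridError("grid has no cells")
        if self.cell_height_km <= 0 or self.cell_width_km <= 0:
            raise InvalidInputError("cell dimensions must be positive")

    @property
    def n_cells(self) -> int:
        return int(self.lats.size)

    @property
    def points(self) -> list[GeoCoordinate]:
        return [GeoCoordinate(la, lo) for la, lo in zip(self.lats, self.lons)]

    def coordinate(self, index: int) -> GeoCoordinate:
        return GeoCoordinate(float(self.lats[index]), float(self.lons[index]))

    def nearest_cell(self, lat: float, lon: float) -> int:
        """Index of the cell center nearest a point (ties to lowest index)."""
        d = haversine_km(float(lat), float(lon), self.lats, self.lons)
        return int(np.argmin(d))

    def nearest_cells(self, lats: Sequence[float], lons: Sequence[float]) -> np.ndarray:
        d = pairwise_distances(np.asarray(lats), np.asarray(lons), self.lats, self.lons)
        return np.argmin(d, axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cell_index": np.arange(self.n_cells), "lat": self.lats, "lon": self.lons}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path, cell_height_km: float, cell_width_km: float) -> "SpatialGrid":
        df = pd.read_csv(path)
        return cls(
            lats=df["lat"].to_numpy(),
            lons=df["lon"].to_numpy(),
            cell_height_km=cell_height_km,
            cell_width_km=cell_width_km,
        )


def _mask_contains(mask, lons: np.ndarray, lats: np.ndarray) -> np.ndarray:
    """Boolean membership of points in a shapely polygon; boundary counts inside."""
    import shapely

    pts = shapely.points(lons, lats)
    # covers() (unlike contains()) includes the boundary
    return shapely.covers(mask, pts)


def build_grid(
    bbox: BoundingBox | tuple[float, float, float, float],
    nx: int,
    ny: int,
    mask=None,
) -> SpatialGrid:
    """Partition ``bbox`` into ``nx`` (east-west) by ``ny`` (north-south) cells.

    Returns the cell centers, optionally retaining only those falling inside
    ``mask`` (a shapely Polygon/MultiPolygon in lon/lat; boundary points are
    kept). Raises :class:`EmptyGridError` if the mask excludes everything.
    """
    if not isinstance(bbox, BoundingBox):
        bbox = BoundingBox(*bbox)
    if nx < 1 or ny < 1:
        raise InvalidInputError("nx and ny must be >= 1")

    dlat = (bbox.lat_max - bbox.lat_min) / ny
    dlon = (bbox.lon_max - bbox.lon_min) / nx
    lat_centers = bbox.lat_min + dlat * (np.arange(ny) + 0.5)
    lon_centers = bbox.lon_min + dlon * (np.arange(nx) + 0.5)
    # row-major: south->north outer, west->east inner
    lat_g, lon_g = np.meshgrid(lat_centers, lon_centers, indexing="ij")
    lats, lons = lat_g.ravel(), lon_g.ravel()

    mask_id = None
    if mask is not None:
        keep = _mask_contains(mask, lons, lats)
        if not keep.any():
            raise EmptyGridError("mask excludes all grid cell centers")
        lats, lons = lats[keep], lons[keep]
        mask_id = getattr(mask, "geom_type", str(type(mask)))

    central_lat = 0.5 * (bbox.lat_min + bbox.lat_max)
    cell_height_km = EARTH_RADIUS_KM * math.radians(dlat)
    cell_width_km = EARTH_RADIUS_KM * math.cos(math.radians(central_lat)) * math.radians(dlon)
    return SpatialGrid(
        lats=lats,
        lons=lons,
        cell_height_km=cell_height_km,
        cell_width_km=cell_width_km,
        provenance={
            "bbox": (bbox.lat_min, bbox.lat_max, bbox.lon_min, bbox.lon_max),
            "nx": nx,
            "ny": ny,
            "dlat_deg": dlat,
            "dlon_deg": dlon,
            "mask": mask_id,
        },
    )
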