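"""Georeferencing of a raster layer on a geographic (lon/lat) grid.

A :class:`GridSpec` describes a north-up regular grid in EPSG:4326 decimal
degrees: pixel (0, 0) has its north-west corner at ``(origin_lat,
origin_lon)`` and rows advance southwards.  All layers of a data packet
share one GridSpec, and all point queries reduce to the pixel math here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import OutOfBounds

#: The only coordinate system supported; inputs must already be lon/lat.
WGS84 = "EPSG:4326"

_EPS = 1e-9


@dataclass(frozen=True)
class GridSpec:
    """Regular north-up geographic grid.

    Parameters
    ----------
    origin_lon:
        Longitude of the west edge of pixel (0, 0), degrees in [-180, 180).
    origin_lat:
        Latitude of the north edge of pixel (0, 0), degrees in (-90, 90].
    res_lon, res_lat:
        Pixel size in degrees, strictly positive.
    width, height:
        Raster dimensions in pixels.
    crs_id:
        Coordinate system identifier; always ``"EPSG:4326"``.
    tile_size:
        Edge length in pixels of the internal tiles used for partial reads.
    """

    origin_lon: float
    origin_lat: float
    res_lon: float
    res_lat: float
    width: int
    height: int
    crs_id: str = WGS84
    tile_size: int = 256

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("grid width and height must be positive")
        if self.res_lon <= 0 or self.res_lat <= 0:
            raise ValueError("grid resolution must be positive")
        if self.tile_size <= 0:
            raise ValueError("tile_size must be positive")
        if not (-180.0 <= self.origin_lon < 180.0):
            raise ValueError("origin_lon must lie in [-180, 180)")
        if not (-90.0 < self.origin_lat <= 90.0):
            raise ValueError("origin_lat must lie in (-90, 90]")
        if self.origin_lon + self.width * self.res_lon > 180.0 + _EPS:
            raise ValueError("grid extends east of longitude 180")
        if self.origin_lat - self.height * self.res_lat < -90.0 - _EPS:
            raise ValueError("grid extends south of latitude -90")

    # -- extents ---------------------------------------------------------

    @property
    def east(self) -> float:
        return self.origin_lon + self.width * self.res_lon

    @property
    def south(self) -> float:
        return self.origin_lat - self.height * self.res_lat

    @property
    def n_tile_rows(self) -> int:
        return math.ceil(self.height / self.tile_size)

    @property
    def n_tile_cols(self) -> int:
        return math.ceil(self.width / self.tile_size)

    # -- pixel math ------------------------------------------------------

    def pixel_center(self, row: int, col: int) -> tuple[float, float]:
        """(lat, lon) of the center of pixel (row, col)."""
        lat = self.origin_lat - (row + 0.5) * self.res_lat
        lon = self.origin_lon + (col + 0.5) * self.res_lon
        return lat, lon

    def tile_of(self, row: int, col: int) -> tuple[int, int]:
        """(tile_row, tile_col) of the tile containing pixel (row, col)."""
        return row // self.tile_size, col // self.tile_size

    def same_georeference(self, other: "GridSpec") -> bool:
        """True when two grids agree on everything except tiling."""
        return (
            self.crs_id == other.crs_id
            and self.width == other.width
            and self.height == other.height
            and math.isclose(self.origin_lon, other.origin_lon, abs_tol=_EPS)
            and math.isclose(self.origin_lat, other.origin_lat, abs_tol=_EPS)
            and math.isclose(self.res_lon, other.res_lon, rel_tol=1e-12)
            and math.isclose(self.res_lat, other.res_lat, rel_tol=1e-12)
        )


def lonlat_to_pixel(grid: GridSpec, latitude: float, longitude: float) -> tuple[int, int]:
    """Map a geographic point to the (row, col) of the pixel containing it.

    Each pixel owns the half-open footprint ``[west, east) x (south, north]``:
    a point exactly on a pixel's north or west edge belongs to that pixel,
    so the grid's own north and west outer edges map to row 0 / col 0 and
    the south and east outer edges are outside.

    Raises
    ------
    OutOfBounds
        When the resulting index falls outside ``[0, height) x [0, width)``;
        the exception carries the computed indices.
    """
    if not (math.isfinite(latitude) and math.isfinite(longitude)):
        raise ValueError("latitude and longitude must be finite")
    col = math.floor((longitude - grid.origin_lon) / grid.res_lon)
    row = math.floor((grid.origin_lat - latitude) / grid.res_lat)
    if not (0 <= row < grid.height and 0 <= col < grid.width):
        raise OutOfBounds(row, col)
    return row, col
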