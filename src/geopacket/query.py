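"""Point queries against a data packet, with caching and read accounting.

The engine never hands coordinates to the payload store.  A query is
resolved in two steps: coordinate → pixel index (:func:`lonlat_to_pixel`),
then pixel → tile, and the store is asked only for ``(feature, tile_row,
tile_col)``.  Every store request is recorded in a :class:`TileReadLog`,
which makes two contracts testable: *parsimony* (a tile is fetched at most
once per run when caching is on, however many samples fall in it) and
*privacy* (request shapes contain tile indices, never latitudes or
longitudes).

Annotation of a sample sheet is a pure function of (records, packet): the
same inputs always produce the same annotations, and records with invalid
coordinates are carried through with a status flag, never dropped.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Union

import numpy as np

from .datapacket import DataPacket, LayerKind, LayerMeta
from .errors import OutOfBounds, UnknownFeature
from .grid import GridSpec, lonlat_to_pixel
from .packetio import PacketReader
from .validate import parse_coordinate

Packet = Union[DataPacket, PacketReader]


@dataclass(frozen=True)
class SampleRecord:
    """One row of a sample sheet, with coordinates kept as submitted.

    Coordinates stay raw strings so QC can inspect exactly what was
    submitted; numeric values are recovered with
    :func:`geopacket.validate.parse_coordinate`.
    """

    sample_id: str
    latitude: str
    longitude: str
    extras: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        for name in ("latitude", "longitude"):
            v = getattr(self, name)
            if not isinstance(v, str):
                object.__setattr__(self, name, format(float(v), ".10g"))


@dataclass(frozen=True)
class CategoricalValue:
    code: int
    short_label: str
    long_label: str


class AnnotationStatus(str, Enum):
    ANNOTATED = "annotated"
    OUT_OF_BOUNDS = "out_of_bounds"
    NODATA_PARTIAL = "nodata_partial"
    INVALID_COORDINATES = "invalid_coordinates"


@dataclass(frozen=True)
class AnnotationRecord:
    """Feature values resolved for one sample.

    ``values[feature]`` is a :class:`CategoricalValue` for categorical
    layers, a float in layer units for continuous layers, or ``None`` when
    the pixel was nodata or the point fell outside that layer's grid.
    """

    sample_id: str
    values: Mapping[str, CategoricalValue | float | None]
    status: AnnotationStatus
    extras: Mapping[str, str] = field(default_factory=dict)


class TileReadLog:
    """Counts payload-store reads per (feature, tile_row, tile_col).

    ``requests`` keeps the raw request tuples in order, which lets tests
    assert the privacy contract: the store never sees coordinates.
    """

    def __init__(self) -> None:
        self.counts: dict[tuple[str, int, int], int] = {}
        self.requests: list[tuple[str, int, int]] = []

    def record(self, feature: str, tile_row: int, tile_col: int) -> None:
        key = (feature, tile_row, tile_col)
        self.counts[key] = self.counts.get(key, 0) + 1
        self.requests.append(key)

    def total_reads(self) -> int:
        return sum(self.counts.values())

    def reads_for_feature(self, feature: str) -> int:
        return sum(n for (f, _, _), n in self.counts.items() if f == feature)


class TileCache:
    """Per-run tile cache keyed by (feature, tile_row, tile_col).

    Unbounded by default — desk-scale packets fit easily — with an optional
    ``max_tiles`` knob applying least-recently-used eviction.
    """

    def __init__(self, max_tiles: int | None = None):
        if max_tiles is not None and max_tiles < 1:
            raise ValueError("max_tiles must be positive or None")
        self.max_tiles = max_tiles
        self._tiles: OrderedDict[tuple[str, int, int], np.ndarray] = OrderedDict()

    def get(self, key: tuple[str, int, int]) -> np.ndarray | None:
        tile = self._tiles.get(key)
        if tile is not None:
            self._tiles.move_to_end(key)
        return tile

    def put(self, key: tuple[str, int, int], tile: np.ndarray) -> None:
        self._tiles[key] = tile
        self._tiles.move_to_end(key)
        if self.max_tiles is not None and len(self._tiles) > self.max_tiles:
            self._tiles.popitem(last=False)

    def __len__(self) -> int:
        return len(self._tiles)


class _PayloadStore:
    """Uniform (feature, tile) access over in-memory or on-disk packets.

    This is the only interface through which queries touch raster data;
    its argument list is deliberately free of coordinates.
    """

    def __init__(self, packet: Packet):
        self._packet = packet
        self.grid: GridSpec = packet.grid
        if isinstance(packet, DataPacket):
            self._metas = {lyr.meta.feature_name: lyr.meta for lyr in packet.layers}
        else:
            self._metas = {meta.feature_name: meta for meta, _ in packet.layers}

    @property
    def feature_names(self) -> list[str]:
        return list(self._metas)

    def meta(self, feature_name: str) -> LayerMeta:
        try:
            return self._metas[feature_name]
        except KeyError:
            raise UnknownFeature(f"packet has no layer {feature_name!r}") from None

    def read_tile(self, feature_name: str, tile_row: int, tile_col: int) -> np.ndarray:
        self.meta(feature_name)  # raises UnknownFeature
        ts = self.grid.tile_size
        if isinstance(self._packet, DataPacket):
            data = self._packet.layer(feature_name).data
            r0, c0 = tile_row * ts, tile_col * ts
            return data[r0:r0 + ts, c0:c0 + ts]
        for meta, reader in self._packet.layers:
            if meta.feature_name == feature_name:
                return reader.read_tile(tile_row, tile_col)
        raise UnknownFeature(feature_name)


def _fetch_tile(
    store: _PayloadStore,
    feature_name: str,
    tile_row: int,
    tile_col: int,
    log: TileReadLog | None,
    cache: TileCache | None,
) -> np.ndarray:
    key = (feature_name, tile_row, tile_col)
    if cache is not None:
        tile = cache.get(key)
        if tile is not None:
            return tile
    if log is not None:
        log.record(feature_name, tile_row, tile_col)
    tile = store.read_tile(feature_name, tile_row, tile_col)
    if cache is not None:
        cache.put(key, tile)
    return tile


def _resolve_value(meta: LayerMeta, raw) -> CategoricalValue | float | None:
    if raw == meta.nodata:
        return None
    if meta.kind is LayerKind.CATEGORICAL:
        code = int(raw)
        table = meta.category_table
        assert table is not None
        return CategoricalValue(code, table.short_label(code), table.long_label(code))
    return float(raw)


def sample_point(
    packet: Packet,
    feature_name: str,
    latitude: float,
    longitude: float,
    log: TileReadLog | None = None,
    cache: TileCache | None = None,
) -> CategoricalValue | float | None:
    """Value of one feature at one point, reading only the covering tile.

    Returns ``None`` when the pixel holds the layer's nodata sentinel.
    Categorical values come back with their labels resolved.

    Raises :class:`UnknownFeature` for an unknown feature name and
    propagates :class:`OutOfBounds` from the pixel mapping.
    """
    store = packet if isinstance(packet, _PayloadStore) else _PayloadStore(packet)
    meta = store.meta(feature_name)
    row, col = lonlat_to_pixel(store.grid, latitude, longitude)
    tile_row, tile_col = store.grid.tile_of(row, col)
    tile = _fetch_tile(store, feature_name, tile_row, tile_col, log, cache)
    ts = store.grid.tile_size
    raw = tile[row - tile_row * ts, col - tile_col * ts]
    return _resolve_value(meta, raw)


def coordinates_valid(record: SampleRecord) -> tuple[float, float] | None:
    """Parsed (lat, lon) when both coordinates are plain decimals within
    WGS84 bounds; ``None`` otherwise."""
    lat = parse_coordinate(record.latitude)
    lon = parse_coordinate(record.longitude)
    if lat is None or lon is None:
        return None
    if abs(lat) > 90.0 or abs(lon) > 180.0:
        return None
    return lat, lon


def annotate(
    records: list[SampleRecord],
    packet: Packet,
    log: TileReadLog | None = None,
    cache: TileCache | None = None,
    use_cache: bool = True,
) -> list[AnnotationRecord]:
    """Annotate a sample sheet with every feature in the packet.

    One :class:`AnnotationRecord` per input record, in input order.
    Records whose coordinates fail validation get
    ``status=invalid_coordinates`` with all values missing; points outside
    the grid get ``out_of_bounds``; points whose pixel is nodata for at
    least one layer get ``nodata_partial``.  With caching enabled (the
    default) each (layer, tile) is fetched from the payload store at most
    once, however many records fall in it.
    """
    store = _PayloadStore(packet)
    if cache is None and use_cache:
        cache = TileCache()
    out: list[AnnotationRecord] = []
    for record in records:
        parsed = coordinates_valid(record)
        if parsed is None:
            out.append(
                AnnotationRecord(
                    sample_id=record.sample_id,
                    values={name: None for name in store.feature_names},
                    status=AnnotationStatus.INVALID_COORDINATES,
                    extras=record.extras,
                )
            )
            continue
        lat, lon = parsed
        values: dict[str, CategoricalValue | float | None] = {}
        status = AnnotationStatus.ANNOTATED
        try:
            row_col = lonlat_to_pixel(store.grid, lat, lon)
        except OutOfBounds:
            out.append(
                AnnotationRecord(
                    sample_id=record.sample_id,
                    values={name: None for name in store.feature_names},
                    status=AnnotationStatus.OUT_OF_BOUNDS,
                    extras=record.extras,
                )
            )
            continue
        row, col = row_col
        tile_row, tile_col = store.grid.tile_of(row, col)
        ts = store.grid.tile_size
        any_missing = False
        for name in store.feature_names:
            tile = _fetch_tile(store, name, tile_row, tile_col, log, cache)
            raw = tile[row - tile_row * ts, col - tile_col * ts]
            value = _resolve_value(store.meta(name), raw)
            values[name] = value
            any_missing = any_missing or value is None
        if any_missing:
            status = AnnotationStatus.NODATA_PARTIAL
        out.append(
            AnnotationRecord(
                sample_id=record.sample_id,
                values=values,
                status=status,
                extras=record.extras,
            )
        )
    return out
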