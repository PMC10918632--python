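"""Versioned multi-layer raster data packets.

A *data packet* bundles co-registered single-band rasters (climate class,
rurality, population density, emissions, deprivation, ...) on one shared
EPSG:4326 grid, together with per-layer metadata: feature name, kind
(categorical or continuous), units, nodata sentinel, category table, and a
BibTeX source citation.  Once released a packet version is static; updates
go into a new packet with an appended changelog entry, so every annotation
can name the exact data it came from.

This module defines the in-memory model, the ``build_packet`` resampling
that co-registers heterogeneous sources onto the target grid, and BibTeX
citation emission.  Serialization lives in :mod:`geopacket.packetio`.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

from .categories import CategoryTable
from .errors import (
    CitationError,
    CRSMismatch,
    DuplicateLayer,
    EmptyIntersection,
    UnknownFeature,
)
from .grid import GridSpec

#: Default nodata sentinels (recorded per layer; never assumed downstream).
DEFAULT_NODATA_CATEGORICAL = 255
DEFAULT_NODATA_CONTINUOUS = -3.4e38


class LayerKind(str, Enum):
    CATEGORICAL = "categorical"
    CONTINUOUS = "continuous"


@dataclass(frozen=True)
class LayerMeta:
    """Descriptive metadata of one raster layer."""

    feature_name: str
    kind: LayerKind
    units: str
    nodata: float
    citation: str
    category_table: CategoryTable | None = None
    source_version: str = ""
    resolution_note: str = ""

    def __post_init__(self) -> None:
        if not self.feature_name:
            raise ValueError("feature_name must be non-empty")
        kind = LayerKind(self.kind)
        object.__setattr__(self, "kind", kind)
        # normalize so citations compare equal across file round-trips
        object.__setattr__(self, "citation", self.citation.strip())
        if kind is LayerKind.CATEGORICAL and self.category_table is None:
            raise ValueError(f"categorical layer {self.feature_name!r} needs a category table")
        if kind is LayerKind.CONTINUOUS and self.category_table is not None:
            raise ValueError(f"continuous layer {self.feature_name!r} cannot have a category table")


@dataclass
class Layer:
    """A raster payload plus its metadata."""

    meta: LayerMeta
    data: np.ndarray

    def __post_init__(self) -> None:
        if self.data.ndim != 2:
            raise ValueError("layer payload must be a 2-D array")

    def validate_categories(self) -> None:
        """Every categorical value must be nodata or a code in the table."""
        if self.meta.kind is not LayerKind.CATEGORICAL:
            return
        table = self.meta.category_table
        assert table is not None
        values = np.unique(self.data)
        bad = [int(v) for v in values if v != self.meta.nodata and int(v) not in table]
        if bad:
            raise ValueError(
                f"layer {self.meta.feature_name!r} holds codes {bad} absent from its category table"
            )


@dataclass
class DataPacket:
    """A versioned set of co-registered layers with provenance."""

    packet_version: str
    grid: GridSpec
    layers: list[Layer] = field(default_factory=list)
    changelog: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [lyr.meta.feature_name for lyr in self.layers]
        if len(set(names)) != len(names):
            raise DuplicateLayer(f"duplicate feature names in packet: {names}")
        for lyr in self.layers:
            if lyr.data.shape != (self.grid.height, self.grid.width):
                raise ValueError(
                    f"layer {lyr.meta.feature_name!r} shape {lyr.data.shape} does not match "
                    f"grid {(self.grid.height, self.grid.width)}"
                )

    @property
    def feature_names(self) -> list[str]:
        return [lyr.meta.feature_name for lyr in self.layers]

    def layer(self, feature_name: str) -> Layer:
        for lyr in self.layers:
            if lyr.meta.feature_name == feature_name:
                return lyr
        raise UnknownFeature(f"packet {self.packet_version!r} has no layer {feature_name!r}")

    def __contains__(self, feature_name: str) -> bool:
        return feature_name in self.feature_names


def packets_equal(a: DataPacket, b: DataPacket) -> bool:
    """Field-by-field equality, bit-exact on raster values."""
    if (
        a.packet_version != b.packet_version
        or a.grid != b.grid
        or a.changelog != b.changelog
        or a.feature_names != b.feature_names
    ):
        return False
    for la, lb in zip(a.layers, b.layers):
        if la.meta != lb.meta:
            return False
        if la.data.dtype != lb.data.dtype or not np.array_equal(la.data, lb.data):
            return False
    return True


# ---------------------------------------------------------------------------
# Resampling / packet assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LayerSource:
    """One input raster for ``build_packet``: payload + its own grid + meta."""

    data: np.ndarray
    grid: GridSpec
    meta: LayerMeta


def _nearest_indices(target: GridSpec, source: GridSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Source (row, col) of each target pixel center, plus validity mask."""
    t_lat = target.origin_lat - (np.arange(target.height) + 0.5) * target.res_lat
    t_lon = target.origin_lon + (np.arange(target.width) + 0.5) * target.res_lon
    src_row = np.floor((source.origin_lat - t_lat) / source.res_lat).astype(np.int64)
    src_col = np.floor((t_lon - source.origin_lon) / source.res_lon).astype(np.int64)
    row_ok = (src_row >= 0) & (src_row < source.height)
    col_ok = (src_col >= 0) & (src_col < source.width)
    mask = row_ok[:, None] & col_ok[None, :]
    return src_row, src_col, mask


def _resample_nearest(src: LayerSource, target: GridSpec) -> np.ndarray:
    src_row, src_col, mask = _nearest_indices(target, src.grid)
    out = np.full((target.height, target.width), src.meta.nodata, dtype=src.data.dtype)
    rr = np.clip(src_row, 0, src.grid.height - 1)
    cc = np.clip(src_col, 0, src.grid.width - 1)
    sampled = src.data[rr[:, None], cc[None, :]]
    out[mask] = sampled[mask]
    return out


def _resample_mean(src: LayerSource, target: GridSpec) -> np.ndarray:
    """Area-mean coarsening: average source pixels whose centers fall in
    each target pixel footprint, ignoring nodata."""
    s_lat = src.grid.origin_lat - (np.arange(src.grid.height) + 0.5) * src.grid.res_lat
    s_lon = src.grid.origin_lon + (np.arange(src.grid.width) + 0.5) * src.grid.res_lon
    t_row = np.floor((target.origin_lat - s_lat) / target.res_lat).astype(np.int64)
    t_col = np.floor((s_lon - target.origin_lon) / target.res_lon).astype(np.int64)
    row_ok = (t_row >= 0) & (t_row < target.height)
    col_ok = (t_col >= 0) & (t_col < target.width)
    data = src.data.astype(np.float64)
    valid = row_ok[:, None] & col_ok[None, :] & (src.data != src.meta.nodata)
    sums = np.zeros((target.height, target.width), dtype=np.float64)
    counts = np.zeros((target.height, target.width), dtype=np.int64)
    rr = np.broadcast_to(t_row[:, None], data.shape)[valid]
    cc = np.broadcast_to(t_col[None, :], data.shape)[valid]
    np.add.at(sums, (rr, cc), data[valid])
    np.add.at(counts, (rr, cc), 1)
    out = np.full((target.height, target.width), src.meta.nodata, dtype=np.float64)
    covered = counts > 0
    out[covered] = sums[covered] / counts[covered]
    return out


def _intersects(a: GridSpec, b: GridSpec) -> bool:
    return not (
        a.east <= b.origin_lon
        or b.east <= a.origin_lon
        or a.origin_lat <= b.south
        or b.origin_lat <= a.south
    )


def build_packet(
    sources: list[LayerSource],
    target_grid: GridSpec,
    packet_version: str = "v1",
    changelog: list[tuple[str, str]] | None = None,
) -> DataPacket:
    """Co-register source rasters onto ``target_grid`` and assemble a packet.

    Categorical sources are resampled by nearest neighbor (the source pixel
    containing each target pixel center); category codes are never
    interpolated.  Continuous sources are averaged over covered source
    pixels when coarsening and sampled nearest-neighbor when refining or at
    equal resolution.  Nodata propagates: a target pixel whose sampled
    source pixels are all nodata becomes nodata.

    Raises
    ------
    CRSMismatch
        A source grid is not on the target coordinate system.
    EmptyIntersection
        A source footprint does not overlap the target grid.
    DuplicateLayer
        Two sources share one feature name.
    """
    seen: set[str] = set()
    layers: list[Layer] = []
    for src in sources:
        if src.grid.crs_id != target_grid.crs_id:
            raise CRSMismatch(
                f"source {src.meta.feature_name!r} is on {src.grid.crs_id}, "
                f"target is {target_grid.crs_id}"
            )
        if not _intersects(src.grid, target_grid):
            raise EmptyIntersection(
                f"source {src.meta.feature_name!r} does not intersect the target grid"
            )
        if src.meta.feature_name in seen:
            raise DuplicateLayer(f"duplicate feature name {src.meta.feature_name!r}")
        seen.add(src.meta.feature_name)

        if src.meta.kind is LayerKind.CATEGORICAL:
            data = _resample_nearest(src, target_grid)
        else:
            coarsening = (
                target_grid.res_lon > src.grid.res_lon * (1 + 1e-12)
                or target_grid.res_lat > src.grid.res_lat * (1 + 1e-12)
            )
            data = _resample_mean(src, target_grid) if coarsening else _resample_nearest(src, target_grid)
        layer = Layer(meta=src.meta, data=data)
        layer.validate_categories()
        layers.append(layer)

    return DataPacket(
        packet_version=packet_version,
        grid=target_grid,
        layers=layers,
        changelog=list(changelog) if changelog else [(packet_version, "initial release")],
    )


# ---------------------------------------------------------------------------
# Citations
# ---------------------------------------------------------------------------

_BIB_HEAD = re.compile(r"@\s*(\w+)\s*\{\s*([^,\s]+)\s*,", re.DOTALL)


def parse_bibtex_entry(text: str) -> tuple[str, str]:
    """Parse one BibTeX entry; return (entry_type, citation_key).

    A deliberately small parser: it checks the ``@type{key, ...}`` shape and
    balanced braces, which is all the packet contract needs (validity plus a
    deduplication key).
    """
    stripped = text.strip()
    m = _BIB_HEAD.match(stripped)
    if not m:
        raise CitationError("citation does not start with a BibTeX @type{key, header")
    depth = 0
    end = None
    for i, ch in enumerate(stripped):
        if ch == "{":
            depth += 1
        elif ch == "}":
            depth -= 1
            if depth == 0:
                end = i
                break
    if end is None or stripped[end + 1:].strip():
        raise CitationError("citation is not exactly one balanced BibTeX entry")
    return m.group(1).lower(), m.group(2)


def emit_citations(packet: DataPacket) -> str:
    """Concatenate the packet's source citations as one BibTeX document.

    Entries are de-duplicated by citation key and emitted in layer order of
    first appearance, so the document is deterministic for a given packet.
    """
    seen: dict[str, str] = {}
    order: list[str] = []
    for lyr in packet.layers:
        citation = lyr.meta.citation
        try:
            _, key = parse_bibtex_entry(citation)
        except CitationError as exc:
            raise CitationError(
                f"layer {lyr.meta.feature_name!r}: {exc}"
            ) from None
        if key not in seen:
            seen[key] = citation.strip()
            order.append(key)
    return "\n\n".join(seen[k] for k in order) + "\n"


def with_new_version(
    packet: DataPacket, new_version: str, description: str
) -> DataPacket:
    """Derive the next packet version, preserving the changelog (append-only)."""
    return DataPacket(
        packet_version=new_version,
        grid=packet.grid,
        layers=[Layer(meta=replace(lyr.meta), data=lyr.data.copy()) for lyr in packet.layers],
        changelog=[*packet.changelog, (new_version, description)],
    )


# re-export for convenience
__all__ = [
    "LayerKind",
    "LayerMeta",
    "Layer",
    "LayerSource",
    "DataPacket",
    "build_packet",
    "packets_equal",
    "parse_bibtex_entry",
    "emit_citations",
    "with_new_version",
    "DEFAULT_NODATA_CATEGORICAL",
    "DEFAULT_NODATA_CONTINUOUS",
]
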