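"""On-disk format of a data packet and tile-granular partial reads.

A packet directory holds::

    manifest.txt          key-value manifest, one section per layer
    CHANGELOG.txt         append-only (version, description) lines
    layers/<feature>.tif  tiled single-band GeoTIFF, one per layer
    citations/<feature>.bib

Rasters are uncompressed tiled GeoTIFFs with standard georeferencing tags
(ModelPixelScale, ModelTiepoint, GeoKeyDirectory for EPSG:4326, and the
GDAL nodata tag), so any GIS tool can open them.  Because tiles are stored
uncompressed at known byte offsets, reading one tile is a true partial
read: :class:`GeoTiffLayerReader.read_tile` seeks to the tile's offset and
reads only its bytes, never the whole raster.  This is the local analogue
of range-request access to a cloud-optimized GeoTIFF, and it is what makes
the privacy contract auditable: the payload store is only ever asked for
(layer, tile index), never for coordinates.

TIFF requires file tile edges to be multiples of 16; when a grid's logical
``tile_size`` is not, the file uses the next multiple of 16 and logical
tile reads crop from the file tiles that cover them.  Read accounting and
caching always operate on the grid's logical tiles.
"""

from __future__ import annotations

import math
import os
from pathlib import Path

import numpy as np
import tifffile

from .categories import CategoryTable
from .datapacket import DataPacket, Layer, LayerKind, LayerMeta
from .errors import CorruptPacket, GridMismatch
from .grid import WGS84, GridSpec

MANIFEST_NAME = "manifest.txt"
CHANGELOG_NAME = "CHANGELOG.txt"

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_KEY_DIRECTORY = 34735
_TAG_GDAL_NODATA = 42113

# GeoKey ids: model type (2 = geographic), raster type (1 = PixelIsArea),
# geographic CRS code.
_GEOKEYS_WGS84 = (1, 1, 0, 3, 1024, 0, 1, 2, 1025, 0, 1, 1, 2048, 0, 1, 4326)


def _file_tile_size(tile_size: int) -> int:
    return ((tile_size + 15) // 16) * 16


# ---------------------------------------------------------------------------
# GeoTIFF write / read
# ---------------------------------------------------------------------------

def write_layer_geotiff(path: Path, data: np.ndarray, grid: GridSpec, nodata: float) -> None:
    scale = (grid.res_lon, grid.res_lat, 0.0)
    tiepoint = (0.0, 0.0, 0.0, grid.origin_lon, grid.origin_lat, 0.0)
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, scale, True),
        (_TAG_MODEL_TIEPOINT, "d", 6, tiepoint, True),
        (_TAG_GEO_KEY_DIRECTORY, "H", len(_GEOKEYS_WGS84), _GEOKEYS_WGS84, True),
        (_TAG_GDAL_NODATA, "s", None, repr(nodata) if isinstance(nodata, float) else str(nodata), True),
    ]
    ts = _file_tile_size(grid.tile_size)
    tifffile.imwrite(
        path,
        data,
        tile=(ts, ts),
        compression=None,
        extratags=extratags,
    )


class GeoTiffLayerReader:
    """Lazy single-layer reader with tile-granular partial reads.

    The reader keeps the TIFF open and serves windows by seeking directly
    to the stored tile byte ranges; it never materializes the full raster
    unless :meth:`read_full` is called.
    """

    def __init__(self, path: Path, grid: GridSpec):
        self.path = Path(path)
        self.grid = grid
        if not self.path.exists():
            raise CorruptPacket(f"missing layer file {self.path}")
        self._tif = tifffile.TiffFile(self.path)
        page = self._tif.pages[0]
        if not page.is_tiled:
            raise CorruptPacket(f"{self.path} is not a tiled raster")
        self._page = page
        self._ftw = page.tilewidth
        self._ftl = page.tilelength
        self._n_file_tile_cols = math.ceil(page.imagewidth / self._ftw)
        self._check_grid()

    def _check_grid(self) -> None:
        page = self._page
        if (page.imagelength, page.imagewidth) != (self.grid.height, self.grid.width):
            raise GridMismatch(
                f"{self.path}: raster is {page.imagewidth}x{page.imagelength} pixels but the "
                f"manifest claims {self.grid.width}x{self.grid.height}"
            )
        scale = page.tags.get(_TAG_MODEL_PIXEL_SCALE)
        tie = page.tags.get(_TAG_MODEL_TIEPOINT)
        if scale is None or tie is None:
            raise GridMismatch(f"{self.path}: missing GeoTIFF georeferencing tags")
        res_lon, res_lat = float(scale.value[0]), float(scale.value[1])
        origin_lon, origin_lat = float(tie.value[3]), float(tie.value[4])
        if not (
            math.isclose(res_lon, self.grid.res_lon, rel_tol=1e-12)
            and math.isclose(res_lat, self.grid.res_lat, rel_tol=1e-12)
            and math.isclose(origin_lon, self.grid.origin_lon, abs_tol=1e-9)
            and math.isclose(origin_lat, self.grid.origin_lat, abs_tol=1e-9)
        ):
            raise GridMismatch(f"{self.path}: GeoTIFF georeferencing disagrees with the manifest")

    def _read_file_tile(self, ftr: int, ftc: int) -> np.ndarray:
        """Read one raw file tile (padded shape) via a byte-range read."""
        page = self._page
        idx = ftr * self._n_file_tile_cols + ftc
        fh = self._tif.filehandle
        fh.seek(page.dataoffsets[idx])
        raw = fh.read(page.databytecounts[idx])
        return np.frombuffer(raw, dtype=page.dtype).reshape(self._ftl, self._ftw)

    def read_window(self, r0: int, r1: int, c0: int, c1: int) -> np.ndarray:
        """Read the half-open pixel window [r0:r1, c0:c1]."""
        out = np.empty((r1 - r0, c1 - c0), dtype=self._page.dtype)
        for ftr in range(r0 // self._ftl, (r1 - 1) // self._ftl + 1):
            for ftc in range(c0 // self._ftw, (c1 - 1) // self._ftw + 1):
                tile = self._read_file_tile(ftr, ftc)
                tr0, tc0 = ftr * self._ftl, ftc * self._ftw
                rr0, rr1 = max(r0, tr0), min(r1, tr0 + self._ftl)
                cc0, cc1 = max(c0, tc0), min(c1, tc0 + self._ftw)
                out[rr0 - r0:rr1 - r0, cc0 - c0:cc1 - c0] = tile[
                    rr0 - tr0:rr1 - tr0, cc0 - tc0:cc1 - tc0
                ]
        return out

    def read_tile(self, tile_row: int, tile_col: int) -> np.ndarray:
        """Read one logical tile of the grid, cropped to the raster extent."""
        ts = self.grid.tile_size
        r0 = tile_row * ts
        c0 = tile_col * ts
        r1 = min(r0 + ts, self.grid.height)
        c1 = min(c0 + ts, self.grid.width)
        return self.read_window(r0, r1, c0, c1)

    def read_full(self) -> np.ndarray:
        return self._page.asarray()

    def close(self) -> None:
        self._tif.close()


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

def _fmt_num(x: float) -> str:
    # repr round-trips floats exactly; ints stay ints
    return repr(int(x)) if isinstance(x, int) or (isinstance(x, float) and x.is_integer() and abs(x) < 1e15) else repr(x)


def _manifest_text(packet: DataPacket) -> str:
    g = packet.grid
    lines = [
        "# geopacket data packet manifest",
        f"packet_version: {packet.packet_version}",
        f"crs: {g.crs_id}",
        f"origin_lon: {_fmt_num(g.origin_lon)}",
        f"origin_lat: {_fmt_num(g.origin_lat)}",
        f"res_lon: {_fmt_num(g.res_lon)}",
        f"res_lat: {_fmt_num(g.res_lat)}",
        f"width: {g.width}",
        f"height: {g.height}",
        f"tile_size: {g.tile_size}",
        "",
    ]
    for lyr in packet.layers:
        m = lyr.meta
        lines.append(f"[layer {m.feature_name}]")
        lines.append(f"file: layers/{m.feature_name}.tif")
        lines.append(f"kind: {m.kind.value}")
        lines.append(f"units: {m.units}")
        lines.append(f"nodata: {_fmt_num(m.nodata)}")
        lines.append(f"dtype: {lyr.data.dtype.name}")
        lines.append(f"source_version: {m.source_version}")
        lines.append(f"resolution_note: {m.resolution_note}")
        lines.append(f"citation_file: citations/{m.feature_name}.bib")
        if m.category_table is not None:
            for code in sorted(m.category_table.entries):
                short, long_ = m.category_table.entries[code]
                lines.append(f"category.{code}: {short} | {long_}")
        lines.append("")
    return "\n".join(lines)


def _parse_manifest(text: str) -> tuple[str, dict[str, str], list[dict[str, str]]]:
    header: dict[str, str] = {}
    layers: list[dict[str, str]] = []
    current: dict[str, str] | None = None
    version = ""
    for raw in text.splitlines():
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        if line.startswith("[layer ") and line.endswith("]"):
            current = {"feature_name": line[len("[layer "):-1]}
            layers.append(current)
            continue
        if ":" not in line:
            raise CorruptPacket(f"unparseable manifest line: {line!r}")
        key, _, value = line.partition(":")
        key = key.strip()
        value = value[1:] if value.startswith(" ") else value
        if current is None:
            header[key] = value
            if key == "packet_version":
                version = value
        else:
            current[key] = value
    if not version:
        raise CorruptPacket("manifest lacks a packet_version")
    return version, header, layers


def _grid_from_header(header: dict[str, str]) -> GridSpec:
    try:
        return GridSpec(
            origin_lon=float(header["origin_lon"]),
            origin_lat=float(header["origin_lat"]),
            res_lon=float(header["res_lon"]),
            res_lat=float(header["res_lat"]),
            width=int(header["width"]),
            height=int(header["height"]),
            crs_id=header.get("crs", WGS84),
            tile_size=int(header["tile_size"]),
        )
    except KeyError as exc:
        raise CorruptPacket(f"manifest lacks grid field {exc}") from None


def _meta_from_section(section: dict[str, str], citation: str) -> LayerMeta:
    kind = LayerKind(section["kind"])
    table = None
    if kind is LayerKind.CATEGORICAL:
        entries: dict[int, tuple[str, str]] = {}
        for key, value in section.items():
            if key.startswith("category."):
                code = int(key[len("category."):])
                short, _, long_ = value.partition(" | ")
                entries[code] = (short, long_)
        table = CategoryTable(entries)
    nodata_str = section["nodata"]
    nodata: float = int(nodata_str) if "." not in nodata_str and "e" not in nodata_str.lower() else float(nodata_str)
    return LayerMeta(
        feature_name=section["feature_name"],
        kind=kind,
        units=section.get("units", ""),
        nodata=nodata,
        citation=citation,
        category_table=table,
        source_version=section.get("source_version", ""),
        resolution_note=section.get("resolution_note", ""),
    )


# ---------------------------------------------------------------------------
# write / read / open
# ---------------------------------------------------------------------------

def write_packet(packet: DataPacket, path: str | os.PathLike) -> Path:
    """Serialize a packet to a directory; returns the manifest path."""
    root = Path(path)
    (root / "layers").mkdir(parents=True, exist_ok=True)
    (root / "citations").mkdir(parents=True, exist_ok=True)
    for lyr in packet.layers:
        write_layer_geotiff(
            root / "layers" / f"{lyr.meta.feature_name}.tif",
            lyr.data,
            packet.grid,
            lyr.meta.nodata,
        )
        (root / "citations" / f"{lyr.meta.feature_name}.bib").write_text(
            lyr.meta.citation.strip() + "\n", encoding="utf-8"
        )
    (root / CHANGELOG_NAME).write_text(
        "".join(f"{v}\t{d}\n" for v, d in packet.changelog), encoding="utf-8"
    )
    manifest = root / MANIFEST_NAME
    manifest.write_text(_manifest_text(packet), encoding="utf-8")
    return manifest


class PacketReader:
    """An opened on-disk packet: metadata eager, raster payloads lazy.

    Point queries through :mod:`geopacket.query` read individual tiles via
    :meth:`GeoTiffLayerReader.read_tile`; call :meth:`load` to materialize
    the whole packet in memory.
    """

    def __init__(self, path: str | os.PathLike):
        self.root = Path(path)
        manifest_path = self.root / MANIFEST_NAME
        if not manifest_path.exists():
            raise CorruptPacket(f"no {MANIFEST_NAME} in {self.root}")
        version, header, sections = _parse_manifest(manifest_path.read_text(encoding="utf-8"))
        self.packet_version = version
        self.grid = _grid_from_header(header)
        self.changelog = self._read_changelog()
        self.layers: list[tuple[LayerMeta, GeoTiffLayerReader]] = []
        for section in sections:
            cit_path = self.root / section.get("citation_file", "")
            citation = cit_path.read_text(encoding="utf-8") if cit_path.is_file() else ""
            meta = _meta_from_section(section, citation)
            reader = GeoTiffLayerReader(self.root / section["file"], self.grid)
            self.layers.append((meta, reader))

    def _read_changelog(self) -> list[tuple[str, str]]:
        path = self.root / CHANGELOG_NAME
        if not path.exists():
            return []
        entries = []
        for line in path.read_text(encoding="utf-8").splitlines():
            if line.strip():
                version, _, description = line.partition("\t")
                entries.append((version, description))
        return entries

    @property
    def feature_names(self) -> list[str]:
        return [meta.feature_name for meta, _ in self.layers]

    def load(self) -> DataPacket:
        layers = [Layer(meta=meta, data=reader.read_full()) for meta, reader in self.layers]
        return DataPacket(
            packet_version=self.packet_version,
            grid=self.grid,
            layers=layers,
            changelog=self.changelog,
        )

    def close(self) -> None:
        for _, reader in self.layers:
            reader.close()

    def __enter__(self) -> "PacketReader":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def read_packet(path: str | os.PathLike) -> DataPacket:
    """Load a packet directory fully into memory (bit-exact round trip)."""
    with PacketReader(path) as reader:
        return reader.load()


def open_packet(path: str | os.PathLike) -> PacketReader:
    """Open a packet for lazy, tile-granular access."""
    return PacketReader(path)
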