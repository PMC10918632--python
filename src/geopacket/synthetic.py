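"""Deterministic synthetic fixtures: packets, sample sheets, paired data.

Nothing in this package downloads real rasters; instead this module
builds packets whose ground truth is known in closed form, sample sheets
with controlled corruption mirroring the failure modes seen in public
archives (null-island placeholders, out-of-range magnitudes, malformed
strings the legacy validator still accepts, INSDC missing-value terms,
and a single over-reported location), and density/diversity pairs with a
tunable population Spearman correlation via a Gaussian copula.

All randomness flows through ``numpy.random.default_rng(seed)`` (the
PCG64 generator), so identical specs produce bit-identical outputs on any
platform.  Raster recipes are integer- or closed-form-valued so no
floating-point accumulation order can perturb them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np

from .categories import CategoryTable, STANDARD_TABLES
from .datapacket import (
    DEFAULT_NODATA_CATEGORICAL,
    DEFAULT_NODATA_CONTINUOUS,
    DataPacket,
    Layer,
    LayerKind,
    LayerMeta,
)
from .errors import BadParameter, BadRecipe
from .grid import GridSpec
from .query import SampleRecord
from .validate import Flag

_PLACEHOLDER_CITATION = """@misc{{synthetic_{name},
  title = {{Synthetic {name} layer (generated fixture)}},
  author = {{geopacket}},
  year = {{2024}},
  note = {{Deterministic synthetic raster; not a real data product}}
}}"""


# ---------------------------------------------------------------------------
# Layer recipes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LayerRecipe:
    """One synthetic layer.

    kinds:
      ``index_gradient``    continuous, value(row, col) = row*width + col
      ``category_blocks``   categorical, rectangular regions per code
      ``constant``          continuous constant value
      ``noise``             continuous i.i.d. Gaussian(mean, sd)
      ``country_checkerboard`` categorical checkerboard of country codes
    """

    feature_name: str
    recipe: Literal[
        "index_gradient", "category_blocks", "constant", "noise", "country_checkerboard"
    ]
    units: str = ""
    table: CategoryTable | None = None
    # category_blocks: list of (code, row0, row1, col0, col1), later wins
    blocks: tuple[tuple[int, int, int, int, int], ...] = ()
    background_code: int | None = None
    value: float = 0.0
    mean: float = 0.0
    sd: float = 1.0
    n_countries: int = 4
    checker_tile: int = 5
    nodata: float | None = None


@dataclass(frozen=True)
class CorruptionRates:
    """Fractions of a sheet to corrupt, one failure mode each; sum <= 1."""

    null_island: float = 0.0
    out_of_range: float = 0.0
    malformed: float = 0.0
    missing_vocab: float = 0.0
    frequent_cluster: float = 0.0

    def __post_init__(self) -> None:
        rates = [self.null_island, self.out_of_range, self.malformed,
                 self.missing_vocab, self.frequent_cluster]
        if any(not (0.0 <= r <= 1.0) for r in rates):
            raise BadParameter("corruption rates must lie in [0, 1]")
        if sum(rates) > 1.0 + 1e-12:
            raise BadParameter("corruption rates must sum to <= 1")


@dataclass(frozen=True)
class SyntheticSpec:
    seed: int
    grid: GridSpec
    layers: tuple[LayerRecipe, ...]
    corruption: CorruptionRates = field(default_factory=CorruptionRates)


def default_grid(width: int = 60, height: int = 40, tile_size: int = 16) -> GridSpec:
    """A 1-degree regional grid over Europe-ish longitudes/latitudes."""
    return GridSpec(
        origin_lon=-20.0, origin_lat=70.0, res_lon=1.0, res_lat=1.0,
        width=width, height=height, tile_size=tile_size,
    )


def _citation(name: str) -> str:
    return _PLACEHOLDER_CITATION.format(name=name)


def _build_layer(recipe: LayerRecipe, grid: GridSpec, rng: np.random.Generator
                 ) -> tuple[Layer, Callable[[int, int], float | int | None]]:
    """Materialize one recipe; returns the layer and a ground-truth closure
    mapping (row, col) to the expected value (None meaning nodata)."""
    h, w = grid.height, grid.width
    if recipe.recipe == "index_gradient":
        nodata = DEFAULT_NODATA_CONTINUOUS if recipe.nodata is None else recipe.nodata
        data = (np.arange(h, dtype=np.float64)[:, None] * w
                + np.arange(w, dtype=np.float64)[None, :])
        meta = LayerMeta(recipe.feature_name, LayerKind.CONTINUOUS, recipe.units or "index",
                         nodata, _citation(recipe.feature_name))
        truth = lambda r, c: float(r * w + c)
    elif recipe.recipe == "constant":
        nodata = DEFAULT_NODATA_CONTINUOUS if recipe.nodata is None else recipe.nodata
        data = np.full((h, w), recipe.value, dtype=np.float64)
        meta = LayerMeta(recipe.feature_name, LayerKind.CONTINUOUS, recipe.units,
                         nodata, _citation(recipe.feature_name))
        v = float(recipe.value)
        truth = lambda r, c: v
    elif recipe.recipe == "noise":
        nodata = DEFAULT_NODATA_CONTINUOUS if recipe.nodata is None else recipe.nodata
        data = rng.normal(recipe.mean, recipe.sd, size=(h, w))
        frozen = data.copy()
        meta = LayerMeta(recipe.feature_name, LayerKind.CONTINUOUS, recipe.units,
                         nodata, _citation(recipe.feature_name))
        truth = lambda r, c: float(frozen[r, c])
    elif recipe.recipe == "category_blocks":
        table = recipe.table or STANDARD_TABLES.get(recipe.feature_name)
        if table is None:
            raise BadRecipe(f"category_blocks layer {recipe.feature_name!r} needs a table")
        nodata = DEFAULT_NODATA_CATEGORICAL if recipe.nodata is None else recipe.nodata
        background = recipe.background_code
        for code, *_ in recipe.blocks:
            if code not in table:
                raise BadRecipe(f"code {code} absent from {recipe.feature_name!r} table")
        if background is not None and background not in table:
            raise BadRecipe(f"background code {background} absent from table")
        fill = int(nodata) if background is None else background
        data = np.full((h, w), fill, dtype=np.uint8)
        for code, r0, r1, c0, c1 in recipe.blocks:
            data[r0:r1, c0:c1] = code
        frozen_blocks = recipe.blocks
        def truth(r, c, _blocks=frozen_blocks, _fill=fill, _nd=int(nodata)):
            val = _fill
            for code, r0, r1, c0, c1 in _blocks:
                if r0 <= r < r1 and c0 <= c < c1:
                    val = code
            return None if val == _nd else val
        meta = LayerMeta(recipe.feature_name, LayerKind.CATEGORICAL, "class",
                         nodata, _citation(recipe.feature_name), category_table=table)
    elif recipe.recipe == "country_checkerboard":
        nodata = DEFAULT_NODATA_CATEGORICAL if recipe.nodata is None else recipe.nodata
        n = recipe.n_countries
        table = recipe.table or CategoryTable(
            {i + 1: (chr(ord("A") + i), f"Country {chr(ord('A') + i)}") for i in range(n)}
        )
        tile = recipe.checker_tile
        rows = np.arange(h)[:, None] // tile
        cols = np.arange(w)[None, :] // tile
        data = ((rows + cols) % n + 1).astype(np.uint8)
        meta = LayerMeta(recipe.feature_name, LayerKind.CATEGORICAL, "country",
                         nodata, _citation(recipe.feature_name), category_table=table)
        truth = lambda r, c, _t=tile, _n=n: int((r // _t + c // _t) % _n + 1)
    else:  # pragma: no cover - recipe literal exhausts cases
        raise BadRecipe(f"unknown recipe {recipe.recipe!r}")
    layer = Layer(meta=meta, data=data)
    layer.validate_categories()
    return layer, truth


def make_packet(spec: SyntheticSpec) -> tuple[DataPacket, dict[str, Callable]]:
    """Build a packet from recipes; also return per-feature ground-truth
    closures so tests can predict any pixel value without the raster."""
    rng = np.random.default_rng(spec.seed)
    layers = []
    truths: dict[str, Callable] = {}
    for recipe in spec.layers:
        layer, truth = _build_layer(recipe, spec.grid, rng)
        layers.append(layer)
        truths[recipe.feature_name] = truth
    packet = DataPacket(
        packet_version=f"synthetic-seed{spec.seed}",
        grid=spec.grid,
        layers=layers,
        changelog=[(f"synthetic-seed{spec.seed}", "synthetic fixture packet")],
    )
    return packet, truths


# ---------------------------------------------------------------------------
# Sample sheets with controlled corruption
# ---------------------------------------------------------------------------

#: Out-of-range magnitudes of the kind archives actually contain.
_OUT_OF_RANGE_VALUES = ("645209.099648", "11500.859", "99999.9", "-731.25")
#: Strings the legacy validator accepts but the strict validators reject.
_MALFORMED_VALUES = ("1234567890a12345678", "12x45", "55.5#1", "7_3")
_MISSING_TERMS = ("not applicable", "not collected", "not provided", "restricted access")


def _fmt(value: float) -> str:
    return f"{value:.6f}"


def make_sheet(
    spec: SyntheticSpec, n: int, min_count: int = 50, min_fraction: float = 0.001
) -> tuple[list[SampleRecord], dict[str, set[Flag]]]:
    """Draw ``n`` records uniform over the grid, then corrupt per rates.

    Returns the records plus a truth table mapping sample_id to the exact
    flag set :func:`geopacket.validate.validate_sheet` should raise for it
    under the same frequent-location thresholds.  Corruption modes are
    applied to disjoint record subsets, so each corrupted record carries
    exactly its intended failure.
    """
    if n < 0:
        raise BadParameter("n must be >= 0")
    rng = np.random.default_rng(spec.seed + 1)
    g = spec.grid
    lats = g.south + rng.random(n) * (g.origin_lat - g.south)
    lons = g.origin_lon + rng.random(n) * (g.east - g.origin_lon)

    records: list[SampleRecord] = []
    truth: dict[str, set[Flag]] = {}
    rates = spec.corruption
    counts = {
        "null_island": int(round(rates.null_island * n)),
        "out_of_range": int(round(rates.out_of_range * n)),
        "malformed": int(round(rates.malformed * n)),
        "missing_vocab": int(round(rates.missing_vocab * n)),
        "frequent_cluster": int(round(rates.frequent_cluster * n)),
    }
    order = rng.permutation(n)
    assignment: dict[int, str] = {}
    pos = 0
    for mode, k in counts.items():
        for idx in order[pos:pos + k]:
            assignment[int(idx)] = mode
        pos += k

    cluster_lat, cluster_lon = _fmt(53.4), _fmt(-3.0)  # fixed over-reported spot
    for i in range(n):
        sid = f"S{i:06d}"
        mode = assignment.get(i)
        lat_s, lon_s = _fmt(lats[i]), _fmt(lons[i])
        flags: set[Flag] = set()
        if mode == "null_island":
            lat_s, lon_s = "0.00", "0.00"
            flags.add(Flag.NULL_ISLAND_PLACEHOLDER)
        elif mode == "out_of_range":
            choice = _OUT_OF_RANGE_VALUES[int(rng.integers(len(_OUT_OF_RANGE_VALUES)))]
            if rng.random() < 0.5:
                lat_s = choice
                flags.add(Flag.LAT_OUT_OF_RANGE)
            else:
                lon_s = "645209.099648"
                flags.add(Flag.LON_OUT_OF_RANGE)
        elif mode == "malformed":
            choice = _MALFORMED_VALUES[int(rng.integers(len(_MALFORMED_VALUES)))]
            if rng.random() < 0.5:
                lat_s = choice
                flags.add(Flag.INVALID_LAT_SYNTAX)
            else:
                lon_s = choice
                flags.add(Flag.INVALID_LON_SYNTAX)
        elif mode == "missing_vocab":
            term = _MISSING_TERMS[int(rng.integers(len(_MISSING_TERMS)))]
            lat_s = lon_s = term
            flags.add(Flag.MISSING_VALUE_VOCAB)
        elif mode == "frequent_cluster":
            lat_s, lon_s = cluster_lat, cluster_lon
        records.append(SampleRecord(sample_id=sid, latitude=lat_s, longitude=lon_s))
        truth[sid] = flags

    # Frequent-location flags depend on final tallies; compute them the way
    # the validator will, against the same thresholds.
    from collections import Counter
    tally: Counter[tuple[float, float]] = Counter()
    parsed: dict[str, tuple[float, float] | None] = {}
    from .validate import parse_coordinate
    for rec in records:
        lat = parse_coordinate(rec.latitude)
        lon = parse_coordinate(rec.longitude)
        parsed[rec.sample_id] = None if lat is None or lon is None else (lat, lon)
        if parsed[rec.sample_id] is not None:
            tally[parsed[rec.sample_id]] += 1
    frequent = {
        loc for loc, c in tally.items() if c >= min_count and c >= min_fraction * n
    }
    for rec in records:
        loc = parsed[rec.sample_id]
        if loc is not None and loc in frequent:
            truth[rec.sample_id].add(Flag.FREQUENT_LOCATION)
    return records, truth


# ---------------------------------------------------------------------------
# Density / diversity pairs
# ---------------------------------------------------------------------------

def make_density_diversity(
    n: int, rho_target: float, seed: int
) -> tuple[list[tuple[float, float]], float]:
    """Paired (population density, diversity) values with tunable dependence.

    Latent ranks come from a Gaussian copula whose Pearson correlation
    ``r = 2·sin(pi·rho_target/6)`` gives population Spearman correlation
    exactly ``rho_target``.  The density margin is mapped through an
    exponential (lognormal-like) transform to a heavy-tailed persons/km²
    scale; Spearman correlation is invariant under such strictly monotone
    maps.  Returns the pairs and ``oracle_rho``, a brute-force Spearman
    computed on the realized draw by exhaustive rank assignment.
    """
    if n < 10:
        raise BadParameter("n must be >= 10")
    if not (0.0 < rho_target < 1.0):
        raise BadParameter("rho_target must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    r = 2.0 * math.sin(math.pi * rho_target / 6.0)
    z1 = rng.standard_normal(n)
    z2 = r * z1 + math.sqrt(1.0 - r * r) * rng.standard_normal(n)
    density = np.exp(5.0 + 1.5 * z1)          # heavy-tailed, persons/km^2 scale
    diversity = 3.0 + 0.8 * z2                # Shannon-index-like scale
    pairs = list(zip(density.tolist(), diversity.tolist()))
    oracle_rho = _brute_force_spearman(density, diversity)
    return pairs, oracle_rho


def _brute_force_spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Independent O(n²) Spearman: average ranks by pairwise counting,
    then the Pearson formula written out longhand."""
    def ranks(v: np.ndarray) -> np.ndarray:
        out = np.empty(len(v))
        for i, vi in enumerate(v):
            less = int((v < vi).sum())
            equal = int((v == vi).sum())
            out[i] = less + (equal + 1) / 2.0
        return out

    rx, ry = ranks(x), ranks(y)
    mx, my = rx.mean(), ry.mean()
    num = float(((rx - mx) * (ry - my)).sum())
    den = math.sqrt(float(((rx - mx) ** 2).sum()) * float(((ry - my) ** 2).sum()))
    return num / den
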