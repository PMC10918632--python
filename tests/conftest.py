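import numpy as np
import pytest

from geopacket import (
    CategoryTable,
    DataPacket,
    GridSpec,
    Layer,
    LayerKind,
    LayerMeta,
    LayerRecipe,
    SyntheticSpec,
    default_grid,
    make_packet,
)


def bib(key: str) -> str:
    return f"@misc{{{key},\n  title = {{Source {key}}},\n  year = {{2024}}\n}}"


@pytest.fixture
def global_1deg_grid() -> GridSpec:
    return GridSpec(
        origin_lon=-180.0, origin_lat=90.0, res_lon=1.0, res_lat=1.0,
        width=360, height=180, tile_size=32,
    )


@pytest.fixture
def two_layer_spec() -> SyntheticSpec:
    """Rurality split water/urban down the middle + an index-gradient
    population layer, on the default regional grid."""
    return SyntheticSpec(
        seed=7,
        grid=default_grid(),
        layers=(
            LayerRecipe(
                "rurality", "category_blocks",
                blocks=((10, 0, 40, 0, 30), (30, 0, 40, 30, 60)),
            ),
            LayerRecipe("population_density", "index_gradient", units="persons/km^2"),
        ),
    )


@pytest.fixture
def two_layer_packet(two_layer_spec):
    packet, truths = make_packet(two_layer_spec)
    return packet, truths


def random_packet(rng: np.random.Generator) -> DataPacket:
    """A randomized small packet: random grid, tile size, layer count."""
    width = int(rng.integers(8, 70))
    height = int(rng.integers(8, 50))
    res = float(rng.choice([0.25, 0.5, 1.0]))
    max_origin_lon = 180.0 - width * res
    max_origin_lat_span = height * res
    origin_lon = float(rng.uniform(-180.0, max_origin_lon))
    origin_lat = float(rng.uniform(-90.0 + max_origin_lat_span, 90.0))
    tile_size = int(rng.choice([8, 16, 32, 256]))
    grid = GridSpec(
        origin_lon=origin_lon, origin_lat=origin_lat, res_lon=res, res_lat=res,
        width=width, height=height, tile_size=tile_size,
    )
    layers = []
    n_layers = int(rng.integers(1, 4))
    for i in range(n_layers):
        if rng.random() < 0.5:
            codes = list(range(1, int(rng.integers(2, 6)) + 1))
            table = CategoryTable({c: (f"c{c}", f"class {c}") for c in codes})
            data = rng.choice(codes + [255], size=(height, width)).astype(np.uint8)
            meta = LayerMeta(f"cat{i}", LayerKind.CATEGORICAL, "class", 255,
                             bib(f"cat{i}"), category_table=table)
        else:
            data = rng.normal(size=(height, width))
            data[rng.random(data.shape) < 0.05] = -9999.0
            meta = LayerMeta(f"cont{i}", LayerKind.CONTINUOUS, "units", -9999.0,
                             bib(f"cont{i}"))
        layers.append(Layer(meta=meta, data=data))
    return DataPacket(
        packet_version="vtest", grid=grid, layers=layers,
        changelog=[("vtest", "randomized test packet")],
    )


def random_inbounds_points(grid: GridSpec, n: int, rng: np.random.Generator):
    lats = grid.south + rng.random(n) * (grid.origin_lat - grid.south)
    lons = grid.origin_lon + rng.random(n) * (grid.east - grid.origin_lon)
    # keep strictly inside to avoid edge-of-grid exclusions
    lats = np.clip(lats, grid.south + 1e-6, grid.origin_lat - 1e-6)
    lons = np.clip(lons, grid.origin_lon + 1e-6, grid.east - 1e-6)
    return lats, lons
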