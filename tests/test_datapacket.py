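import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from geopacket import (
    CategoryTable,
    DataPacket,
    GridSpec,
    Layer,
    LayerKind,
    LayerMeta,
    LayerSource,
    build_packet,
    emit_citations,
    packets_equal,
    read_packet,
    with_new_version,
    write_packet,
)
from geopacket.errors import (
    CitationError,
    CorruptPacket,
    CRSMismatch,
    DuplicateLayer,
    EmptyIntersection,
    GridMismatch,
)
from conftest import bib, random_packet


def small_grid(res=1.0, width=4, height=4, tile_size=16):
    return GridSpec(origin_lon=0.0, origin_lat=4.0 * res / 1.0, res_lon=res, res_lat=res,
                    width=width, height=height, tile_size=tile_size)


def cat_meta(name="landcover", codes=(1, 2, 3)):
    table = CategoryTable({c: (f"c{c}", f"class {c}") for c in codes})
    return LayerMeta(name, LayerKind.CATEGORICAL, "class", 255, bib(name), category_table=table)


class TestBuildPacket:
    def test_identity_resampling_categorical(self):
        grid = small_grid()
        data = np.array([[1, 2, 3, 1]] * 4, dtype=np.uint8)
        src = LayerSource(data=data, grid=grid, meta=cat_meta())
        packet = build_packet([src], grid)
        np.testing.assert_array_equal(packet.layers[0].data, data)

    def test_mean_coarsening_matches_block_mean_oracle(self):
        # 4x4 source at 0.5 deg -> 2x2 target at 1.0 deg
        src_grid = GridSpec(origin_lon=0.0, origin_lat=2.0, res_lon=0.5, res_lat=0.5,
                            width=4, height=4, tile_size=16)
        tgt_grid = GridSpec(origin_lon=0.0, origin_lat=2.0, res_lon=1.0, res_lat=1.0,
                            width=2, height=2, tile_size=16)
        data = np.array(
            [[1.0, 2.0, 1.0, 2.0],
             [3.0, 4.0, 3.0, 4.0],
             [1.0, 2.0, 1.0, 2.0],
             [3.0, 4.0, 3.0, 4.0]]
        )
        meta = LayerMeta("pop", LayerKind.CONTINUOUS, "x", -9999.0, bib("pop"))
        packet = build_packet([LayerSource(data=data, grid=src_grid, meta=meta)], tgt_grid)
        # brute-force oracle: mean over the 2x2 source block under each target pixel
        oracle = np.empty((2, 2))
        for r in range(2):
            for c in range(2):
                oracle[r, c] = data[2 * r:2 * r + 2, 2 * c:2 * c + 2].mean()
        np.testing.assert_allclose(packet.layers[0].data, oracle)
        assert oracle[0, 0] == 2.5

    def test_mean_coarsening_of_constant_is_constant(self):
        src_grid = GridSpec(origin_lon=0.0, origin_lat=2.0, res_lon=0.5, res_lat=0.5,
                            width=4, height=4, tile_size=16)
        tgt_grid = GridSpec(origin_lon=0.0, origin_lat=2.0, res_lon=1.0, res_lat=1.0,
                            width=2, height=2, tile_size=16)
        meta = LayerMeta("pop", LayerKind.CONTINUOUS, "x", -9999.0, bib("pop"))
        packet = build_packet(
            [LayerSource(data=np.full((4, 4), 7.25), grid=src_grid, meta=meta)], tgt_grid
        )
        np.testing.assert_array_equal(packet.layers[0].data, np.full((2, 2), 7.25))

    def test_nodata_propagates_through_mean(self):
        src_grid = GridSpec(origin_lon=0.0, origin_lat=2.0, res_lon=0.5, res_lat=0.5,
                            width=4, height=4, tile_size=16)
        tgt_grid = GridSpec(origin_lon=0.0, origin_lat=2.0, res_lon=1.0, res_lat=1.0,
                            width=2, height=2, tile_size=16)
        data = np.full((4, 4), -9999.0)
        data[0, 0] = 4.0  # only one valid pixel in the top-left block
        meta = LayerMeta("pop", LayerKind.CONTINUOUS, "x", -9999.0, bib("pop"))
        packet = build_packet([LayerSource(data=data, grid=src_grid, meta=meta)], tgt_grid)
        out = packet.layers[0].data
        assert out[0, 0] == 4.0  # mean over the single non-nodata pixel
        assert out[0, 1] == -9999.0 and out[1, 0] == -9999.0 and out[1, 1] == -9999.0

    def test_categorical_refinement_is_nearest(self):
        src_grid = GridSpec(origin_lon=0.0, origin_lat=2.0, res_lon=1.0, res_lat=1.0,
                            width=2, height=2, tile_size=16)
        tgt_grid = GridSpec(origin_lon=0.0, origin_lat=2.0, res_lon=0.5, res_lat=0.5,
                            width=4, height=4, tile_size=16)
        data = np.array([[1, 2], [3, 1]], dtype=np.uint8)
        packet = build_packet(
            [LayerSource(data=data, grid=src_grid, meta=cat_meta())], tgt_grid
        )
        np.testing.assert_array_equal(packet.layers[0].data, np.kron(data, np.ones((2, 2), np.uint8)))

    def test_crs_mismatch(self):
        grid = small_grid()
        bad = GridSpec(origin_lon=0.0, origin_lat=4.0, res_lon=1.0, res_lat=1.0,
                       width=4, height=4, crs_id="EPSG:3857", tile_size=16)
        src = LayerSource(data=np.ones((4, 4), np.uint8), grid=bad, meta=cat_meta())
        with pytest.raises(CRSMismatch):
            build_packet([src], grid)

    def test_empty_intersection(self):
        grid = small_grid()
        far = GridSpec(origin_lon=100.0, origin_lat=4.0, res_lon=1.0, res_lat=1.0,
                       width=4, height=4, tile_size=16)
        src = LayerSource(data=np.ones((4, 4), np.uint8), grid=far, meta=cat_meta())
        with pytest.raises(EmptyIntersection):
            build_packet([src], grid)

    def test_duplicate_feature_name(self):
        grid = small_grid()
        src = LayerSource(data=np.ones((4, 4), np.uint8), grid=grid, meta=cat_meta())
        with pytest.raises(DuplicateLayer):
            build_packet([src, src], grid)


class TestPacketRoundTrip:
    def test_two_layer_round_trip(self, two_layer_packet, tmp_path):
        packet, _ = two_layer_packet
        write_packet(packet, tmp_path)
        assert packets_equal(read_packet(tmp_path), packet)

    def test_six_layer_order_preserved(self, tmp_path):
        names = ["koppen", "rurality", "population_density", "co2", "no2", "deprivation"]
        grid = small_grid()
        layers = []
        for i, name in enumerate(names):
            meta = LayerMeta(name, LayerKind.CONTINUOUS, "u", -9999.0, bib(name))
            layers.append(Layer(meta=meta, data=np.full((4, 4), float(i))))
        packet = DataPacket("v2", grid, layers, [("v2", "six layers")])
        write_packet(packet, tmp_path)
        assert read_packet(tmp_path).feature_names == names

    def test_missing_layer_file_is_corrupt(self, two_layer_packet, tmp_path):
        packet, _ = two_layer_packet
        write_packet(packet, tmp_path)
        (tmp_path / "layers" / "rurality.tif").unlink()
        with pytest.raises(CorruptPacket):
            read_packet(tmp_path)

    def test_manifest_grid_tamper_is_mismatch(self, two_layer_packet, tmp_path):
        packet, _ = two_layer_packet
        write_packet(packet, tmp_path)
        manifest = tmp_path / "manifest.txt"
        text = manifest.read_text().replace(f"width: {packet.grid.width}", "width: 100")
        manifest.write_text(text)
        with pytest.raises(GridMismatch):
            read_packet(tmp_path)

    def test_changelog_append_only(self, two_layer_packet, tmp_path):
        packet, _ = two_layer_packet
        v2 = with_new_version(packet, "v2", "updated sources")
        write_packet(v2, tmp_path)
        back = read_packet(tmp_path)
        assert back.changelog[0] == packet.changelog[0]
        assert back.changelog[-1] == ("v2", "updated sources")

    @given(seed=st.integers(0, 2**32 - 1))
    @settings(max_examples=15, deadline=None)
    def test_randomized_round_trip_bit_exact(self, seed, tmp_path_factory):
        """read(write(p)) == p over random grids, tile sizes, layer mixes."""
        rng = np.random.default_rng(seed)
        packet = random_packet(rng)
        out = tmp_path_factory.mktemp("pkt")
        write_packet(packet, out)
        assert packets_equal(read_packet(out), packet)


class TestCitations:
    def test_three_distinct_entries(self, tmp_path):
        grid = small_grid()
        layers = [
            Layer(meta=LayerMeta(f"f{i}", LayerKind.CONTINUOUS, "u", -9999.0, bib(f"k{i}")),
                  data=np.zeros((4, 4)))
            for i in range(3)
        ]
        doc = emit_citations(DataPacket("v1", grid, layers, [("v1", "x")]))
        assert doc.count("@misc") == 3

    def test_shared_key_deduplicated(self):
        grid = small_grid()
        layers = [
            Layer(meta=LayerMeta("a", LayerKind.CONTINUOUS, "u", -9999.0, bib("shared")),
                  data=np.zeros((4, 4))),
            Layer(meta=LayerMeta("b", LayerKind.CONTINUOUS, "u", -9999.0, bib("shared")),
                  data=np.zeros((4, 4))),
        ]
        doc = emit_citations(DataPacket("v1", grid, layers, [("v1", "x")]))
        assert doc.count("@misc") == 1

    def test_empty_citation_names_layer(self):
        grid = small_grid()
        layers = [
            Layer(meta=LayerMeta("nocite", LayerKind.CONTINUOUS, "u", -9999.0, ""),
                  data=np.zeros((4, 4))),
        ]
        with pytest.raises(CitationError, match="nocite"):
            emit_citations(DataPacket("v1", grid, layers, [("v1", "x")]))

    def test_unbalanced_citation_rejected(self):
        grid = small_grid()
        layers = [
            Layer(meta=LayerMeta("bad", LayerKind.CONTINUOUS, "u", -9999.0,
                                 "@misc{k, title = {unclosed}"),
                  data=np.zeros((4, 4))),
        ]
        with pytest.raises(CitationError):
            emit_citations(DataPacket("v1", grid, layers, [("v1", "x")]))


class TestLayerInvariants:
    def test_categorical_values_must_be_coded(self):
        meta = cat_meta(codes=(1, 2))
        layer = Layer(meta=meta, data=np.array([[1, 2], [9, 255]], dtype=np.uint8))
        with pytest.raises(ValueError, match=r"\[9\]"):
            layer.validate_categories()

    def test_categorical_needs_table(self):
        with pytest.raises(ValueError):
            LayerMeta("x", LayerKind.CATEGORICAL, "c", 255, bib("x"))
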