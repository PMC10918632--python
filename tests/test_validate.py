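import random

import pytest
from hypothesis import given, settings, strategies as st

from geopacket import (
    Flag,
    LayerRecipe,
    SampleRecord,
    SyntheticSpec,
    ValidationConfig,
    check_country,
    check_water_biome,
    default_grid,
    detect_placeholders,
    make_packet,
    validate_latitude,
    validate_legacy,
    validate_longitude,
    validate_sheet,
)
from geopacket.errors import UnknownCountry
from geopacket.query import annotate


class TestLegacyValidator:
    """The archive's historical single-field pattern, flaws reproduced."""

    @pytest.mark.parametrize("text", ["1234567890a12345678", "12345", "645209.099648",
                                      "+12.5", "-0.000001", "90.12345678"])
    def test_accepts(self, text):
        assert validate_legacy(text)

    @pytest.mark.parametrize("text", ["abc", "", "12.123456789", "1.2.3", "not collected"])
    def test_rejects(self, text):
        assert not validate_legacy(text)


class TestProposedValidators:
    @pytest.mark.parametrize("text,ok", [
        ("645209.099648", False),   # magnitude far beyond WGS84
        ("90.0", True),
        ("90", True),
        ("-90.000", True),
        ("90.1", False),
        ("90.0000001", False),
        ("-45.1234567", True),      # any decimal granularity
        ("0", True),
        ("0.00", True),
        ("1e2", False),             # no exponent notation
        (" 45", False),             # no whitespace
        ("45.", False),
        ("not collected", False),
    ])
    def test_latitude(self, text, ok):
        assert validate_latitude(text) is ok

    @pytest.mark.parametrize("text,ok", [
        ("11500.859", False),
        ("180.0", True),
        ("-180.000", True),
        ("180.1", False),
        ("179.9999999", True),
        ("-100.5", True),
        ("99.99", True),
        ("181", False),
    ])
    def test_longitude(self, text, ok):
        assert validate_longitude(text) is ok

    @staticmethod
    def _oracle_plain_decimal(text: str) -> float | None:
        """Character-scan parse of an optionally signed plain decimal,
        independent of any regex."""
        s = text
        if s and s[0] in "+-":
            s = s[1:]
        if "." in s:
            whole, _, frac = s.partition(".")
            if not (whole and frac and whole.isdigit() and frac.isdigit()):
                return None
            return float(text)
        if not s.isdigit() or not s:
            return None
        return float(text)

    @given(
        sign=st.sampled_from(["", "+", "-"]),
        body=st.text(alphabet="0123456789.e ", min_size=1, max_size=12),
    )
    @settings(max_examples=2000, deadline=None)
    def test_validators_match_parse_oracle(self, sign, body):
        """validate_latitude(text) <=> (plain decimal AND |value| <= 90);
        longitude likewise with 180."""
        text = sign + body
        value = self._oracle_plain_decimal(text)
        assert validate_latitude(text) is (value is not None and abs(value) <= 90.0)
        assert validate_longitude(text) is (value is not None and abs(value) <= 180.0)

    @given(
        whole=st.integers(0, 10**9),
        frac=st.one_of(st.none(), st.integers(0, 10**8)),
        sign=st.sampled_from(["", "+", "-"]),
    )
    @settings(max_examples=500, deadline=None)
    def test_legacy_superset_on_digit_strings(self, whole, frac, sign):
        """On digit-only decimals with <= 9 fraction digits, everything the
        strict validators accept, the legacy pattern also accepts — and the
        converse fails (the legacy pattern is strictly more permissive)."""
        text = sign + str(whole) + ("" if frac is None else f".{frac}")
        if len(text.partition(".")[2]) > 9:
            return
        if validate_latitude(text) or validate_longitude(text):
            assert validate_legacy(text)

    def test_legacy_strictly_more_permissive(self):
        for text in ["645209.099648", "1234567890a12345678"]:
            assert validate_legacy(text)
            assert not validate_latitude(text) and not validate_longitude(text)


class TestDetectPlaceholders:
    def test_null_island_exact_zero(self):
        records = [
            SampleRecord("a", "0.00", "0.0000"),
            SampleRecord("b", "0.00", "0.01"),
            SampleRecord("c", "10.0", "10.0"),
        ]
        report = detect_placeholders(records, min_count=2, min_fraction=0.001)
        assert report.null_island_ids == ["a"]

    def test_distinct_locations_not_frequent(self):
        records = [SampleRecord(f"s{i}", f"{i}.0", f"{i}.0") for i in range(10)]
        report = detect_placeholders(records, min_count=2, min_fraction=0.001)
        assert report.frequent_locations == []

    def test_large_cluster_found_with_count(self):
        records = [SampleRecord(f"r{i}", "53.4", "-3.0") for i in range(1000)]
        records += [SampleRecord(f"u{i}", f"{i % 50}.5", "7.0") for i in range(10)]
        report = detect_placeholders(records, min_count=100, min_fraction=0.5)
        assert report.frequent_locations == [(53.4, -3.0, 1000)]

    def test_unparseable_reported_separately(self):
        records = [SampleRecord("ok", "1.0", "2.0"), SampleRecord("bad", "x", "2.0")]
        report = detect_placeholders(records, min_count=2, min_fraction=0.001)
        assert report.unparseable_ids == ["bad"]

    def test_shuffle_invariance(self):
        records = [SampleRecord(f"s{i}", "10.0" if i % 3 else "0.00",
                                "20.0" if i % 3 else "0.00") for i in range(60)]
        base = detect_placeholders(records, min_count=5, min_fraction=0.01)
        shuffled = records[:]
        random.Random(0).shuffle(shuffled)
        other = detect_placeholders(shuffled, min_count=5, min_fraction=0.01)
        assert sorted(base.null_island_ids) == sorted(other.null_island_ids)
        assert base.frequent_locations == other.frequent_locations


@pytest.fixture
def consistency_packet():
    """Rurality water/urban halves plus a 2-country checkerboard."""
    spec = SyntheticSpec(
        seed=3,
        grid=default_grid(),
        layers=(
            LayerRecipe("rurality", "category_blocks",
                        blocks=((10, 0, 40, 0, 30), (30, 0, 40, 30, 60))),
            LayerRecipe("country", "country_checkerboard", n_countries=2, checker_tile=20),
        ),
    )
    packet, truths = make_packet(spec)
    return packet, truths


class TestWaterBiome:
    def _annotation_at(self, packet, row, col):
        lat, lon = packet.grid.pixel_center(row, col)
        return annotate([SampleRecord("s", f"{lat:.6f}", f"{lon:.6f}")], packet)[0]

    def test_water_point_terrestrial_biome_conflicts(self, consistency_packet):
        packet, _ = consistency_packet
        ann = self._annotation_at(packet, 5, 5)  # water half
        assert check_water_biome(ann, "Human-gut") is True

    def test_water_point_river_biome_consistent(self, consistency_packet):
        packet, _ = consistency_packet
        ann = self._annotation_at(packet, 5, 5)
        assert check_water_biome(ann, "Large river biome") is False

    def test_land_point_never_conflicts(self, consistency_packet):
        packet, _ = consistency_packet
        ann = self._annotation_at(packet, 5, 45)  # urban half
        assert check_water_biome(ann, "Human-gut") is False

    def test_missing_rurality_no_determination(self, consistency_packet):
        packet, _ = consistency_packet
        ann = self._annotation_at(packet, 5, 5)
        stripped = type(ann)(sample_id=ann.sample_id,
                             values={"rurality": None}, status=ann.status)
        assert check_water_biome(stripped, "Human-gut") is False


class TestCountryCheck:
    def test_matching_report_no_conflict(self, consistency_packet):
        packet, truths = consistency_packet
        lat, lon = packet.grid.pixel_center(0, 0)
        code = truths["country"](0, 0)
        name = packet.layer("country").meta.category_table.short_label(code)
        assert check_country(packet, lat, lon, name) is False

    def test_wrong_report_conflicts(self, consistency_packet):
        packet, truths = consistency_packet
        lat, lon = packet.grid.pixel_center(0, 0)
        code = truths["country"](0, 0)
        other = "B" if code == 1 else "A"
        assert check_country(packet, lat, lon, other) is True

    def test_nodata_point_no_determination(self, consistency_packet):
        packet, _ = consistency_packet
        layer = packet.layer("country")
        layer.data[0, 0] = int(layer.meta.nodata)  # open ocean
        lat, lon = packet.grid.pixel_center(0, 0)
        assert check_country(packet, lat, lon, "A") is False

    def test_missing_vocab_report_no_determination(self, consistency_packet):
        packet, _ = consistency_packet
        lat, lon = packet.grid.pixel_center(0, 0)
        assert check_country(packet, lat, lon, "not provided") is False

    def test_unknown_country_distinct_from_conflict(self, consistency_packet):
        packet, _ = consistency_packet
        lat, lon = packet.grid.pixel_center(0, 0)
        with pytest.raises(UnknownCountry):
            check_country(packet, lat, lon, "Atlantis")


class TestValidateSheet:
    def test_out_of_range_latitude_path(self):
        records = [SampleRecord("s1", "645209.099648", "0.0")]
        report = validate_sheet(records)
        assert report.per_record["s1"] == {Flag.LAT_OUT_OF_RANGE}

    def test_malformed_latitude_path(self):
        records = [SampleRecord("s1", "1234567890a12345678", "0.0")]
        report = validate_sheet(records)
        assert report.per_record["s1"] == {Flag.INVALID_LAT_SYNTAX}

    def test_syntax_and_range_never_cooccur(self):
        for text in ["645209.099648", "1234567890a12345678", "90.1", "abc", "12.3.4"]:
            report = validate_sheet([SampleRecord("s", text, "0.0")])
            flags = report.per_record["s"]
            assert not ({Flag.LAT_OUT_OF_RANGE, Flag.INVALID_LAT_SYNTAX} <= flags)

    def test_missing_vocab_suppresses_syntax_flags(self):
        records = [SampleRecord("s1", "not collected", "not collected")]
        report = validate_sheet(records)
        assert report.per_record["s1"] == {Flag.MISSING_VALUE_VOCAB}

    def test_clean_sheet_no_findings(self):
        records = [SampleRecord(f"s{i}", f"{10 + i}.25", f"{-3 - i}.5") for i in range(5)]
        report = validate_sheet(records)
        assert all(not flags for flags in report.per_record.values())
        assert all(n == 0 for n in report.dataset_stats.values())

    def test_dataset_stats_equal_per_record_tally(self):
        records = [
            SampleRecord("a", "0.00", "0.00"),
            SampleRecord("b", "99999.9", "12x45"),
            SampleRecord("c", "not provided", "7.0"),
            SampleRecord("d", "45.0", "45.0"),
        ]
        report = validate_sheet(records)
        tally = {flag: 0 for flag in Flag}
        for flags in report.per_record.values():
            for flag in flags:
                tally[flag] += 1
        assert report.dataset_stats == tally

    def test_layer_checks_with_packet(self, consistency_packet):
        packet, _ = consistency_packet
        lat, lon = packet.grid.pixel_center(5, 5)  # water, country code exists
        records = [
            SampleRecord("wet", f"{lat:.6f}", f"{lon:.6f}",
                         extras={"Environment Biome": "Human-gut"}),
            SampleRecord("dry", f"{lat:.6f}", f"{lon:.6f}",
                         extras={"Environment Biome": "Ocean water"}),
        ]
        report = validate_sheet(records, packet)
        assert Flag.ON_WATER_BIOME_CONFLICT in report.per_record["wet"]
        assert Flag.ON_WATER_BIOME_CONFLICT not in report.per_record["dry"]

    def test_country_mismatch_with_packet(self, consistency_packet):
        packet, truths = consistency_packet
        lat, lon = packet.grid.pixel_center(0, 0)
        code = truths["country"](0, 0)
        table = packet.layer("country").meta.category_table
        right = table.short_label(code)
        wrong = "B" if right == "A" else "A"
        records = [
            SampleRecord("good", f"{lat:.6f}", f"{lon:.6f}", extras={"country": right}),
            SampleRecord("bad", f"{lat:.6f}", f"{lon:.6f}", extras={"country": wrong}),
        ]
        report = validate_sheet(records, packet)
        assert Flag.COUNTRY_MISMATCH not in report.per_record["good"]
        assert Flag.COUNTRY_MISMATCH in report.per_record["bad"]
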