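"""Coordinate and metadata QC for sample sheets.

Public sequence archives have historically validated latitude/longitude
fields with a single permissive pattern whose unescaped ``.`` acts as a
wildcard, so strings like ``1234567890a12345678`` pass and magnitudes far
outside WGS84 (``645209.099648``) are accepted.  This module reproduces
that legacy validator exactly (to demonstrate the flaw), implements strict
per-axis replacements that bound latitude to ±90.0 and longitude to
±180.0 at any decimal granularity, and layers dataset-level checks on
top: null-island placeholders (0.00N 0.00E), suspiciously frequent
locations, water-vs-biome conflicts, country-vs-coordinate conflicts, and
the INSDC controlled vocabulary for intentionally missing values.

Per-record findings are flags, never rejections: every input record is
carried through with its flag set, and dataset statistics are exact
tallies of the per-record flags.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import TYPE_CHECKING, Iterable

from .errors import InputError, UnknownCountry

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .datapacket import DataPacket
    from .query import AnnotationRecord, SampleRecord

# Legacy archive pattern, reproduced verbatim including the unescaped "."
# wildcard that lets a non-digit through and the missing magnitude bound.
LEGACY_PATTERN = r"^[+-]?[0-9]+.?[0-9]{0,8}$"

# Strict per-axis validators: optionally signed plain decimals, any number
# of fraction digits, |lat| <= 90.0 (90 only with a zero fraction),
# |lon| <= 180.0 likewise.  No exponent notation, no whitespace.  A run of
# redundant leading zeros is tolerated ("090.0" is still ninety degrees),
# keeping the validators exactly equivalent to "parses as a plain decimal
# and the value is within bounds".
LATITUDE_PATTERN = r"^[-+]?0*(([1-8]?\d(\.\d+)?)|90(\.0+)?)$"
LONGITUDE_PATTERN = r"^[-+]?0*((1[0-7]\d(\.\d+)?)|([1-9]?\d(\.\d+)?)|180(\.0+)?)$"

# "Number-shaped": same decimal syntax with no magnitude bound.  Splits the
# two archive failure modes: a number-shaped string beyond bounds is an
# out-of-range value, anything else is a syntax error.
_NUMBER_SHAPE = r"^[-+]?\d+(\.\d+)?$"

#: INSDC controlled vocabulary for intentionally absent values.
MISSING_VOCAB = frozenset(
    {"not applicable", "not collected", "not provided", "restricted access"}
)

#: Substrings that mark a biome description as water-associated.
DEFAULT_WATER_VOCAB = frozenset(
    {"water", "marine", "ocean", "sea", "river", "lake", "aquatic", "wetland", "wastewater"}
)

_legacy_re = re.compile(LEGACY_PATTERN)
_lat_re = re.compile(LATITUDE_PATTERN)
_lon_re = re.compile(LONGITUDE_PATTERN)
_number_re = re.compile(_NUMBER_SHAPE)


def validate_legacy(text: str) -> bool:
    """Match against the legacy single-field pattern, flaws included."""
    return _legacy_re.match(text) is not None


def validate_latitude(text: str) -> bool:
    """True iff ``text`` is a plain signed decimal with |value| <= 90.0."""
    return _lat_re.match(text) is not None


def validate_longitude(text: str) -> bool:
    """True iff ``text`` is a plain signed decimal with |value| <= 180.0."""
    return _lon_re.match(text) is not None


def is_number_shaped(text: str) -> bool:
    return _number_re.match(text) is not None


def parse_coordinate(text: str) -> float | None:
    """Float value of a number-shaped coordinate string, else ``None``."""
    stripped = text.strip()
    if not _number_re.match(stripped):
        return None
    return float(stripped)


def is_missing_vocab(text: str) -> bool:
    """Case-insensitive exact match (after trimming) against INSDC terms."""
    return text.strip().lower() in MISSING_VOCAB


@dataclass(frozen=True)
class ValidatorSet:
    """The pattern bundle a submission pipeline would configure."""

    legacy_pattern: str = LEGACY_PATTERN
    latitude_pattern: str = LATITUDE_PATTERN
    longitude_pattern: str = LONGITUDE_PATTERN
    missing_vocab: frozenset[str] = MISSING_VOCAB


class Flag(str, Enum):
    INVALID_LAT_SYNTAX = "INVALID_LAT_SYNTAX"
    INVALID_LON_SYNTAX = "INVALID_LON_SYNTAX"
    LAT_OUT_OF_RANGE = "LAT_OUT_OF_RANGE"
    LON_OUT_OF_RANGE = "LON_OUT_OF_RANGE"
    NULL_ISLAND_PLACEHOLDER = "NULL_ISLAND_PLACEHOLDER"
    FREQUENT_LOCATION = "FREQUENT_LOCATION"
    ON_WATER_BIOME_CONFLICT = "ON_WATER_BIOME_CONFLICT"
    COUNTRY_MISMATCH = "COUNTRY_MISMATCH"
    MISSING_VALUE_VOCAB = "MISSING_VALUE_VOCAB"


@dataclass
class ValidationReport:
    """Per-record flag sets plus exact dataset-level tallies."""

    per_record: dict[str, set[Flag]]
    frequent_locations: list[tuple[float, float, int]] = field(default_factory=list)
    unparseable_ids: list[str] = field(default_factory=list)

    @property
    def dataset_stats(self) -> dict[Flag, int]:
        stats: dict[Flag, int] = {flag: 0 for flag in Flag}
        for flags in self.per_record.values():
            for flag in flags:
                stats[flag] += 1
        return stats

    @property
    def n_flagged(self) -> int:
        return sum(1 for flags in self.per_record.values() if flags)

    def flagged_ids(self, flag: Flag) -> set[str]:
        return {sid for sid, flags in self.per_record.items() if flag in flags}


@dataclass(frozen=True)
class ValidationConfig:
    """Knobs for dataset-level checks.

    ``min_count``/``min_fraction`` gate the frequent-location report: a
    distinct coordinate pair is reported only when it occurs at least
    ``min_count`` times *and* makes up at least ``min_fraction`` of the
    sheet.  Column names locate the optional biome and country metadata in
    the sheet's extra columns.
    """

    min_count: int = 50
    min_fraction: float = 0.001
    water_vocab: frozenset[str] = DEFAULT_WATER_VOCAB
    rurality_feature: str = "rurality"
    country_feature: str = "country"
    biome_column: str = "Environment Biome"
    country_column: str = "country"


# ---------------------------------------------------------------------------
# Field-level flags
# ---------------------------------------------------------------------------

def _field_flags(text: str, axis: str) -> set[Flag]:
    """Flags for one coordinate field; missing-vocab suppresses the rest."""
    if is_missing_vocab(text):
        return {Flag.MISSING_VALUE_VOCAB}
    stripped = text.strip()
    ok = validate_latitude(stripped) if axis == "lat" else validate_longitude(stripped)
    if ok:
        return set()
    if is_number_shaped(stripped):
        return {Flag.LAT_OUT_OF_RANGE if axis == "lat" else Flag.LON_OUT_OF_RANGE}
    return {Flag.INVALID_LAT_SYNTAX if axis == "lat" else Flag.INVALID_LON_SYNTAX}


# ---------------------------------------------------------------------------
# Placeholder / frequent-location detection
# ---------------------------------------------------------------------------

@dataclass
class PlaceholderReport:
    null_island_ids: list[str]
    frequent_locations: list[tuple[float, float, int]]
    unparseable_ids: list[str]


def detect_placeholders(
    records: Iterable["SampleRecord"],
    min_count: int = 50,
    min_fraction: float = 0.001,
) -> PlaceholderReport:
    """Find null-island placeholders and suspiciously frequent locations.

    Null island is exact numeric equality with (0, 0) after parsing, so
    "0.00"/"0.0000" both hit.  A location is *frequent* when it occurs at
    least ``min_count`` times and in at least ``min_fraction`` of all
    records; results are sorted by count descending, ties broken by
    (lat, lon) ascending.  Records whose coordinates do not parse are
    excluded from the tally and reported separately.
    """
    if min_count < 2:
        raise ValueError("min_count must be >= 2")
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must be in (0, 1]")
    records = list(records)
    null_island: list[str] = []
    unparseable: list[str] = []
    tally: Counter[tuple[float, float]] = Counter()
    for rec in records:
        lat = parse_coordinate(rec.latitude)
        lon = parse_coordinate(rec.longitude)
        if lat is None or lon is None:
            unparseable.append(rec.sample_id)
            continue
        tally[(lat, lon)] += 1
        if lat == 0.0 and lon == 0.0:
            null_island.append(rec.sample_id)
    n = len(records)
    frequent = [
        (lat, lon, count)
        for (lat, lon), count in tally.items()
        if count >= min_count and n > 0 and count >= min_fraction * n
    ]
    frequent.sort(key=lambda t: (-t[2], t[0], t[1]))
    return PlaceholderReport(null_island, frequent, unparseable)


# ---------------------------------------------------------------------------
# Cross-field consistency checks (need an annotated packet)
# ---------------------------------------------------------------------------

def check_water_biome(
    annotation: "AnnotationRecord",
    biome_text: str,
    water_vocab: frozenset[str] = DEFAULT_WATER_VOCAB,
    rurality_feature: str = "rurality",
) -> bool:
    """True when the point sits on water but the biome text never mentions it.

    A missing rurality value (nodata, out of bounds) yields no
    determination and returns False.
    """
    from .categories import RURALITY_WATER_CODE
    from .query import CategoricalValue

    value = annotation.values.get(rurality_feature)
    if not isinstance(value, CategoricalValue):
        return False
    if value.code != RURALITY_WATER_CODE:
        return False
    text = biome_text.lower()
    return not any(term in text for term in water_vocab)


def check_country(
    packet: "DataPacket",
    latitude: float,
    longitude: float,
    reported_country: str,
    country_feature: str = "country",
) -> bool:
    """True when the coordinate's country layer code contradicts the report.

    Missing on either side — nodata under the point (e.g. open ocean), or
    an INSDC missing-value term reported — yields no determination and
    returns False.  A reported name that matches no label in the country
    layer's category table raises :class:`UnknownCountry`.
    """
    from .errors import OutOfBounds
    from .query import CategoricalValue, sample_point

    reported = reported_country.strip()
    if not reported or is_missing_vocab(reported):
        return False
    layer_meta = None
    for lyr in packet.layers:
        if lyr.meta.feature_name == country_feature:
            layer_meta = lyr.meta
    if layer_meta is None or layer_meta.category_table is None:
        raise UnknownCountry(f"packet has no categorical layer {country_feature!r}")
    code_by_label = {}
    for code, (short, long_) in layer_meta.category_table.entries.items():
        code_by_label[short.lower()] = code
        code_by_label[long_.lower()] = code
    reported_code = code_by_label.get(reported.lower())
    if reported_code is None:
        raise UnknownCountry(f"unknown country name {reported_country!r}")
    try:
        sampled = sample_point(packet, country_feature, latitude, longitude)
    except OutOfBounds:
        return False
    if not isinstance(sampled, CategoricalValue):
        return False
    return sampled.code != reported_code


# ---------------------------------------------------------------------------
# Whole-sheet validation
# ---------------------------------------------------------------------------

def validate_sheet(
    records: list["SampleRecord"],
    packet: "DataPacket | None" = None,
    config: ValidationConfig | None = None,
) -> ValidationReport:
    """Run every applicable QC check over a sample sheet.

    Field-level checks (syntax, range, missing vocabulary) and
    dataset-level placeholder detection always run; the water-vs-biome and
    country-vs-coordinate checks run only when a packet with the relevant
    layers is supplied and the sheet carries the relevant columns.
    """
    from .query import annotate

    config = config or ValidationConfig()
    per_record: dict[str, set[Flag]] = {}
    for rec in records:
        flags = _field_flags(rec.latitude, "lat") | _field_flags(rec.longitude, "lon")
        per_record[rec.sample_id] = flags

    placeholders = detect_placeholders(records, config.min_count, config.min_fraction)
    for sid in placeholders.null_island_ids:
        per_record[sid].add(Flag.NULL_ISLAND_PLACEHOLDER)
    frequent_set = {(lat, lon) for lat, lon, _ in placeholders.frequent_locations}
    if frequent_set:
        for rec in records:
            lat = parse_coordinate(rec.latitude)
            lon = parse_coordinate(rec.longitude)
            if lat is not None and lon is not None and (lat, lon) in frequent_set:
                per_record[rec.sample_id].add(Flag.FREQUENT_LOCATION)

    if packet is not None:
        has_rurality = config.rurality_feature in packet.feature_names
        has_country = config.country_feature in packet.feature_names
        if has_rurality or has_country:
            annotations = annotate(records, packet)
            by_id = {rec.sample_id: rec for rec in records}
            for ann in annotations:
                rec = by_id[ann.sample_id]
                biome = rec.extras.get(config.biome_column)
                if has_rurality and biome is not None:
                    if check_water_biome(
                        ann, biome, config.water_vocab, config.rurality_feature
                    ):
                        per_record[ann.sample_id].add(Flag.ON_WATER_BIOME_CONFLICT)
                reported = rec.extras.get(config.country_column)
                if has_country and reported is not None:
                    coords = parse_coordinate(rec.latitude), parse_coordinate(rec.longitude)
                    if coords[0] is not None and coords[1] is not None:
                        try:
                            if check_country(
                                packet, coords[0], coords[1], reported, config.country_feature
                            ):
                                per_record[ann.sample_id].add(Flag.COUNTRY_MISMATCH)
                        except UnknownCountry:
                            pass  # unresolvable report: no determination

    return ValidationReport(
        per_record=per_record,
        frequent_locations=placeholders.frequent_locations,
        unparseable_ids=placeholders.unparseable_ids,
    )
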