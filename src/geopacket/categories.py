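"""Category tables for the categorical layers of a data packet.

Two standard codings ship with the package:

* the degree-of-urbanization settlement classification (level 2 of the
  GHSL settlement model), here called the *rurality* layer — eight classes
  from "urban centre" down to "very low density rural", plus "water";
* the 30-class Köppen-Geiger climate classification with compound labels
  such as "Temperate, no dry season, warm summer".

Packets may also carry bespoke tables (e.g. a synthetic country layer).
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class CategoryTable:
    """Mapping from integer raster code to (short_label, long_label)."""

    entries: dict[int, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for code, (short, long_) in self.entries.items():
            if not isinstance(code, int) or code < 0:
                raise ValueError(f"category code {code!r} must be a non-negative integer")
            if not short or not long_:
                raise ValueError(f"category {code} has an empty label")

    def __contains__(self, code: int) -> bool:
        return code in self.entries

    def short_label(self, code: int) -> str:
        return self.entries[code][0]

    def long_label(self, code: int) -> str:
        return self.entries[code][1]

    @property
    def codes(self) -> frozenset[int]:
        return frozenset(self.entries)


#: Degree-of-urbanization (settlement model, level 2) coding.
RURALITY_TABLE = CategoryTable(
    {
        30: ("urban centre", "Urban centre (high density cluster)"),
        23: ("dense urban cluster", "Dense urban cluster"),
        22: ("semi-dense urban cluster", "Semi-dense urban cluster"),
        21: ("suburban or peri-urban", "Suburban or peri-urban area"),
        13: ("rural cluster", "Rural cluster"),
        12: ("low density rural", "Low density rural grid cell"),
        11: ("very low density", "Very low density rural grid cell"),
        10: ("water", "Water body"),
    }
)

#: Code for open water in the rurality coding; used by the biome QC check.
RURALITY_WATER_CODE = 10
RURALITY_URBAN_CENTRE_CODE = 30

_KOPPEN_CLASSES = [
    (1, "Af", "Tropical, rainforest"),
    (2, "Am", "Tropical, monsoon"),
    (3, "Aw", "Tropical, savannah"),
    (4, "BWh", "Arid, desert, hot"),
    (5, "BWk", "Arid, desert, cold"),
    (6, "BSh", "Arid, steppe, hot"),
    (7, "BSk", "Arid, steppe, cold"),
    (8, "Csa", "Temperate, dry summer, hot summer"),
    (9, "Csb", "Temperate, dry summer, warm summer"),
    (10, "Csc", "Temperate, dry summer, cold summer"),
    (11, "Cwa", "Temperate, dry winter, hot summer"),
    (12, "Cwb", "Temperate, dry winter, warm summer"),
    (13, "Cwc", "Temperate, dry winter, cold summer"),
    (14, "Cfa", "Temperate, no dry season, hot summer"),
    (15, "Cfb", "Temperate, no dry season, warm summer"),
    (16, "Cfc", "Temperate, no dry season, cold summer"),
    (17, "Dsa", "Cold, dry summer, hot summer"),
    (18, "Dsb", "Cold, dry summer, warm summer"),
    (19, "Dsc", "Cold, dry summer, cold summer"),
    (20, "Dsd", "Cold, dry summer, very cold winter"),
    (21, "Dwa", "Cold, dry winter, hot summer"),
    (22, "Dwb", "Cold, dry winter, warm summer"),
    (23, "Dwc", "Cold, dry winter, cold summer"),
    (24, "Dwd", "Cold, dry winter, very cold winter"),
    (25, "Dfa", "Cold, no dry season, hot summer"),
    (26, "Dfb", "Cold, no dry season, warm summer"),
    (27, "Dfc", "Cold, no dry season, cold summer"),
    (28, "Dfd", "Cold, no dry season, very cold winter"),
    (29, "ET", "Polar, tundra"),
    (30, "EF", "Polar, frost"),
]

#: 30-class Köppen-Geiger coding (codes 1-30, compound climate labels).
KOPPEN_TABLE = CategoryTable({c: (s, l) for c, s, l in _KOPPEN_CLASSES})

STANDARD_TABLES: dict[str, CategoryTable] = {
    "rurality": RURALITY_TABLE,
    "koppen": KOPPEN_TABLE,
}
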