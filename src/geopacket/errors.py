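"""Exception hierarchy for geopacket.

Every error raised by the library derives from :class:`GeopacketError` so
callers (and the CLI) can distinguish library failures from programming
errors with a single ``except`` clause.
"""


class GeopacketError(Exception):
    """Base class for all geopacket errors."""


class CRSMismatch(GeopacketError):
    """A source raster is not on the packet's coordinate reference system."""


class EmptyIntersection(GeopacketError):
    """A source raster does not overlap the target grid at all."""


class DuplicateLayer(GeopacketError):
    """Two layers in one packet claim the same feature name."""


class CorruptPacket(GeopacketError):
    """A packet directory is missing a layer file the manifest promises."""


class GridMismatch(GeopacketError):
    """Manifest georeferencing disagrees with the raster file's own tags."""


class CitationError(GeopacketError):
    """A layer citation is absent or does not parse as one BibTeX entry."""


class OutOfBounds(GeopacketError):
    """A point falls outside the grid footprint.

    Carries the computed (row, col) indices so callers can report where the
    point would have landed.
    """

    def __init__(self, row: int, col: int, message: str | None = None):
        self.row = row
        self.col = col
        super().__init__(message or f"pixel ({row}, {col}) outside grid")


class UnknownFeature(GeopacketError):
    """A query names a feature the packet does not contain."""


class UnknownCategory(GeopacketError):
    """A category code is not in the layer's category table."""


class UnknownCountry(GeopacketError):
    """A reported country name cannot be resolved to a known code."""


class NotCategorical(GeopacketError):
    """A categorical-only operation was applied to a continuous layer."""


class TooFewPairs(GeopacketError):
    """Fewer than two complete pairs remain for correlation."""


class DegenerateInput(GeopacketError):
    """Rank correlation undefined: one vector has zero rank variance."""


class BadRecipe(GeopacketError):
    """A synthetic layer recipe is inconsistent with its category table."""


class BadParameter(GeopacketError):
    """A synthetic-data parameter is outside its admissible range."""


class InputError(GeopacketError):
    """A sample sheet or other user input cannot be read or lacks columns."""
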