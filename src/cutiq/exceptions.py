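"""Exception hierarchy shared across the package.

All errors derive from :class:`CutiqError` so callers can catch the package's
failures with a single except clause; each subclass maps to one failure mode
(bad file format, inconsistent annotation, broken geometry, ...).
"""


class CutiqError(Exception):
    """Base class for all package errors."""


class FormatError(CutiqError, ValueError):
    """Raster or table input does not have the expected layout (e.g. RGB
    image where single-channel grayscale is required)."""


class SchemaError(CutiqError, ValueError):
    """JSON/CSV document is missing required fields or mixes record types."""


class TraceValidationError(CutiqError, ValueError):
    """A boundary trace is internally inconsistent (orientation flag
    contradicting the geometry, background region overlapping the band)."""


class GeometryError(CutiqError, ValueError):
    """Degenerate or impossible geometry: zero-length tangent, empty
    polygon, band wider than the image, unplaceable cells."""


class OutOfBoundsError(CutiqError, ValueError):
    """A sampling line leaves the image raster."""


class MeasurementError(CutiqError, ValueError):
    """A measurement could not be made at any of the requested positions."""


class InputError(CutiqError, ValueError):
    """Empty or ill-sized inputs to an analysis stage."""
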