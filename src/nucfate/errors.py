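"""Exception hierarchy used across the package."""


class NucfateError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(NucfateError, ValueError):
    """An argument violates a documented precondition."""


class GeometryError(ValidationError):
    """The requested nucleus does not fit the image geometry."""


class SegmentationError(NucfateError):
    """Otsu segmentation is undefined (e.g. constant image)."""


class NormalizationError(NucfateError):
    """Baseline normalization impossible (zero baseline mean, too few frames)."""


class TessellationError(NucfateError):
    """Voronoi tessellation undefined (collinear or degenerate input)."""


class FormatError(NucfateError):
    """A required column or field is missing or malformed in an input file."""
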