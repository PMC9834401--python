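"""Exception types shared across the package."""


class MitoquantError(ValueError):
    """Base class for domain errors."""


class DegenerateGeometryError(MitoquantError):
    """Input geometry insufficient to define the requested object
    (too few points, collinear contour, coincident spindle poles)."""


class OutOfBoundsError(MitoquantError):
    """A sampling path leaves the image frame."""


class FormatError(MitoquantError):
    """An input file could not be parsed as the expected format."""
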