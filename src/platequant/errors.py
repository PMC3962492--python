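"""Exception hierarchy for the plate-quantification pipeline.

Every error raised by the library derives from :class:`PlateQuantError`, so
callers (and the CLI) can distinguish pipeline failures from programming
errors with a single ``except`` clause.
"""


class PlateQuantError(Exception):
    """Base class for all pipeline errors."""


class UnsupportedImageError(PlateQuantError):
    """Image has a channel count other than 1 or 3."""


class DegenerateImageError(PlateQuantError):
    """Image is constant (or otherwise carries no usable signal)."""


class ParameterError(PlateQuantError):
    """A parameter violates its documented precondition."""


class GridFailureError(PlateQuantError):
    """The colony grid could not be fitted on one of the axes."""

    def __init__(self, message: str, axis: str | None = None):
        super().__init__(message)
        self.axis = axis


class CoordinateError(PlateQuantError):
    """A pixel coordinate lies outside the image."""


class AlignmentError(PlateQuantError):
    """Profile alignment against a reference failed."""


class ReferenceMismatchError(PlateQuantError):
    """Reference and target images are not compatible."""
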