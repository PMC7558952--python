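"""Exception hierarchy.

Validation problems (bad inputs, malformed files, inconsistent metadata)
derive from :class:`ValidationError`; numerical failures of the fitting
machinery derive from :class:`FitConvergenceError`.  The CLI maps the two
branches to exit codes 2 and 3 respectively.
"""


class GlassAgeError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(GlassAgeError):
    """Input data or configuration violates a documented precondition."""


class FormatError(ValidationError):
    """A file could not be parsed with the declared dialect."""


class WindowError(ValidationError):
    """A baseline/fit window is empty, too small, or overlaps another."""


class SegmentationError(ValidationError):
    """A thermogram does not match the declared thermal program."""


class RateMismatchError(ValidationError):
    """Two curves that must share a scan rate do not."""


class TransitionNotFoundError(GlassAgeError):
    """No glass-transition step could be located in the curve."""


class AnchorError(ValidationError):
    """An integration reference temperature lies outside the curve."""


class ParameterError(ValidationError):
    """A model parameter is outside its physical domain."""


class GeometryError(ValidationError):
    """A synthetic construction does not fit on the requested grid."""


class ResolutionError(ValidationError):
    """A simulation step size is too coarse for the requested program."""


class ConditioningError(GlassAgeError):
    """A regression problem is numerically degenerate."""


class FitConvergenceError(GlassAgeError):
    """Nonlinear least squares failed to converge after multi-start."""
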