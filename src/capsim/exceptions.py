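"""Exception hierarchy for capsim."""


class CapsimError(Exception):
    """Base class for all capsim errors."""


class ConfigurationError(CapsimError, ValueError):
    """Invalid grid, transport, placement or simulation configuration."""


class PlacementError(CapsimError, RuntimeError):
    """An element could not be placed within the attempt budget."""


class MaskFormatError(CapsimError, ValueError):
    """A label mask contains unknown pixel values or has an incompatible shape."""


class GeometryError(CapsimError, ValueError):
    """A point or ROI violates a geometric precondition (e.g. outside the capsule)."""


class NumericalInstabilityError(CapsimError, RuntimeError):
    """The explicit solver produced NaN or out-of-range concentrations."""


class DegenerateProfileError(CapsimError, ValueError):
    """A profile is constant or otherwise unusable for the requested operation."""


class FitFailureError(CapsimError, RuntimeError):
    """Growth-curve fitting failed to converge from every start."""


class AlignmentError(CapsimError, ValueError):
    """Two series could not be aligned on a common time grid or length."""


class InsufficientDataError(CapsimError, ValueError):
    """Too few data points for the requested metric."""
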