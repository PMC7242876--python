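"""Exception hierarchy for adipophen."""


class AdipophenError(Exception):
    """Base class for all adipophen errors."""


class InvalidCalibrationError(AdipophenError):
    """CT rescale slope is zero or otherwise unusable."""


class NoBodyFoundError(AdipophenError):
    """No voxel survives the body threshold."""


class UndefinedFractionError(AdipophenError):
    """A ratio with an empty denominator (ROI, body, dose...)."""


class InvalidContourError(AdipophenError):
    """A planar ROI contour is degenerate or self-intersecting."""


class InvalidScheduleError(AdipophenError):
    """A light/dark schedule does not define two phases."""


class InvalidTableError(AdipophenError):
    """A Ct or densitometry table violates its contract."""


class PhantomError(AdipophenError):
    """A synthetic phantom cannot be built with the requested parameters."""
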