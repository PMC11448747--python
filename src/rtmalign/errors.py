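"""Exception and warning types shared across the package."""


class RtmalignError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(RtmalignError):
    """A requested lens layout is not physically realizable.

    Raised e.g. when the implied objective-to-tube-lens separation
    (d_total - d_sample - d_cam) is not positive.
    """


class ConfigError(RtmalignError):
    """A microscope configuration file is malformed or inconsistent."""


class MeasurementError(RtmalignError):
    """A measured feature distance is missing, non-positive or otherwise unusable."""


class InsufficientFeaturesError(RtmalignError):
    """Fewer features were detected in a line profile than the measurement needs."""


class OutOfRangeError(RtmalignError):
    """A measured magnification ratio falls outside the scanned model curve.

    Widen the d_sample scan range rather than extrapolating the model.
    """


class NonMonotonicCurveError(RtmalignError):
    """The normalized magnification curve is not monotonic where inversion is attempted."""


class NoSolutionWarning(UserWarning):
    """No tube-lens position produces an image for the given channel and d_sample."""


class AlignmentWarning(UserWarning):
    """Per-channel working-distance estimates disagree more than expected."""
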