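"""Exception hierarchy for the brace-kinematics pipeline."""


class BracekinError(Exception):
    """Base class for all package errors."""


class UnknownTaskError(BracekinError, ValueError):
    """An ADL task name outside the supported set."""


class ConfigError(BracekinError, ValueError):
    """Invalid simulation or pipeline configuration."""


class FormatError(BracekinError, ValueError):
    """A recording file violates the expected text dialect."""


class StructuralError(FormatError):
    """A recording file is missing a required block (e.g. one sensor)."""


class RangeError(BracekinError, ValueError):
    """Integer counts outside the sensor's representable range."""


class OrientationError(BracekinError, ValueError):
    """Accelerometer vector has no defined tilt (zero in-plane magnitude)."""


class CalibrationError(BracekinError, RuntimeError):
    """No quiescent static window available for referencing."""


class AlignmentError(BracekinError, RuntimeError):
    """Brace and criterion streams could not be aligned."""


class ParameterError(BracekinError, ValueError):
    """Invalid analysis parameter (e.g. filter cutoff above Nyquist)."""


class PairingError(BracekinError, ValueError):
    """Paired statistics requested on mismatched sample sets."""


class QuantityMismatchError(BracekinError, TypeError):
    """Angle and velocity curves mixed in a single ensemble."""


class SmoothnessError(BracekinError, RuntimeError):
    """Residual field smoothness is undefined (zero variance)."""


class ThresholdError(BracekinError, RuntimeError):
    """No random-field threshold exists below the search ceiling."""
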