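"""Exception hierarchy shared across the pipeline stages."""


class ExpotrackError(Exception):
    """Base class for all package errors."""


class FormatError(ExpotrackError, ValueError):
    """A file does not conform to the expected schema."""


class OrderingError(ExpotrackError, ValueError):
    """Timestamps are not strictly increasing where they must be."""


class EmptyInputError(ExpotrackError, ValueError):
    """An operation received an empty series, log or track."""


class InsufficientDataError(ExpotrackError, ValueError):
    """Too few samples/points for the operation to be meaningful."""


class ParameterError(ExpotrackError, ValueError):
    """A parameter is outside its documented range."""


class CalibrationError(ExpotrackError, ValueError):
    """Calibration points do not define a monotone curve."""


class AlignmentError(ExpotrackError, ValueError):
    """No sensor stream overlaps the fusion grid."""


class DomainError(ExpotrackError, ValueError):
    """Values outside the mathematical domain of an operation."""


class ConfigError(ExpotrackError, ValueError):
    """Pipeline configuration is invalid or references missing files."""
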