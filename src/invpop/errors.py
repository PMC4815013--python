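"""Exception hierarchy.

Two top-level families mirror the CLI exit codes: configuration problems
(exit 2) and data problems (exit 3).
"""


class InvpopError(Exception):
    """Base class for all package errors."""


class ConfigError(InvpopError):
    """Invalid configuration: bad thresholds, undefined labels, missing calibration."""


class DataError(InvpopError):
    """Invalid or insufficient input data."""


class AlignmentError(DataError):
    """Malformed alignment (unequal lengths, illegal characters, duplicate ids)."""


class MetadataError(DataError):
    """Sequence metadata missing or inconsistent with the alignment."""


class AnnotationError(DataError):
    """Gene annotation incompatible with the alignment (frame, stops, bounds)."""


class InsufficientSampleError(DataError):
    """Too few sequences for the requested statistic."""


class UndefinedValueError(DataError):
    """The statistic is undefined for this input (e.g. zero retained sites)."""
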