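"""Exception hierarchy.

``VocScreenError`` is the common base; ``ValidationError`` subclasses map to
CLI exit code 1, everything else unexpected maps to exit code 2.
"""


class VocScreenError(Exception):
    """Base class for all package errors."""


class ValidationError(VocScreenError):
    """Bad user input: parameters, schemas, configuration."""


class InvalidParameterError(ValidationError, ValueError):
    """A numeric argument violates its domain (non-positive volume, ...)."""


class InputError(ValidationError):
    """Malformed data input (non-increasing grid, empty image, ...)."""


class SchemaError(ValidationError):
    """A table or log does not match the expected schema."""


class ConfigurationError(ValidationError):
    """Inconsistent or incomplete configuration."""


class AlignmentError(ValidationError):
    """Two series cannot be aligned on a common time base."""


class InsufficientDataError(ValidationError):
    """Not enough samples for the requested operation."""


class ModeError(ValidationError):
    """An ionization mode is not allowed for the given sum formula."""


class UnknownElementError(ValidationError, LookupError):
    """A sum formula contains an element without a mass table entry."""


class RangeError(ValidationError):
    """A query falls outside the supported/calibrated range."""


class FitError(ValidationError):
    """A regression problem is degenerate."""
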