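"""Exception taxonomy shared across the package.

Errors that a caller can reasonably branch on get their own class; everything
else surfaces as ValueError subclasses so bare ``except ValueError`` still
catches malformed input.
"""


class HandkinError(Exception):
    """Base class for all package-specific errors."""


class FormatError(HandkinError, ValueError):
    """A file does not follow the expected dialect (missing columns, etc.)."""


class ParseError(HandkinError, ValueError):
    """A cell or row could not be converted to the expected type."""


class EthogramValidationError(HandkinError, ValueError):
    """Ethogram rows violate ordering, alternation or range constraints."""


class ParameterError(HandkinError, ValueError):
    """A parameter value is outside its admissible range."""


class StateError(HandkinError, RuntimeError):
    """An operation was applied in the wrong object state (e.g. re-calibration)."""


class UnitError(HandkinError, ValueError):
    """Positions are in the wrong unit state for the requested operation."""


class InsufficientDataError(HandkinError, ValueError):
    """Not enough usable samples to perform the computation."""


class ConfigurationError(HandkinError, KeyError):
    """A required body part or configuration entry is absent."""


class FitError(HandkinError, ValueError):
    """A model fit is degenerate (e.g. collinear points for a circle fit)."""


class UndefinedResultError(HandkinError, ArithmeticError):
    """The requested quantity is mathematically undefined for this input."""
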