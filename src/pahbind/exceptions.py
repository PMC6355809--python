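"""Exception hierarchy shared across the package."""


class PahbindError(Exception):
    """Base class for all package errors."""


class DomainError(PahbindError, ValueError):
    """An input lies outside the mathematical domain of an operation."""


class ValidationError(PahbindError, ValueError):
    """A data object violates its structural invariants."""


class InsufficientDataError(PahbindError, ValueError):
    """Too few data points to attempt a fit."""


class FitFailureError(PahbindError, RuntimeError):
    """A nonlinear fit could not produce a meaningful result.

    Carries a ``diagnostics`` dict describing what went wrong.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class ParseError(PahbindError, ValueError):
    """A file could not be parsed; names the offending line where possible."""
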