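"""Exception hierarchy.

Everything raised on purpose by this package derives from
:class:`CaptureBiasError`, so callers can catch package-level failures
with a single ``except`` clause while still distinguishing parse,
validation and numerical problems.
"""

from __future__ import annotations


class CaptureBiasError(Exception):
    """Base class for all package errors."""


class ParseError(CaptureBiasError, ValueError):
    """A text input could not be parsed.

    Carries the offending path and 1-based line number when known.
    """

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = str(path) if path is not None else ""
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


class SchemaError(CaptureBiasError, ValueError):
    """A tabular input is missing required columns or has wrong types."""


class ValidationError(CaptureBiasError, ValueError):
    """Data violate an invariant (duplicate sites, negative counts, ...)."""


class InfeasibleError(ValidationError):
    """Requested simulation parameters cannot be satisfied."""


class EmptyInputError(CaptureBiasError, ValueError):
    """An operation received no usable data."""


class UndefinedRatioError(CaptureBiasError, ArithmeticError):
    """A ratio statistic has a zero or missing denominator."""


class NumericalError(CaptureBiasError, ArithmeticError):
    """A numerical routine produced a non-finite intermediate."""
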