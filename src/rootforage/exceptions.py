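"""Exception hierarchy shared across the package.

All errors raised on bad scientific input derive from
:class:`RootForageError`, so callers (and the CLI) can distinguish
validation problems (exit code 2) from computational degeneracies
(exit code 3).
"""


class RootForageError(Exception):
    """Base class for all package errors."""


class DomainError(RootForageError, ValueError):
    """A numeric input lies outside the model's domain (e.g. Vmax <= 0)."""


class StructuralError(RootForageError, ValueError):
    """Inputs are malformed or misaligned (missing columns, label mismatch)."""


class UnitError(RootForageError, ValueError):
    """A unit string is unknown or cannot be converted to canonical units."""


class InsufficientDataError(RootForageError, ValueError):
    """Too few observations for the requested analysis."""


class DegenerateError(RootForageError, ArithmeticError):
    """The computation is degenerate (constant trait, zero variance, ...)."""
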