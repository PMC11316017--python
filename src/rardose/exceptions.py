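"""Exception hierarchy.

Everything raised on purpose derives from :class:`RardoseError`, so callers
(and the CLI) can catch one type.  Most errors are also ``ValueError``
subclasses because they signal bad inputs rather than internal failure.
"""

from __future__ import annotations


class RardoseError(Exception):
    """Base class for all errors raised by this package."""


class InvalidConditionError(RardoseError, ValueError):
    """A dose condition violates its invariants (e.g. accumulated dose <= 0)."""


class InvalidInputError(RardoseError, ValueError):
    """A scalar input is outside its mathematical domain (NaN, inf, zero divisor)."""


class DegenerateDesignError(RardoseError, ValueError):
    """Too few points, or too few distinct doses, to identify the model."""


class FitFailureError(RardoseError, RuntimeError):
    """Nonlinear fit did not converge; carries the last iterate and status."""

    def __init__(self, message: str, last_params=None, status: str | None = None):
        super().__init__(message)
        self.last_params = last_params
        self.status = status


class InversionDomainError(RardoseError, ValueError):
    """The reading is outside the range the calibration curve can produce."""


class UnreachableReadingError(RardoseError, ValueError):
    """Quadratic inversion: negative discriminant, no real dose yields the reading."""


class ExtrapolationError(RardoseError, ValueError):
    """Inverted dose lies beyond the permitted extrapolation cap."""


class MissingDataError(RardoseError, ValueError):
    """A required (marker, group) cell has no readings."""


class IncompleteDesignError(RardoseError, ValueError):
    """The study design lacks the groups a pipeline stage needs."""


class ConfigError(RardoseError, ValueError):
    """A synthetic-study or analysis configuration violates its invariants."""


class ValidationError(RardoseError, ValueError):
    """Input-file validation failed; ``violations`` lists every problem found."""

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__(
            "study validation failed:\n" + "\n".join(f"  - {v}" for v in self.violations)
        )
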