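"""Radio-adaptive response (RAR) arithmetic.

An animal primed with a small acute dose D_p and challenged later with a
larger dose D_c has accumulated D_{p+c} = D_p + D_c.  Reading the primed
group's biomarker back through the acute calibration curve yields the RAR
equivalent dose D_RAR: the single acute dose that would have produced the
same biological change.  The RAR factor

    f_RAR = 1 - (D_RAR - D_p) / D_{p+c}

quantifies adaptation: f_RAR = 1 when the combined exposure reads like the
priming dose alone (full adaptation), smaller values as D_RAR approaches
the accumulated dose.  The companion priming-dose difference

    delta = 1 - N_{p+c} / N_c

compares the primed group's raw reading N_{p+c} with the challenge-only
group's N_c; it is positive when priming reduced the response.

All functions here are pure scalar arithmetic: no clamping, no rounding.
Values outside [0, 1] are reported as-is with a flag, because they signal
data problems that clamping would hide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .exceptions import InvalidConditionError, InvalidInputError

__all__ = [
    "DoseCondition",
    "RarFactorResult",
    "rar_factor",
    "effective_dose_from_factor",
    "priming_delta",
    "percent_change",
]


@dataclass(frozen=True)
class DoseCondition:
    """A priming + challenge exposure, all doses in mSv equivalent dose.

    ``accumulated_dose`` is the arithmetic sum D_p + D_c (55 mSv for the
    5+50 condition, 60 mSv for 10+50).
    """

    priming_dose: float
    challenge_dose: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.priming_dose) and math.isfinite(self.challenge_dose)):
            raise InvalidConditionError("doses must be finite")
        if self.priming_dose < 0 or self.challenge_dose < 0:
            raise InvalidConditionError(
                f"doses must be non-negative, got "
                f"({self.priming_dose}, {self.challenge_dose})"
            )

    @property
    def accumulated_dose(self) -> float:
        return self.priming_dose + self.challenge_dose

    @property
    def label(self) -> str:
        """Condition label in the '5+50' style used throughout reports."""

        def fmt(x: float) -> str:
            return f"{x:g}"

        return f"{fmt(self.priming_dose)}+{fmt(self.challenge_dose)}"


@dataclass(frozen=True)
class RarFactorResult:
    """A RAR factor together with the equivalent dose it came from."""

    rared: float
    factor: float
    in_unit_interval: bool


def _require_invertible(condition: DoseCondition) -> None:
    if condition.accumulated_dose <= 0:
        raise InvalidConditionError(
            f"accumulated dose must be positive, got {condition.accumulated_dose}"
        )


def rar_factor(d_rar: float, condition: DoseCondition) -> RarFactorResult:
    """RAR factor f_RAR = 1 - (D_RAR - D_p)/D_{p+c}.

    Parameters
    ----------
    d_rar : float
        RAR equivalent dose in mSv, read off the acute calibration curve.
    condition : DoseCondition
        The priming/challenge exposure that produced the reading.

    Returns
    -------
    RarFactorResult
        Unclamped factor plus a flag marking whether it lies in [0, 1].
    """
    _require_invertible(condition)
    if not math.isfinite(d_rar):
        raise InvalidInputError(f"d_rar must be finite, got {d_rar}")
    factor = 1.0 - (d_rar - condition.priming_dose) / condition.accumulated_dose
    return RarFactorResult(
        rared=d_rar, factor=factor, in_unit_interval=0.0 <= factor <= 1.0
    )


def effective_dose_from_factor(factor: float, condition: DoseCondition) -> float:
    """Algebraic inverse of :func:`rar_factor`.

    Returns the equivalent dose D_RAR = D_p + (1 - f)*D_{p+c} that yields
    ``factor`` under ``condition``.  Used by the synthetic generator to
    encode a chosen adaptation strength as an effective dose.
    """
    _require_invertible(condition)
    if not math.isfinite(factor):
        raise InvalidInputError(f"factor must be finite, got {factor}")
    return condition.priming_dose + (1.0 - factor) * condition.accumulated_dose


def priming_delta(n_pc: float, n_c: float) -> float:
    """Priming-dose difference delta = 1 - N_{p+c}/N_c.

    ``n_pc`` is the primed+challenged group's reading, ``n_c`` the
    challenge-only group's.  Positive when priming lowered the reading;
    the sign is meaningful and never clamped.
    """
    if n_c == 0:
        raise InvalidInputError("challenge-only reading n_c must be nonzero")
    if not (math.isfinite(n_pc) and math.isfinite(n_c)):
        raise InvalidInputError("readings must be finite")
    return 1.0 - n_pc / n_c


def percent_change(value: float, reference: float) -> float:
    """Signed percent change 100*(value - reference)/reference."""
    if reference == 0:
        raise InvalidInputError("reference must be nonzero")
    if not (math.isfinite(value) and math.isfinite(reference)):
        raise InvalidInputError("readings must be finite")
    return 100.0 * (value - reference) / reference
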