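"""Inverse dosimetry: map a biomarker reading back to an equivalent dose.

Each calibration family has a closed-form inverse:

* linear        x = (y - b) / a
* exponential   x = ln((y - y0)/A) / R0, defined when (y - y0)/A > 0
* quadratic     the root of B2*x^2 + B1*x + (intercept - y) on the
                data-bearing monotone branch

Extrapolation beyond the fitted dose domain is allowed up to twice the
domain's upper bound (flagged ``in_domain=False``); beyond that the
request is refused rather than silently extrapolated.  Negative inverted
doses are returned unclamped with a note, so noisy inputs surface as
negative doses instead of being quietly floored at zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .calibration import CalibrationModel
from .exceptions import (
    ExtrapolationError,
    InversionDomainError,
    UnreachableReadingError,
)

__all__ = ["InversionResult", "invert_dose", "EXTRAPOLATION_FACTOR"]

#: inverted doses above this multiple of the fitted upper dose are refused
EXTRAPOLATION_FACTOR = 2.0

_TOL = 1e-9


@dataclass(frozen=True)
class InversionResult:
    """An inverted dose, with provenance of any branch/domain decisions."""

    dose: float
    in_domain: bool
    branch_note: str = ""


def invert_dose(
    model: CalibrationModel,
    reading: float,
    extrapolation_factor: float = EXTRAPOLATION_FACTOR,
) -> InversionResult:
    """Invert ``model`` at ``reading``, returning the equivalent dose in mSv."""
    if not math.isfinite(reading):
        raise InversionDomainError(f"reading must be finite, got {reading}")
    lo, hi = model.dose_domain
    cap = extrapolation_factor * hi
    notes: list[str] = []

    if model.family == "linear":
        dose = _invert_linear(model, reading)
    elif model.family == "exponential":
        dose = _invert_exponential(model, reading)
    elif model.family == "quadratic":
        dose = _invert_quadratic(model, reading, cap, notes)
    else:  # pragma: no cover
        raise InversionDomainError(f"unknown family {model.family!r}")

    if dose > cap + _TOL:
        raise ExtrapolationError(
            f"{model.marker_id or model.family}: inverted dose {dose:.3g} mSv "
            f"exceeds the extrapolation cap {cap:g} mSv"
        )
    if dose < 0:
        notes.append("negative-dose")
    in_domain = (lo - _TOL) <= dose <= (hi + _TOL)
    if not in_domain and dose >= 0:
        notes.append("extrapolated")
    return InversionResult(dose=dose, in_domain=in_domain, branch_note="; ".join(notes))


def _invert_linear(model: CalibrationModel, reading: float) -> float:
    a = model.constants["a"]
    b = model.constants["b"]
    if a == 0:
        raise InversionDomainError(
            f"{model.marker_id or 'linear model'}: flat line (a = 0) cannot be inverted"
        )
    return (reading - b) / a


def _invert_exponential(model: CalibrationModel, reading: float) -> float:
    c = model.constants
    arg = (reading - c["y0"]) / c["A"]
    if arg <= 0:
        raise InversionDomainError(
            f"{model.marker_id or 'exponential model'}: reading {reading:g} lies "
            f"beyond the asymptote y0 = {c['y0']:g}"
        )
    return math.log(arg) / c["R0"]


def _invert_quadratic(
    model: CalibrationModel, reading: float, cap: float, notes: list[str]
) -> float:
    c = model.constants
    b2, b1 = c["B2"], c["B1"]
    if b2 == 0:
        if b1 == 0:
            raise InversionDomainError("flat quadratic cannot be inverted")
        return (reading - c["intercept"]) / b1

    disc = b1 * b1 - 4.0 * b2 * (c["intercept"] - reading)
    if disc < 0:
        if disc > -1e-9 * max(b1 * b1, 1.0):
            disc = 0.0  # grazing the vertex within round-off
        else:
            raise UnreachableReadingError(
                f"{model.marker_id or 'quadratic model'}: reading {reading:g} is "
                "beyond the parabola's extremum (negative discriminant)"
            )
    sq = math.sqrt(disc)
    roots = sorted(((-b1 - sq) / (2 * b2), (-b1 + sq) / (2 * b2)))

    lo, hi = model.dose_domain
    vertex = model.vertex
    # the data-bearing branch is the side of the vertex containing the
    # domain's lower edge (the acute-dose side); roots are symmetric about
    # the vertex, so at most one root lies on that branch.
    if vertex is not None:
        on_branch = [r for r in roots if (r <= vertex + _TOL) == (lo <= vertex)]
    else:  # pragma: no cover - b2 == 0 handled above
        on_branch = roots

    in_domain = [r for r in roots if (lo - _TOL) <= r <= (hi + _TOL)]
    if on_branch:
        chosen = min(on_branch) if len(on_branch) > 1 else on_branch[0]
    elif in_domain:
        chosen = min(in_domain)
        notes.append("off-branch root inside dose domain accepted")
    else:
        chosen = min(roots, key=abs)
        notes.append("no root on the data-bearing branch")
    rejected = [r for r in roots if r != chosen]
    if rejected:
        notes.append(
            "alternate root " + ", ".join(f"{r:.4g}" for r in rejected) + " rejected"
        )
    return chosen
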