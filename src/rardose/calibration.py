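"""Dose-response calibration-curve fitting.

Each biomarker's group-mean response over the acute exposure groups
(0, 5, 10, 50 mSv) is fitted with one of three families:

* linear        y = a*x + b
* exponential   y = A*exp(R0*x) + y0
* quadratic     y = intercept + B1*x + B2*x**2

The family per marker is configuration, not model selection: antioxidant
enzymes (GSH, CAT) and the comet tail moment / olive tail moment follow
saturating exponentials, SOD / EPR / DNA% / Hb / RDWs are linear, and MDA
and tail length are quadratic.

Fit diagnostics mirror the conventions of small-n dosimetry practice:
linear fits report the signed Pearson correlation between dose and
response together with its two-sided p-value from the correlation-t
transform; nonlinear fits report the (non-negative) correlation between
observed and fitted responses and a categorical convergence status, since
no meaningful correlation p exists for three constants on four points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .exceptions import (
    DegenerateDesignError,
    FitFailureError,
    InvalidInputError,
)

__all__ = [
    "DosePoint",
    "CalibrationModel",
    "fit_linear",
    "fit_exponential",
    "fit_quadratic",
    "fit_family",
    "pearson_r",
    "correlation_pvalue",
]

#: relative change in residual sum of squares that counts as converged
RSS_TOL = 1e-10
#: iteration cap for the nonlinear solver
MAX_ITER = 500

FAMILIES = ("linear", "exponential", "quadratic")
_CONSTANT_NAMES = {
    "linear": ("a", "b"),
    "exponential": ("A", "R0", "y0"),
    "quadratic": ("intercept", "B1", "B2"),
}


@dataclass(frozen=True)
class DosePoint:
    """One (dose, group-mean response) calibration point."""

    dose: float
    response: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise InvalidInputError(f"dose must be >= 0, got {self.dose}")
        if self.weight <= 0:
            raise InvalidInputError(f"weight must be > 0, got {self.weight}")


@dataclass
class CalibrationModel:
    """A fitted dose-response curve and its diagnostics.

    ``direction`` is 'increasing' or 'decreasing' when the curve is
    monotone over ``dose_domain``; a quadratic whose vertex falls inside
    the domain is flagged 'non-monotone' and only its data-bearing branch
    (the one containing the domain's lower edge) is invertible.
    """

    marker_id: str
    family: str
    constants: dict[str, float]
    dose_domain: tuple[float, float]
    direction: str
    r_value: float | None = None
    p_value: float | None = None
    fit_status: str = "converged"
    constant_errors: dict[str, float] | None = None
    notes: list[str] = field(default_factory=list)

    # -- curve evaluation -------------------------------------------------
    def predict(self, dose):
        """Evaluate the fitted curve at ``dose`` (scalar or array)."""
        x = np.asarray(dose, dtype=float)
        c = self.constants
        if self.family == "linear":
            y = c["a"] * x + c["b"]
        elif self.family == "exponential":
            y = c["A"] * np.exp(c["R0"] * x) + c["y0"]
        elif self.family == "quadratic":
            y = c["intercept"] + c["B1"] * x + c["B2"] * x**2
        else:  # pragma: no cover - guarded at construction
            raise ValueError(f"unknown family {self.family!r}")
        return float(y) if np.isscalar(dose) else y

    def derivative(self, dose: float) -> float:
        c = self.constants
        if self.family == "linear":
            return c["a"]
        if self.family == "exponential":
            return c["A"] * c["R0"] * math.exp(c["R0"] * dose)
        return c["B1"] + 2.0 * c["B2"] * dose

    @property
    def vertex(self) -> float | None:
        """Stationary dose of a quadratic; None for other families or B2=0."""
        if self.family != "quadratic" or self.constants["B2"] == 0:
            return None
        return -self.constants["B1"] / (2.0 * self.constants["B2"])

    def monotone_branch(self) -> tuple[float, float]:
        """The dose interval on which the curve is invertible.

        For monotone models this is the whole fitted domain; for a
        non-monotone quadratic it is clipped at the vertex.
        """
        lo, hi = self.dose_domain
        v = self.vertex
        if self.direction == "non-monotone" and v is not None:
            return (lo, v) if v > lo else (v, hi)
        return (lo, hi)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "marker_id": self.marker_id,
            "family": self.family,
            "constants": dict(self.constants),
            "constant_errors": dict(self.constant_errors) if self.constant_errors else None,
            "dose_domain": list(self.dose_domain),
            "direction": self.direction,
            "r_value": self.r_value,
            "p_value": self.p_value,
            "fit_status": self.fit_status,
            "notes": list(self.notes),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        return cls(
            marker_id=d["marker_id"],
            family=d["family"],
            constants=dict(d["constants"]),
            dose_domain=tuple(d["dose_domain"]),
            direction=d["direction"],
            r_value=d.get("r_value"),
            p_value=d.get("p_value"),
            fit_status=d.get("fit_status", "converged"),
            constant_errors=dict(d["constant_errors"]) if d.get("constant_errors") else None,
            notes=list(d.get("notes", [])),
        )


# ---------------------------------------------------------------------------
# correlation diagnostics
# ---------------------------------------------------------------------------

def pearson_r(xs: Sequence[float], ys: Sequence[float]) -> float:
    """Product-moment correlation; raises on zero variance."""
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.shape != y.shape:
        raise InvalidInputError("xs and ys must have equal length")
    if x.size < 3:
        raise InvalidInputError("need at least 3 points for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InvalidInputError("correlation undefined for zero-variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    return max(-1.0, min(1.0, r))


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided significance of a correlation on n points.

    Uses the exact small-sample transform t = r*sqrt(n-2)/sqrt(1-r^2)
    referred to Student's t with n-2 degrees of freedom.  |r| = 1 returns
    0 by continuity.
    """
    if n < 3:
        raise InvalidInputError(f"need n >= 3, got {n}")
    if not math.isfinite(r) or abs(r) > 1:
        raise InvalidInputError(f"correlation must lie in [-1, 1], got {r}")
    if abs(r) == 1.0:
        return 0.0
    t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), n - 2))


# ---------------------------------------------------------------------------
# fitting helpers
# ---------------------------------------------------------------------------

def _xyw(points: Sequence[DosePoint]):
    x = np.array([p.dose for p in points], dtype=float)
    y = np.array([p.response for p in points], dtype=float)
    w = np.array([p.weight for p in points], dtype=float)
    return x, y, w


def _domain(x: np.ndarray) -> tuple[float, float]:
    return (float(x.min()), float(x.max()))


def _obs_fit_r(y: np.ndarray, yhat: np.ndarray) -> float | None:
    """Correlation between observed and fitted values; None if degenerate."""
    if np.ptp(y) == 0 or np.ptp(yhat) == 0:
        return None
    rss = float(np.sum((y - yhat) ** 2))
    if rss <= 1e-24 * max(1.0, float(np.sum(y**2))):
        return 1.0
    return float(np.corrcoef(y, yhat)[0, 1])


# ---------------------------------------------------------------------------
# family fitters
# ---------------------------------------------------------------------------

def fit_linear(points: Sequence[DosePoint], marker_id: str = "") -> CalibrationModel:
    """Ordinary (optionally weighted) least-squares line y = a*x + b."""
    x, y, w = _xyw(points)
    if x.size < 2 or np.unique(x).size < 2:
        raise DegenerateDesignError("linear fit needs >= 2 distinct doses")

    coeffs, cov = _polyfit_with_cov(x, y, w, deg=1)
    a, b = float(coeffs[1]), float(coeffs[0])

    notes: list[str] = []
    errors: dict[str, float] | None = None
    if cov is not None:
        errors = {"a": math.sqrt(cov[1, 1]), "b": math.sqrt(cov[0, 0])}
    else:
        notes.append("exact fit: standard errors undefined")

    if np.ptp(y) == 0:
        r_value, p_value, status = None, None, "zero-variance"
        notes.append("zero response variance: correlation undefined")
    else:
        r_value = pearson_r(x, y) if x.size >= 3 else None
        p_value = (
            correlation_pvalue(r_value, x.size) if r_value is not None else None
        )
        status = "converged" if x.size > 2 else "exact"

    direction = "increasing" if a > 0 else ("decreasing" if a < 0 else "flat")
    return CalibrationModel(
        marker_id=marker_id,
        family="linear",
        constants={"a": a, "b": b},
        dose_domain=_domain(x),
        direction=direction,
        r_value=r_value,
        p_value=p_value,
        fit_status=status,
        constant_errors=errors,
        notes=notes,
    )


def _polyfit_with_cov(x, y, w, deg):
    """Weighted polynomial LSQ returning ascending coefficients and covariance."""
    sw = np.sqrt(w)
    X = np.vander(x, deg + 1, increasing=True)
    Xw = X * sw[:, None]
    yw = y * sw
    coeffs, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    dof = x.size - (deg + 1)
    if dof <= 0:
        return coeffs, None
    resid = yw - Xw @ coeffs
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(Xw.T @ Xw)
    return coeffs, cov


def _exp_initial_guess(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Deterministic start for y = A*exp(R0*x) + y0.

    The asymptote y0 is seeded from the response at the largest dose,
    nudged 1% of the response range away from the zero-dose response so
    the log arguments stay one-signed; A follows from the zero-dose
    response and R0 from the slope of log|y - y0| against dose.
    """
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    span = float(np.ptp(ys))
    if span == 0:
        raise FitFailureError(
            "all responses equal: rate constant unidentifiable",
            status="degenerate",
        )
    sign = 1.0 if ys[-1] > ys[0] else -1.0  # approach asymptote from below/above
    y0 = ys[-1] + sign * 0.01 * span
    a0 = ys[0] - y0
    z = np.log(np.abs(ys - y0))
    slope = np.polyfit(xs, z, 1)[0]
    r0 = float(slope) if slope != 0 else -1.0 / max(float(xs[-1]), 1.0)
    return np.array([a0, r0, y0], dtype=float)


def fit_exponential(points: Sequence[DosePoint], marker_id: str = "") -> CalibrationModel:
    """Nonlinear least squares for y = A*exp(R0*x) + y0 (Levenberg-Marquardt)."""
    x, y, w = _xyw(points)
    if x.size < 3 or np.unique(x).size < 3:
        raise DegenerateDesignError(
            "exponential fit needs >= 3 distinct doses for 3 constants"
        )
    p0 = _exp_initial_guess(x, y)
    sw = np.sqrt(w)

    def resid(p):
        a, r0, y0 = p
        return sw * (a * np.exp(r0 * x) + y0 - y)

    result = optimize.least_squares(
        resid,
        p0,
        method="lm",
        ftol=RSS_TOL * 1e-2,
        xtol=1e-14,
        gtol=1e-14,
        max_nfev=MAX_ITER * 4,
    )
    if not result.success:
        raise FitFailureError(
            f"exponential fit did not converge: {result.message}",
            last_params=dict(zip(_CONSTANT_NAMES["exponential"], result.x)),
            status="not-converged",
        )
    a, r0, y0 = (float(v) for v in result.x)
    yhat = a * np.exp(r0 * x) + y0

    errors = None
    dof = x.size - 3
    if dof > 0:
        jac = result.jac
        s2 = float(2.0 * result.cost) / dof
        try:
            cov = s2 * np.linalg.inv(jac.T @ jac)
            diag = np.maximum(np.diag(cov), 0.0)  # guard round-off negatives
            errors = dict(zip(_CONSTANT_NAMES["exponential"], np.sqrt(diag)))
        except np.linalg.LinAlgError:
            errors = None

    d = a * r0  # derivative sign is constant in x
    direction = "increasing" if d > 0 else ("decreasing" if d < 0 else "flat")
    return CalibrationModel(
        marker_id=marker_id,
        family="exponential",
        constants={"A": a, "R0": r0, "y0": y0},
        dose_domain=_domain(x),
        direction=direction,
        r_value=_obs_fit_r(y, yhat),
        p_value=None,
        fit_status="converged" if dof > 0 else "exact",
        constant_errors=errors,
    )


def fit_quadratic(points: Sequence[DosePoint], marker_id: str = "") -> CalibrationModel:
    """Least-squares parabola y = intercept + B1*x + B2*x^2.

    The vertex -B1/(2*B2) is recorded; if it falls strictly inside the
    fitted dose domain the model is flagged non-monotone and inversion is
    restricted to the branch containing the domain's lower edge.
    """
    x, y, w = _xyw(points)
    if x.size < 3 or np.unique(x).size < 3:
        raise DegenerateDesignError("quadratic fit needs >= 3 distinct doses")
    coeffs, cov = _polyfit_with_cov(x, y, w, deg=2)
    intercept, b1, b2 = (float(c) for c in coeffs)
    yhat = intercept + b1 * x + b2 * x**2

    errors = None
    notes: list[str] = []
    if cov is not None:
        errors = {
            "intercept": math.sqrt(cov[0, 0]),
            "B1": math.sqrt(cov[1, 1]),
            "B2": math.sqrt(cov[2, 2]),
        }
    else:
        notes.append("exact fit: standard errors undefined")

    lo, hi = _domain(x)
    d_lo = b1 + 2 * b2 * lo
    d_hi = b1 + 2 * b2 * hi
    if b2 != 0 and lo < -b1 / (2 * b2) < hi:
        direction = "non-monotone"
        vertex = -b1 / (2 * b2)
        notes.append(
            f"vertex at {vertex:.4g} mSv lies inside the dose domain; "
            f"inversion restricted to the branch containing {lo:g} mSv"
        )
    elif d_lo > 0 or d_hi > 0:
        direction = "increasing"
    elif d_lo < 0 or d_hi < 0:
        direction = "decreasing"
    else:
        direction = "flat"

    return CalibrationModel(
        marker_id=marker_id,
        family="quadratic",
        constants={"intercept": intercept, "B1": b1, "B2": b2},
        dose_domain=(lo, hi),
        direction=direction,
        r_value=_obs_fit_r(y, yhat),
        p_value=None,
        fit_status="converged" if x.size > 3 else "exact",
        constant_errors=errors,
        notes=notes,
    )


_FITTERS = {
    "linear": fit_linear,
    "exponential": fit_exponential,
    "quadratic": fit_quadratic,
}


def fit_family(
    family: str, points: Sequence[DosePoint], marker_id: str = ""
) -> CalibrationModel:
    """Dispatch to the fitter for ``family`` ('linear'/'exponential'/'quadratic')."""
    try:
        fitter = _FITTERS[family]
    except KeyError:
        raise InvalidInputError(
            f"unknown family {family!r}; expected one of {FAMILIES}"
        ) from None
    return fitter(points, marker_id=marker_id)
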