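"""Synthetic study generator with known ground truth.

Generates a complete in-silico version of the rat study — 7 groups x 11
markers x n animals — from known calibration curves, so every pipeline
stage can be tested against the truth that produced the data.

Generating model, per marker:

* acute/control groups: per-animal readings are drawn i.i.d. from a
  Normal centred on the curve value g(dose) with SD = CV * g(dose),
  truncated at zero (biomarker readings cannot be negative);
* the challenge-only group is centred on g(D_c);
* each combined (priming+challenge) group is centred on g(D_eff), where
  the effective dose D_eff = D_p + (1 - f*) * D_{p+c} encodes the chosen
  true adaptation factor f*.  Recovering f* through calibration,
  inversion and the RAR-factor formula is then an identity in the
  noiseless limit.

Defaults are the reference study's printed constants and RAR factors at
a replicate coefficient of variation of 0.05, so a default simulation
resembles the real study.  The generator encodes no repair kinetics or
time course: adaptation is purely an effective-dose shift.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import reference
from .calibration import CalibrationModel
from .core import effective_dose_from_factor
from .exceptions import ConfigError
from .study import StudyDesign, default_design

__all__ = ["MarkerSpec", "SyntheticConfig", "GroundTruth", "generate_study",
           "generate_group_readings", "default_markers"]

#: dose span of the generating curves (mSv)
CURVE_DOMAIN = (0.0, 50.0)


@dataclass(frozen=True)
class MarkerSpec:
    """Generating curve, noise and adaptation strengths for one marker."""

    marker_id: str
    family: str
    constants: dict[str, float]
    cv: float = 0.05
    adaptation: dict[str, float] = field(default_factory=dict)  # condition label -> f*
    units: str = ""

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ConfigError(f"{self.marker_id}: CV must be >= 0, got {self.cv}")
        for label, f in self.adaptation.items():
            if not np.isfinite(f):
                raise ConfigError(f"{self.marker_id}: adaptation factor at {label} not finite")

    def curve(self) -> CalibrationModel:
        """The generating curve as an evaluable model over [0, 50] mSv."""
        model = CalibrationModel(
            marker_id=self.marker_id,
            family=self.family,
            constants=dict(self.constants),
            dose_domain=CURVE_DOMAIN,
            direction="increasing",
            fit_status="ground-truth",
        )
        lo, hi = CURVE_DOMAIN
        d_lo, d_hi = model.derivative(lo), model.derivative(hi)
        if d_lo > 0 and d_hi > 0:
            model.direction = "increasing"
        elif d_lo < 0 and d_hi < 0:
            model.direction = "decreasing"
        else:
            v = model.vertex
            if v is None or not (lo < v < hi):
                raise ConfigError(
                    f"{self.marker_id}: generating curve is not monotone on "
                    f"[{lo:g}, {hi:g}] mSv"
                )
            model.direction = "non-monotone"
            model.notes.append(
                f"quadratic vertex at {v:.4g} mSv inside the dose domain; "
                f"usable branch is [{lo:g}, {v:.4g}]"
            )
        return model


def default_markers(cv: float = 0.05) -> dict[str, MarkerSpec]:
    """The 11 RAR markers with the reference study's curves and factors."""
    markers = {}
    for m in reference.RAR_MARKERS:
        entry = reference.CALIBRATION_CONSTANTS[m]
        markers[m] = MarkerSpec(
            marker_id=m,
            family=entry["family"],
            constants=dict(entry["constants"]),
            cv=cv,
            adaptation={
                label: reference.REFERENCE_RARF[label][m]
                for label in reference.CONDITIONS
            },
            units=reference.MARKER_UNITS.get(m, ""),
        )
    return markers


@dataclass
class SyntheticConfig:
    """Full specification of one synthetic study."""

    design: StudyDesign = field(default_factory=default_design)
    markers: dict[str, MarkerSpec] = field(default_factory=default_markers)
    n_animals: int | None = None  # None: use each group's own n
    seed: int = 0


@dataclass
class GroundTruth:
    """What the generator knew: curves, true factors, effective doses, seed."""

    seed: int
    markers: dict[str, dict]
    conditions: dict[str, dict[str, dict]]  # label -> marker -> {factor, effective_dose}

    def to_dict(self) -> dict:
        return {"seed": self.seed, "markers": self.markers, "conditions": self.conditions}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(seed=d["seed"], markers=d["markers"], conditions=d["conditions"])


def generate_group_readings(
    marker: MarkerSpec,
    dose: float,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """n i.i.d. truncated-normal readings around the curve value at ``dose``."""
    if n < 1:
        raise ConfigError(f"need n >= 1 animals, got {n}")
    curve = marker.curve()
    lo, hi = curve.dose_domain
    if not (lo <= dose <= hi):
        warnings.warn(
            f"{marker.marker_id}: dose {dose:g} mSv outside the generating "
            f"curve domain [{lo:g}, {hi:g}]; mean extrapolated",
            stacklevel=2,
        )
    mean = float(curve.predict(dose))
    if marker.cv == 0:
        return np.full(n, mean)
    if mean <= 0:
        raise ConfigError(
            f"{marker.marker_id}: curve value {mean:g} at {dose:g} mSv is not "
            "positive; multiplicative noise undefined"
        )
    sd = marker.cv * mean
    a = (0.0 - mean) / sd  # truncate at zero
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)


def generate_study(config: SyntheticConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate the whole study; deterministic given ``config.seed``.

    Returns the per-animal readings table (marker_id, group_id,
    animal_index, value, units) and the :class:`GroundTruth` oracle.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    conditions: dict[str, dict[str, dict]] = {}

    for group in config.design:
        n = config.n_animals if config.n_animals is not None else group.n_animals
        for marker in config.markers.values():
            if group.role == "combined":
                label = group.condition.label
                f_true = marker.adaptation.get(label)
                if f_true is None:
                    raise ConfigError(
                        f"{marker.marker_id}: no adaptation factor configured "
                        f"for condition {label}"
                    )
                dose = effective_dose_from_factor(f_true, group.condition)
                _check_on_branch(marker, dose)
                conditions.setdefault(label, {})[marker.marker_id] = {
                    "factor": f_true,
                    "effective_dose": dose,
                }
            elif group.role == "rar_control":
                dose = group.challenge_dose
            else:
                dose = group.single_dose
            values = generate_group_readings(marker, dose, n, rng)
            rows.extend(
                {
                    "marker_id": marker.marker_id,
                    "group_id": group.group_id,
                    "animal_index": i + 1,
                    "value": float(v),
                    "units": marker.units,
                }
                for i, v in enumerate(values)
            )

    truth = GroundTruth(
        seed=config.seed,
        markers={
            m.marker_id: {"family": m.family, "constants": dict(m.constants), "cv": m.cv}
            for m in config.markers.values()
        },
        conditions=conditions,
    )
    return pd.DataFrame(rows), truth


def _check_on_branch(marker: MarkerSpec, dose: float) -> None:
    """Refuse effective doses that fall past a quadratic's vertex.

    Beyond the vertex the curve doubles back, so the encoded adaptation
    could never be recovered by inversion — a configuration error, not a
    data property.
    """
    curve = marker.curve()
    v = curve.vertex
    if curve.direction == "non-monotone" and v is not None and dose > v:
        raise ConfigError(
            f"{marker.marker_id}: effective dose {dose:.4g} mSv lies beyond "
            f"the quadratic vertex at {v:.4g} mSv; the adaptation factor is "
            "unrecoverable on the data-bearing branch"
        )
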