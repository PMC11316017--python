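"""End-to-end radio-adaptive response analysis.

The pipeline turns a table of per-animal biomarker readings and a study
design into:

1. per-(marker, group) summaries (mean, n-1 SD, n);
2. one fitted calibration curve per marker over the acute groups;
3. per marker x condition RAR estimates: the combined group's mean is
   inverted through the curve to a RAR equivalent dose (RARED), the RAR
   factor follows from the defining formula, and the priming-dose
   difference delta contrasts the combined group with the challenge-only
   group;
4. the aggregate RAR table (per-condition mean and n-1 SD over markers);
5. Welch t-tests of every exposed group against the sham control.

Markers with no configured calibration family (e.g. hematocrit and MCHC,
whose dose response merely fluctuates) pass through summaries and
significance testing but get no RAR row.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import reference
from .calibration import CalibrationModel, DosePoint, fit_family
from .core import DoseCondition, priming_delta, rar_factor
from .exceptions import (
    ExtrapolationError,
    IncompleteDesignError,
    InvalidInputError,
    InversionDomainError,
    MissingDataError,
    UnreachableReadingError,
)
from .inversion import invert_dose
from .reporting import round_half_away
from .study import GroupSpec, StudyDesign

__all__ = [
    "MarkerSummary",
    "RarEstimate",
    "RarTable",
    "StudyResults",
    "summarize_groups",
    "build_calibration_set",
    "fit_calibrations",
    "compute_rar_row",
    "aggregate_rar_table",
    "significance_vs_control",
    "run_study",
    "default_families",
]

READING_COLUMNS = ["marker_id", "group_id", "animal_index", "value", "units"]


@dataclass(frozen=True)
class MarkerSummary:
    marker_id: str
    group_id: str
    mean: float
    sd: float  # NaN for n == 1
    n: int


@dataclass(frozen=True)
class RarEstimate:
    """One RAR table cell: a marker under one priming+challenge condition."""

    marker_id: str
    condition: DoseCondition
    reading_used: float
    rared: float
    factor: float
    delta: float
    in_domain: bool = True
    notes: str = ""


@dataclass
class RarTable:
    """Per-condition rows of RAR estimates with aggregate statistics."""

    conditions: list[DoseCondition]
    estimates: list[RarEstimate]
    annotations: list[str] = field(default_factory=list)

    def row(self, condition: DoseCondition) -> list[RarEstimate]:
        return [e for e in self.estimates if e.condition == condition]

    def row_stats(self, condition: DoseCondition) -> dict[str, float]:
        row = self.row(condition)
        rared = np.array([e.rared for e in row], dtype=float)
        fac = np.array([e.factor for e in row], dtype=float)
        sd = (
            {"rared_sd": float(np.std(rared, ddof=1)), "factor_sd": float(np.std(fac, ddof=1))}
            if len(row) >= 2
            else {"rared_sd": float("nan"), "factor_sd": float("nan")}
        )
        return {
            "rared_mean": float(np.mean(rared)),
            "factor_mean": float(np.mean(fac)),
            **sd,
        }

    def to_frame(self, rounded: bool = False) -> pd.DataFrame:
        """Wide report: one RARED row and one RARF row per condition.

        ``rounded`` applies the report convention (doses at 1 decimal,
        factors at 2) using half-away-from-zero rounding.
        """
        rows = []
        for cond in self.conditions:
            row = {e.marker_id: e.rared for e in self.row(cond)}
            st = self.row_stats(cond)
            rows.append({"condition": cond.label, "quantity": "RARED",
                         **row, "average": st["rared_mean"], "sd": st["rared_sd"]})
            frow = {e.marker_id: e.factor for e in self.row(cond)}
            rows.append({"condition": cond.label, "quantity": "RARF",
                         **frow, "average": st["factor_mean"], "sd": st["factor_sd"]})
        frame = pd.DataFrame(rows)
        if rounded:
            num = frame.columns.difference(["condition", "quantity"])
            for i in frame.index:
                nd = 1 if frame.loc[i, "quantity"] == "RARED" else 2
                frame.loc[i, num] = [
                    round_half_away(v, nd) if pd.notna(v) else v
                    for v in frame.loc[i, num]
                ]
        return frame


@dataclass
class StudyResults:
    """Everything the pipeline produces for one study."""

    summaries: pd.DataFrame
    calibrations: dict[str, CalibrationModel]
    rar_table: RarTable
    significance: pd.DataFrame


# ---------------------------------------------------------------------------
# stage 1: summaries
# ---------------------------------------------------------------------------

def summarize_groups(
    readings: pd.DataFrame,
    expected_groups: list[str] | None = None,
    expected_markers: list[str] | None = None,
) -> pd.DataFrame:
    """Per-(marker, group) mean, n-1 sample SD and count.

    SD is NaN for single-animal cells.  When expectations are given,
    every (marker, group) cell must be populated.
    """
    _check_readings(readings)
    g = readings.groupby(["marker_id", "group_id"], sort=False)["value"]
    out = g.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count").reset_index()

    if expected_groups is not None and expected_markers is not None:
        have = {(m, gid) for m, gid in zip(out["marker_id"], out["group_id"])}
        missing = [
            f"({m}, {gid})"
            for m in expected_markers
            for gid in expected_groups
            if (m, gid) not in have
        ]
        if missing:
            raise MissingDataError(
                "no readings for cell(s): " + ", ".join(missing)
            )
    return out


def _check_readings(readings: pd.DataFrame) -> None:
    needed = {"marker_id", "group_id", "value"}
    missing = needed - set(readings.columns)
    if missing:
        raise InvalidInputError(f"readings table lacks column(s) {sorted(missing)}")
    if len(readings) == 0:
        raise MissingDataError("readings table is empty")


def _cell(summaries: pd.DataFrame, marker_id: str, group_id: str) -> MarkerSummary:
    sel = summaries[
        (summaries["marker_id"] == marker_id) & (summaries["group_id"] == group_id)
    ]
    if len(sel) == 0:
        raise MissingDataError(f"no summary for cell ({marker_id}, {group_id})")
    r = sel.iloc[0]
    return MarkerSummary(marker_id, group_id, float(r["mean"]), float(r["sd"]), int(r["n"]))


# ---------------------------------------------------------------------------
# stage 2: calibration sets and fits
# ---------------------------------------------------------------------------

def build_calibration_set(
    summaries: pd.DataFrame, design: StudyDesign
) -> dict[str, list[DosePoint]]:
    """One (dose, group-mean) point per acute group per marker.

    Combined and challenge-only groups never enter the fit.  A design
    without a zero-dose group is accepted with a warning; a design with
    no acute groups at all is refused.
    """
    acute = design.acute_groups()
    if not acute:
        raise IncompleteDesignError("design has no acute (single-dose) groups")
    if not any(g.single_dose == 0 for g in acute):
        warnings.warn(
            "design has no zero-dose group; curves are anchored only by "
            "irradiated groups",
            stacklevel=2,
        )
    points: dict[str, list[DosePoint]] = {}
    for marker_id in summaries["marker_id"].unique():
        pts = []
        for g in acute:
            cell = _cell(summaries, marker_id, g.group_id)
            pts.append(DosePoint(dose=g.single_dose, response=cell.mean))
        points[str(marker_id)] = pts
    return points


def default_families() -> dict[str, str]:
    """The marker -> family map of the reference study."""
    return {m: v["family"] for m, v in reference.CALIBRATION_CONSTANTS.items()}


def fit_calibrations(
    summaries: pd.DataFrame,
    design: StudyDesign,
    families: dict[str, str] | None = None,
) -> dict[str, CalibrationModel]:
    """Fit the configured family per marker; markers without one are skipped."""
    families = default_families() if families is None else families
    points = build_calibration_set(summaries, design)
    models: dict[str, CalibrationModel] = {}
    for marker_id, pts in points.items():
        family = families.get(marker_id)
        if family is None:
            continue
        models[marker_id] = fit_family(family, pts, marker_id=marker_id)
    return models


# ---------------------------------------------------------------------------
# stage 3: RAR rows
# ---------------------------------------------------------------------------

def compute_rar_row(
    marker_id: str,
    model: CalibrationModel,
    summaries: pd.DataFrame,
    condition: DoseCondition,
    design: StudyDesign,
) -> RarEstimate:
    """RARED / RARF / delta for one marker under one combined condition.

    The combined group's mean reading is inverted through the acute
    calibration curve (the reference study inverts a group summary, not
    per-animal replicates).
    """
    combined = _group_for_condition(design, condition)
    rar_control = design.rar_control_for(condition.challenge_dose)
    reading = _cell(summaries, marker_id, combined.group_id).mean
    n_c = _cell(summaries, marker_id, rar_control.group_id).mean

    try:
        inv = invert_dose(model, reading)
    except Exception as exc:
        raise type(exc)(
            f"{marker_id} at {condition.label}: {exc}"
        ) from exc
    result = rar_factor(inv.dose, condition)
    return RarEstimate(
        marker_id=marker_id,
        condition=condition,
        reading_used=reading,
        rared=inv.dose,
        factor=result.factor,
        delta=priming_delta(reading, n_c),
        in_domain=inv.in_domain,
        notes=inv.branch_note,
    )


def _group_for_condition(design: StudyDesign, condition: DoseCondition) -> GroupSpec:
    for g in design.combined_groups():
        if (g.priming_dose, g.challenge_dose) == (
            condition.priming_dose,
            condition.challenge_dose,
        ):
            return g
    raise IncompleteDesignError(
        f"design has no combined group for condition {condition.label}"
    )


def aggregate_rar_table(
    estimates: list[RarEstimate], annotations: list[str] | None = None
) -> RarTable:
    """Collect estimates into per-condition rows with mean and n-1 SD."""
    conditions: list[DoseCondition] = []
    for e in estimates:
        if e.condition not in conditions:
            conditions.append(e.condition)
    return RarTable(
        conditions=conditions,
        estimates=list(estimates),
        annotations=list(annotations or []),
    )


# ---------------------------------------------------------------------------
# stage 4: significance
# ---------------------------------------------------------------------------

def significance_vs_control(
    readings: pd.DataFrame, control_group: str = "G1"
) -> pd.DataFrame:
    """Welch two-sided t-test of every exposed group against the control.

    Returns one row per (marker, group) with the p-value and a flag at
    the p <= 0.05 working threshold.  No multiple-testing correction is
    applied.
    """
    _check_readings(readings)
    rows = []
    for marker_id, sub in readings.groupby("marker_id", sort=False):
        ctrl = sub.loc[sub["group_id"] == control_group, "value"].to_numpy(float)
        if ctrl.size < 2:
            raise MissingDataError(
                f"control group {control_group} has fewer than 2 readings "
                f"for marker {marker_id}"
            )
        for group_id, cell in sub.groupby("group_id", sort=False):
            if group_id == control_group:
                continue
            vals = cell["value"].to_numpy(float)
            if vals.size < 2:
                raise MissingDataError(
                    f"group {group_id} has fewer than 2 readings for {marker_id}"
                )
            if np.array_equal(vals, ctrl):
                p = 1.0  # identical samples: no evidence of difference
            elif np.ptp(vals) == 0 and np.ptp(ctrl) == 0:
                # degenerate zero-variance cells (noiseless simulations)
                p = 1.0 if vals[0] == ctrl[0] else 0.0
            else:
                p = float(stats.ttest_ind(vals, ctrl, equal_var=False).pvalue)
            rows.append(
                {
                    "marker_id": marker_id,
                    "group_id": group_id,
                    "p_value": p,
                    "significant": p <= 0.05,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_study(
    readings: pd.DataFrame,
    design: StudyDesign,
    families: dict[str, str] | None = None,
) -> StudyResults:
    """The full analysis: summaries -> calibration -> RAR table -> tests."""
    families = default_families() if families is None else families
    markers = [str(m) for m in readings["marker_id"].unique()]
    summaries = summarize_groups(
        readings, expected_groups=design.group_ids, expected_markers=markers
    )
    models = fit_calibrations(summaries, design, families)

    annotations = [
        f"{m}: {note}"
        for m, model in models.items()
        for note in model.notes
    ]
    skipped = [m for m in markers if m not in models]
    if skipped:
        annotations.append(
            "no calibration family configured (excluded from RAR rows): "
            + ", ".join(skipped)
        )

    estimates = []
    for g in design.combined_groups():
        condition = g.condition
        for marker_id in markers:
            if marker_id not in models:
                continue
            try:
                est = compute_rar_row(
                    marker_id, models[marker_id], summaries, condition, design
                )
            except (InversionDomainError, UnreachableReadingError, ExtrapolationError) as exc:
                # a noisy curve can place a reading outside its invertible
                # range; the cell is dropped and the failure reported
                annotations.append(f"dropped cell: {exc}")
                continue
            if est.notes:
                annotations.append(f"{marker_id} at {condition.label}: {est.notes}")
            estimates.append(est)

    control = design.control_group().group_id
    return StudyResults(
        summaries=summaries,
        calibrations=models,
        rar_table=aggregate_rar_table(estimates, annotations),
        significance=significance_vs_control(readings, control),
    )
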