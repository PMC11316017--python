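"""Study file formats: readings.csv, design.yaml, config.yaml and outputs.

One dialect throughout: comma-separated UTF-8 text with a header row and
dot decimal separator; doses are always equivalent doses in mSv, carried
in the column name (``priming_dose_mSv``) rather than per row.

Validation is eager and exhaustive: :func:`read_study` collects every
cross-reference violation (unknown group ids, negative doses, role/dose
inconsistencies, mixed units within a marker) and raises one
:class:`~rardose.exceptions.ValidationError` listing all of them.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .calibration import FAMILIES, CalibrationModel
from .exceptions import ValidationError
from .pipeline import READING_COLUMNS, RarTable, StudyResults, default_families
from .study import StudyDesign

__all__ = [
    "read_readings",
    "read_design",
    "read_config",
    "read_study",
    "write_study",
    "write_calibrations",
    "read_calibrations",
    "write_results",
]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_readings(path) -> pd.DataFrame:
    """Read a per-animal readings table (marker_id, group_id, animal_index, value, units)."""
    frame = pd.read_csv(path)
    missing = [c for c in READING_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(
            [f"{path}: readings file lacks column(s) {missing}"]
        )
    return frame[READING_COLUMNS]


def read_design(path) -> StudyDesign:
    """Read a YAML study design (a ``groups:`` list of per-group records)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "groups" not in doc:
        raise ValidationError([f"{path}: design file must contain a 'groups' list"])
    return StudyDesign.from_rows(doc["groups"])


def read_config(path) -> dict:
    """Read the analysis config (marker -> family map plus options)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    families = doc.get("families", {})
    bad = [f"{m}: unknown family {fam!r}" for m, fam in families.items()
           if fam not in FAMILIES]
    if bad:
        raise ValidationError([f"{path}: {b}" for b in bad])
    return doc


def read_study(
    readings_path, design_path, config_path=None
) -> tuple[pd.DataFrame, StudyDesign, dict]:
    """Read and cross-validate a complete study.

    Returns (readings, design, config).  When no config file is given the
    reference study's marker->family map is used.
    """
    readings = read_readings(readings_path)
    design = read_design(design_path)
    config = read_config(config_path) if config_path else {"families": default_families()}

    violations: list[str] = []
    known = set(design.group_ids)
    for gid in readings["group_id"].unique():
        if gid not in known:
            violations.append(f"readings reference unknown group id {gid!r}")
    for marker_id, sub in readings.groupby("marker_id", sort=False):
        units = sub["units"].dropna().unique()
        if len(units) > 1:
            violations.append(
                f"marker {marker_id!r} mixes units: {sorted(map(str, units))}"
            )
    bad_values = readings["value"].isna()
    for idx in readings.index[bad_values]:
        violations.append(f"readings row {idx}: missing value")
    if violations:
        raise ValidationError(violations)
    return readings, design, config


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_study(
    out_dir, readings: pd.DataFrame, design: StudyDesign, config: dict | None = None
) -> dict[str, Path]:
    """Write readings.csv, design.yaml and config.yaml under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "readings": out / "readings.csv",
        "design": out / "design.yaml",
        "config": out / "config.yaml",
    }
    readings[READING_COLUMNS].to_csv(paths["readings"], index=False)
    with open(paths["design"], "w") as fh:
        yaml.safe_dump({"groups": design.to_rows()}, fh, sort_keys=False)
    if config is None:
        config = {"families": default_families()}
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return paths


def write_calibrations(path, models: dict[str, CalibrationModel]) -> None:
    doc = {m: model.to_dict() for m, model in models.items()}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_calibrations(path) -> dict[str, CalibrationModel]:
    with open(path) as fh:
        doc = json.load(fh)
    return {m: CalibrationModel.from_dict(d) for m, d in doc.items()}


def write_results(out_dir, results: StudyResults) -> dict[str, Path]:
    """Write summaries.csv, calibration.json, significance.csv, rar_table.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "summaries": out / "summaries.csv",
        "calibration": out / "calibration.json",
        "significance": out / "significance.csv",
        "rar_table": out / "rar_table.csv",
        "annotations": out / "annotations.txt",
    }
    results.summaries.to_csv(paths["summaries"], index=False)
    write_calibrations(paths["calibration"], results.calibrations)
    results.significance.to_csv(paths["significance"], index=False)
    _write_rar_table(paths["rar_table"], results.rar_table)
    with open(paths["annotations"], "w") as fh:
        for line in results.rar_table.annotations:
            fh.write(line + "\n")
    return paths


def _write_rar_table(path, table: RarTable) -> None:
    table.to_frame(rounded=True).to_csv(path, index=False)
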