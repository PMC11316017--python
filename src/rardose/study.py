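"""Study-design data model: groups, roles, and dose conditions.

A study is a set of exposure groups.  Roles encode how each group enters
the analysis:

* ``control``      sham, no irradiation (dose 0); anchors the curves
* ``acute``        a single acute dose; calibration point
* ``rar_control``  challenge dose only; denominator of the delta contrast
* ``combined``     priming then challenge; the group whose reading is
                   inverted to a RAR equivalent dose

Roles must be consistent with the doses (a combined group has both doses
positive, etc.); the file reader enforces this eagerly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import DoseCondition
from .exceptions import IncompleteDesignError, ValidationError
from . import reference

__all__ = ["GroupSpec", "StudyDesign", "ROLES", "default_design"]

ROLES = ("control", "acute", "rar_control", "combined")


@dataclass(frozen=True)
class GroupSpec:
    """One exposure group of the irradiation plan."""

    group_id: str
    role: str
    priming_dose: float
    challenge_dose: float
    interval_days: float | None = None
    readout_hr: float = 24.0
    n_animals: int = 5

    @property
    def single_dose(self) -> float:
        """The acute dose of a single-exposure group (priming or challenge)."""
        return self.priming_dose if self.challenge_dose == 0 else self.challenge_dose

    @property
    def condition(self) -> DoseCondition:
        return DoseCondition(self.priming_dose, self.challenge_dose)

    def role_violations(self) -> list[str]:
        """Role/dose consistency problems, empty when the spec is coherent."""
        p, c = self.priming_dose, self.challenge_dose
        problems = []
        if self.role not in ROLES:
            problems.append(f"group {self.group_id}: unknown role {self.role!r}")
            return problems
        expected = {
            "control": p == 0 and c == 0,
            "acute": p > 0 and c == 0,
            "rar_control": p == 0 and c > 0,
            "combined": p > 0 and c > 0,
        }[self.role]
        if not expected:
            problems.append(
                f"group {self.group_id}: role {self.role!r} inconsistent with "
                f"doses ({p:g}, {c:g}) mSv"
            )
        if p < 0 or c < 0:
            problems.append(f"group {self.group_id}: negative dose")
        return problems


@dataclass
class StudyDesign:
    """An ordered collection of groups with lookup helpers."""

    groups: list[GroupSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        violations = []
        seen = set()
        for g in self.groups:
            if g.group_id in seen:
                violations.append(f"duplicate group id {g.group_id}")
            seen.add(g.group_id)
            violations.extend(g.role_violations())
        if violations:
            raise ValidationError(violations)

    def __iter__(self):
        return iter(self.groups)

    def __len__(self) -> int:
        return len(self.groups)

    @property
    def group_ids(self) -> list[str]:
        return [g.group_id for g in self.groups]

    def group(self, group_id: str) -> GroupSpec:
        for g in self.groups:
            if g.group_id == group_id:
                return g
        raise KeyError(group_id)

    def acute_groups(self) -> list[GroupSpec]:
        """Single-acute-dose groups (incl. sham control) used for calibration."""
        return [g for g in self.groups if g.role in ("control", "acute")]

    def combined_groups(self) -> list[GroupSpec]:
        return [g for g in self.groups if g.role == "combined"]

    def control_group(self) -> GroupSpec:
        for g in self.groups:
            if g.role == "control":
                return g
        raise IncompleteDesignError("design has no sham control group")

    def rar_control_for(self, challenge_dose: float) -> GroupSpec:
        """The challenge-only group matching a combined group's challenge dose."""
        for g in self.groups:
            if g.role == "rar_control" and g.challenge_dose == challenge_dose:
                return g
        raise IncompleteDesignError(
            f"no challenge-only (rar_control) group at {challenge_dose:g} mSv"
        )

    # -- serialization ----------------------------------------------------
    def to_rows(self) -> list[dict]:
        return [
            {
                "group_id": g.group_id,
                "role": g.role,
                "priming_dose_mSv": g.priming_dose,
                "challenge_dose_mSv": g.challenge_dose,
                "interval_days": g.interval_days,
                "readout_hr": g.readout_hr,
                "n_animals": g.n_animals,
            }
            for g in self.groups
        ]

    @classmethod
    def from_rows(cls, rows) -> "StudyDesign":
        groups = [
            GroupSpec(
                group_id=str(r["group_id"]),
                role=str(r["role"]),
                priming_dose=float(r.get("priming_dose_mSv", 0.0) or 0.0),
                challenge_dose=float(r.get("challenge_dose_mSv", 0.0) or 0.0),
                interval_days=(
                    None if r.get("interval_days") in (None, "", "null")
                    else float(r["interval_days"])
                ),
                readout_hr=float(r.get("readout_hr", 24) or 24),
                n_animals=int(r.get("n_animals", 5) or 5),
            )
            for r in rows
        ]
        return cls(groups)


def default_design() -> StudyDesign:
    """The seven-group rat irradiation plan (0/5/10/50 mSv acute, 5+50, 10+50)."""
    return StudyDesign.from_rows(reference.DEFAULT_DESIGN_ROWS)
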