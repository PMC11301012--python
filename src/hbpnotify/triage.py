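"""Urgent-notification triage for home blood pressure averages.

A participant's per-period averages are graded against JSH2009-style
hypertension bands (Grade I >= 140/90, Grade II >= 160/100, Grade III
>= 180/110 mmHg, systolic and/or diastolic). A period qualifies for an
urgent notification only when its average rests on at least three retained
measurements and its grade meets the active policy's minimum:

* ``GRADE_II_PLUS`` — notify on Grade II or higher (the system's initial
  operation, October 2013 to June 2014);
* ``GRADE_III_ONLY`` — notify on Grade III only (from July 2014 on, after
  Grade II risk was judged adequately covered by the regular report).

The review-office discussion itself is outside algorithmic scope; the
machine decision is the criteria alone, with a ``reasons`` audit trail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Sequence

from .labs import CategoryFlags
from .readings import PERIODS, PeriodAverage

GRADES = ("none", "grade1", "grade2", "grade3")

POLICY_REVISION_DATE = date(2014, 7, 1)

_CATEGORY_LETTER_LINES = {
    "blood_sugar": "Blood sugar outside the reference range (possible glucose metabolism disorder).",
    "renal": "Renal function values outside the reference range (possible renal dysfunction).",
    "lipid": "Serum lipid values outside the reference range (possible lipid abnormality).",
    "hematological": "Blood cell counts or morphology outside the reference range (possible hematological abnormality).",
    "liver": "Liver enzyme values outside the reference range (possible liver dysfunction).",
}


@dataclass(frozen=True)
class GradeThresholds:
    """Hypertension grade cut-offs in mmHg, met when systolic OR diastolic
    reaches the bound (inclusive ``>=`` comparison)."""

    grade1: tuple[float, float] = (140.0, 90.0)
    grade2: tuple[float, float] = (160.0, 100.0)
    grade3: tuple[float, float] = (180.0, 110.0)

    def __post_init__(self) -> None:
        for lo, hi in zip((self.grade1, self.grade2), (self.grade2, self.grade3)):
            if not (hi[0] > lo[0] and hi[1] > lo[1]):
                raise ValueError("grade thresholds must be strictly increasing")


@dataclass(frozen=True)
class NotificationPolicy:
    """Which grade triggers a letter, and the minimum measurements an
    average must rest on (default 3; averages of two or fewer readings never
    trigger)."""

    label: str = "GRADE_III_ONLY"
    min_measurements: int = 3

    def __post_init__(self) -> None:
        if self.label not in ("GRADE_II_PLUS", "GRADE_III_ONLY"):
            raise ValueError(f"unknown policy label {self.label!r}")
        if self.min_measurements < 1:
            raise ValueError("min_measurements must be >= 1")

    @property
    def min_grade(self) -> str:
        return "grade2" if self.label == "GRADE_II_PLUS" else "grade3"


def policy_for_date(when: date, min_measurements: int = 3) -> NotificationPolicy:
    """Policy active on a calendar date: Grade II+ before July 2014,
    Grade III only from then on."""
    label = "GRADE_II_PLUS" if when < POLICY_REVISION_DATE else "GRADE_III_ONLY"
    return NotificationPolicy(label=label, min_measurements=min_measurements)


@dataclass(frozen=True)
class TriageResult:
    participant_id: str
    triggered: bool
    grade: str  # highest grade among eligible periods; "none" if no eligible period reaches grade1
    qualifying_periods: tuple[str, ...]
    policy: str
    reasons: tuple[str, ...] = field(default_factory=tuple)


def grade_bp(mean_sbp: float, mean_dbp: float, thresholds: GradeThresholds = GradeThresholds()) -> str:
    """Highest grade whose systolic or diastolic threshold the means reach."""
    if mean_sbp <= 0 or mean_dbp <= 0:
        raise ValueError("blood pressure means must be positive")
    for grade_label, (s, d) in (
        ("grade3", thresholds.grade3),
        ("grade2", thresholds.grade2),
        ("grade1", thresholds.grade1),
    ):
        if mean_sbp >= s or mean_dbp >= d:
            return grade_label
    return "none"


def evaluate_notification(
    averages: Sequence[PeriodAverage],
    policy: NotificationPolicy = NotificationPolicy(),
    thresholds: GradeThresholds = GradeThresholds(),
) -> TriageResult:
    """Decide whether a participant's period averages trigger a letter.

    A period qualifies iff it has ``n_used >= policy.min_measurements`` and
    its grade meets the policy minimum. The reported grade is the maximum
    over all eligible (enough-measurement) periods, whether or not it
    triggers.
    """
    pid = averages[0].participant_id if averages else ""
    min_rank = GRADES.index(policy.min_grade)
    reasons: list[str] = []
    qualifying: list[str] = []
    best = "none"
    any_eligible = False
    for avg in averages:
        if avg.n_used == 0 or avg.mean_sbp is None or avg.mean_dbp is None:
            reasons.append(f"{avg.period}: no measurements")
            continue
        grade = grade_bp(avg.mean_sbp, avg.mean_dbp, thresholds)
        if avg.n_used < policy.min_measurements:
            reasons.append(
                f"{avg.period}: {grade} on {avg.n_used} measurement(s) — "
                f"below the {policy.min_measurements}-measurement minimum, ignored"
            )
            continue
        any_eligible = True
        if GRADES.index(grade) > GRADES.index(best):
            best = grade
        if GRADES.index(grade) >= min_rank:
            qualifying.append(avg.period)
            reasons.append(
                f"{avg.period}: {grade} "
                f"({avg.mean_sbp:.1f}/{avg.mean_dbp:.1f} mmHg, n={avg.n_used}) "
                f"meets {policy.label}"
            )
        else:
            reasons.append(
                f"{avg.period}: {grade} "
                f"({avg.mean_sbp:.1f}/{avg.mean_dbp:.1f} mmHg, n={avg.n_used}) "
                f"below {policy.label} minimum"
            )
    if not any_eligible:
        reasons.append("no eligible period")
    return TriageResult(
        participant_id=pid,
        triggered=bool(qualifying),
        grade=best,
        qualifying_periods=tuple(p for p in PERIODS if p in qualifying),
        policy=policy.label,
        reasons=tuple(reasons),
    )


def compose_letter(
    result: TriageResult,
    flags: CategoryFlags,
    averages: Sequence[PeriodAverage],
) -> str:
    """Render the urgent notification letter text.

    States the hypertension grade, the period averages it rests on, one line
    per abnormal laboratory category (if any), and a fixed care
    recommendation. Deterministic: identical inputs yield identical text.
    """
    if not result.triggered:
        raise ValueError("cannot compose a letter for a non-triggered result")
    grade_names = {"grade2": "Grade II", "grade3": "Grade III"}
    lines = [
        "URGENT NOTIFICATION OF HOME BLOOD PRESSURE RESULTS",
        f"Participant: {result.participant_id}",
        "",
        f"Your 14-day home blood pressure averages indicate "
        f"{grade_names.get(result.grade, result.grade)} hypertension.",
        "Average values by time of day:",
    ]
    for avg in averages:
        if avg.n_used == 0:
            lines.append(f"  {avg.period}: no measurements")
        else:
            mark = " *" if avg.period in result.qualifying_periods else ""
            lines.append(
                f"  {avg.period}: {avg.mean_sbp:.1f}/{avg.mean_dbp:.1f} mmHg "
                f"(n={avg.n_used}){mark}"
            )
    lines.append("  (* period meeting the urgent notification criteria)")
    abnormal = [cat for cat in flags.field_order() if getattr(flags, cat)]
    if abnormal:
        lines.append("")
        lines.append("Your blood test also showed abnormal (non-urgent) values:")
        for cat in abnormal:
            lines.append(f"  - {_CATEGORY_LETTER_LINES[cat]}")
    lines += [
        "",
        "We strongly recommend that you consult a physician promptly and",
        "bring this letter with you.",
        "",
    ]
    return "\n".join(lines)
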