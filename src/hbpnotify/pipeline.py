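"""End-to-end batch pipeline: readings -> triage -> flags -> association -> behavior.

The study's live office workflow is modeled as a batch pipeline over CSV
stages. Every intermediate table is persisted so each stage can be re-run and
tested in isolation, and a machine-readable manifest records the
configuration hash and row counts at each stage. Inputs come either from
files or from the synthetic generator (exactly one of the two).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .assoc import association_frame, pairwise_association, render_association_report
from .behavior import (
    mcnemar,
    paired_subgroup,
    read_questionnaire_csv,
    render_behavior_report,
    tabulate,
)
from .labs import CATEGORIES, LABS_CSV_COLUMNS, flags_frame, read_labs_csv
from .readings import averages_frame, read_measurements_csv, PERIODS, PeriodAverage
from .synthetic import SyntheticConfig, generate_cohort
from .triage import (
    GradeThresholds,
    NotificationPolicy,
    compose_letter,
    evaluate_notification,
)
from .labs import CategoryFlags

logger = logging.getLogger(__name__)


class InputPaths(BaseModel):
    measurements: Path
    labs: Path
    questionnaire: Path


class ThresholdConfig(BaseModel):
    grade1: tuple[float, float] = (140.0, 90.0)
    grade2: tuple[float, float] = (160.0, 100.0)
    grade3: tuple[float, float] = (180.0, 110.0)

    def build(self) -> GradeThresholds:
        return GradeThresholds(self.grade1, self.grade2, self.grade3)


class PolicyConfig(BaseModel):
    label: str = "GRADE_III_ONLY"
    min_measurements: int = 3

    def build(self) -> NotificationPolicy:
        return NotificationPolicy(self.label, self.min_measurements)


class RunConfig(BaseModel):
    """One pipeline run: input files XOR a simulate block, plus analysis
    parameters."""

    inputs: InputPaths | None = None
    simulate: SyntheticConfig | None = None
    thresholds: ThresholdConfig = Field(default_factory=ThresholdConfig)
    policy: PolicyConfig = Field(default_factory=PolicyConfig)
    alpha_family: float = 0.05
    seed: int | None = None

    @model_validator(mode="after")
    def _exactly_one_source(self):
        if (self.inputs is None) == (self.simulate is None):
            raise ValueError("exactly one of 'inputs' and 'simulate' must be given")
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh))


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_inputs(paths: InputPaths) -> ValidationReport:
    """Schema, type, and referential checks on the three input CSVs.

    Blocking errors (missing file/column, unparseable values) are separated
    from non-blocking warnings (e.g. a lab row whose participant has no
    measurements; the row is retained).
    """
    report = ValidationReport()
    frames: dict[str, pd.DataFrame] = {}
    required = {
        "measurements": ["participant_id", "timestamp", "sbp", "dbp"],
        "labs": LABS_CSV_COLUMNS,
        "questionnaire": ["participant_id", "wave", "category"],
    }
    for name in required:
        path = getattr(paths, name)
        if not Path(path).exists():
            report.errors.append(f"{name}: file not found: {path}")
            continue
        try:
            frames[name] = pd.read_csv(path, dtype={"participant_id": str})
        except Exception as exc:  # malformed CSV is blocking
            report.errors.append(f"{name}: unreadable CSV ({exc})")
            continue
        for col in required[name]:
            if col not in frames[name].columns:
                report.errors.append(f"{name}: missing required column '{col}'")
    if report.errors:
        return report

    m = frames["measurements"]
    for col in ("sbp", "dbp"):
        if not pd.api.types.is_numeric_dtype(m[col]):
            report.errors.append(f"measurements: column '{col}' is not numeric")
    bad_ts = m["timestamp"].map(lambda s: pd.isna(pd.to_datetime(s, errors="coerce")))
    for idx in m.index[bad_ts][:5]:
        report.errors.append(
            f"measurements: row {idx}: unparseable timestamp {m.loc[idx, 'timestamp']!r}"
        )
    if not report.errors:
        bad_bp = m[(m["sbp"] <= m["dbp"]) | (m["dbp"] <= 0)]
        for idx in bad_bp.index[:5]:
            report.errors.append(
                f"measurements: row {idx}: require sbp > dbp > 0 "
                f"(got {m.loc[idx, 'sbp']}/{m.loc[idx, 'dbp']})"
            )
    measured_ids = set(m["participant_id"])
    for idx, pid in frames["labs"]["participant_id"].items():
        if pid not in measured_ids:
            report.warnings.append(
                f"labs: row {idx}: participant {pid} has no measurements; row retained"
            )
    bad_sex = frames["labs"][~frames["labs"]["sex"].isin(["male", "female"])]
    for idx in bad_sex.index[:5]:
        report.errors.append(f"labs: row {idx}: sex must be male/female")
    q = frames["questionnaire"]
    bad_wave = q[~q["wave"].isin(["pre", "post"])]
    for idx in bad_wave.index[:5]:
        report.errors.append(f"questionnaire: row {idx}: wave must be pre/post")
    return report


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.model_dump(mode="json"), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute all stages, writing every intermediate and the manifest to
    ``out_dir``. Returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config_hash": _config_hash(config),
        "config": config.model_dump(mode="json"),
        "counts": {},
    }

    # inputs
    if config.simulate is not None:
        sim = config.simulate
        if config.seed is not None:
            sim = sim.model_copy(update={"seed": config.seed})
        cohort = generate_cohort(sim)
        input_dir = out / "inputs"
        paths_map = cohort.write(input_dir)
        paths = InputPaths(
            measurements=paths_map["measurements"],
            labs=paths_map["labs"],
            questionnaire=paths_map["questionnaire"],
        )
    else:
        paths = config.inputs

    report = validate_inputs(paths)
    if not report.ok:
        raise ValueError("input validation failed:\n" + "\n".join(report.errors))
    for w in report.warnings:
        logger.warning(w)
    manifest["validation_warnings"] = len(report.warnings)

    # readings -> per-period averages
    measurements = read_measurements_csv(paths.measurements)
    manifest["counts"]["measurements"] = len(measurements)
    averages = averages_frame(measurements)
    averages.to_csv(out / "averages.csv", index=False)
    participant_ids = sorted({m.participant_id for m in measurements})
    manifest["counts"]["participants_measured"] = len(participant_ids)

    # lab flags (needed for letters)
    panels = read_labs_csv(paths.labs)
    flags = flags_frame(panels)
    flags.to_csv(out / "flags.csv", index=False)
    manifest["counts"]["lab_panels"] = len(panels)
    flags_by_pid = {
        row.participant_id: CategoryFlags(
            **{c: bool(getattr(row, c)) for c in CATEGORIES}
        )
        for row in flags.itertuples()
    }

    # triage + letters
    policy = config.policy.build()
    thresholds = config.thresholds.build()
    letters_dir = out / "letters"
    letters_dir.mkdir(exist_ok=True)
    triage_rows = []
    n_letters = 0
    for pid in participant_ids:
        avg_rows = averages[averages["participant_id"] == pid]
        avgs = [
            PeriodAverage(
                pid,
                r.period,
                int(r.n_used),
                None if pd.isna(r.mean_sbp) else float(r.mean_sbp),
                None if pd.isna(r.mean_dbp) else float(r.mean_dbp),
            )
            for r in avg_rows.itertuples()
        ]
        result = evaluate_notification(avgs, policy, thresholds)
        logger.info(
            "participant %s: data received -> criteria evaluated -> %s",
            pid,
            "letter composed" if result.triggered else "no letter",
        )
        triage_rows.append(
            {
                "participant_id": pid,
                "triggered": result.triggered,
                "grade": result.grade,
                "qualifying_periods": ";".join(result.qualifying_periods),
                "policy": result.policy,
            }
        )
        if result.triggered:
            pf = flags_by_pid.get(pid, CategoryFlags(*(False,) * 5))
            (letters_dir / f"{pid}.txt").write_text(
                compose_letter(result, pf, avgs), encoding="utf-8"
            )
            n_letters += 1
    triage_df = pd.DataFrame(
        triage_rows,
        columns=["participant_id", "triggered", "grade", "qualifying_periods", "policy"],
    )
    triage_df.to_csv(out / "triage.csv", index=False)
    manifest["counts"]["notified"] = n_letters

    # association among notified participants
    notified_ids = set(triage_df[triage_df["triggered"]]["participant_id"])
    notified_flags = flags[flags["participant_id"].isin(notified_ids)]
    if len(notified_flags) >= 2:
        assoc = pairwise_association(notified_flags, config.alpha_family)
        association_frame(assoc).to_csv(out / "association.csv", index=False)
        (out / "association.txt").write_text(render_association_report(assoc))
        manifest["counts"]["association_pairs"] = len(assoc)
    else:
        manifest["counts"]["association_pairs"] = 0
        logger.warning("fewer than two notified participants; association skipped")

    # behavior change among notified participants
    q = read_questionnaire_csv(paths.questionnaire)
    q_notified = q[q["participant_id"].isin(notified_ids)]
    if len(q_notified):
        pre = tabulate(q_notified, "pre")
        post = tabulate(q_notified, "post")
        pairs = paired_subgroup(q_notified)
        m = mcnemar(pairs)
        from .behavior import tabulate_counts, ANSWER_CATEGORIES

        paired_pre = tabulate_counts(
            [sum(1 for _, p, _ in pairs if p == c) for c in ANSWER_CATEGORIES], "pre"
        ) if pairs else None
        paired_post = tabulate_counts(
            [sum(1 for _, _, p in pairs if p == c) for c in ANSWER_CATEGORIES], "post"
        ) if pairs else None
        (out / "behavior.txt").write_text(
            render_behavior_report(pre, post, paired_pre, paired_post, m)
        )
        manifest["counts"]["paired_respondents"] = len(pairs)
    else:
        manifest["counts"]["paired_respondents"] = 0

    manifest["counts"]["letters"] = n_letters
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
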