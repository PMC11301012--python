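"""Synthetic cohort generator with the statistical structure the pipeline assumes.

The generator emulates a population undergoing a 14-day home blood pressure
protocol alongside a blood panel and pre/post questionnaires:

* demographics: a bimodal age mixture (peaks in the 30s and 60s) and a
  roughly 2:1 female:male ratio;
* blood pressure: a latent hypertension grade per participant, a true BP
  drawn within that grade's band, and noisy readings whose presence follows
  per-period adherence probabilities (morning/evening high, midday low),
  with occasional same-period repeats;
* laboratory panels: the five abnormality-category flags are drawn from a
  pairwise log-linear model over the 2^5 joint states — field terms are
  solved numerically so marginals match the configured base rates, and the
  symmetric coupling matrix sets conditional log odds ratios between
  category pairs. Analyte values are then placed just outside (or well
  inside) the reference bounds so the flagging stage recovers the intended
  flags exactly; lipid is emitted directly as its boolean column;
* behavior: a pre-survey answer per participant and a post-notification
  answer drawn from a care-seeking transition model whose switch-to-regular-
  treatment probability depends on whether triage (run on the generated
  readings, with the configured policy) would notify the participant.

Everything is driven by one integer seed through a single numpy Generator, so
identical configurations produce byte-identical CSVs.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime, time, timedelta
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy import optimize

from .behavior import ANSWER_CATEGORIES, NO_ANSWER
from .labs import CATEGORIES, LABS_CSV_COLUMNS, default_ranges
from .readings import PERIODS, BPMeasurement, period_averages
from .triage import GradeThresholds, NotificationPolicy, evaluate_notification

GRADE_LABELS = ("none", "grade1", "grade2", "grade3")

#: Bands (sbp_lo, sbp_hi, dbp_lo, dbp_hi) the latent true BP is drawn from,
#: one per grade, kept 1-2 mmHg inside the grade cut-offs.
GRADE_BP_BANDS = {
    "none": (105.0, 135.0, 65.0, 85.0),
    "grade1": (141.0, 158.0, 91.0, 98.0),
    "grade2": (161.0, 178.0, 101.0, 108.0),
    "grade3": (181.0, 205.0, 111.0, 125.0),
}

_PERIOD_CLOCK = {  # start hour and length (hours) of each period window
    "morning": (4, 7),
    "midday": (11, 5),
    "evening": (16, 12),  # wraps past midnight
}


class SyntheticConfig(BaseModel):
    """All knobs of the generator. Defaults give a small, realistic cohort."""

    n_participants: int = Field(default=500, ge=1)
    seed: int = 0
    start_date: date = date(2014, 3, 1)
    n_days: int = 14

    female_fraction: float = Field(default=2 / 3, ge=0.0, le=1.0)
    age_means: tuple[float, float] = (35.0, 65.0)
    age_sds: tuple[float, float] = (7.0, 8.0)
    age_weights: tuple[float, float] = (0.45, 0.55)

    grade_prevalence: dict[str, float] = Field(
        default_factory=lambda: {
            "none": 0.70,
            "grade1": 0.20,
            "grade2": 0.07,
            "grade3": 0.03,
        }
    )
    adherence: dict[str, float] = Field(
        default_factory=lambda: {"morning": 0.90, "midday": 0.25, "evening": 0.85}
    )
    repeat_rate: float = Field(default=0.08, ge=0.0)  # Poisson mean of extra same-period readings
    bp_noise_sd: float = Field(default=8.0, ge=0.0)

    category_base_rates: dict[str, float] = Field(
        default_factory=lambda: {
            "blood_sugar": 0.46,
            "renal": 0.40,
            "lipid": 0.35,
            "hematological": 0.17,
            "liver": 0.11,
        }
    )
    #: symmetric couplings, keys "cat_a|cat_b" in category order
    pairwise_log_odds: dict[str, float] = Field(default_factory=dict)

    policy_label: str = "GRADE_III_ONLY"
    min_measurements: int = 3

    #: care-seeking transition model
    pre_answer_probs: dict[str, float] = Field(
        default_factory=lambda: {
            "regular_treatment": 0.42,
            "discontinued_followup": 0.06,
            "lifestyle_precaution": 0.17,
            "followup_no_medication": 0.11,
            "never_pointed_out": 0.24,
        }
    )
    p_stay_regular: float = Field(default=0.95, ge=0.0, le=1.0)
    p_switch_to_regular_notified: float = Field(default=0.50, ge=0.0, le=1.0)
    p_switch_to_regular_unnotified: float = Field(default=0.10, ge=0.0, le=1.0)
    response_rate_pre: float = Field(default=0.90, ge=0.0, le=1.0)
    response_rate_post: float = Field(default=0.64, ge=0.0, le=1.0)

    @field_validator("grade_prevalence")
    @classmethod
    def _check_grades(cls, v):
        if set(v) != set(GRADE_LABELS):
            raise ValueError(f"grade_prevalence must cover {GRADE_LABELS}")
        if any(p < 0 for p in v.values()) or abs(sum(v.values()) - 1.0) > 1e-9:
            raise ValueError("grade_prevalence must be a probability vector")
        return v

    @field_validator("category_base_rates")
    @classmethod
    def _check_rates(cls, v):
        if set(v) != set(CATEGORIES):
            raise ValueError(f"category_base_rates must cover {CATEGORIES}")
        if any(not (0.0 < p < 1.0) for p in v.values()):
            raise ValueError("category base rates must lie strictly in (0, 1)")
        return v

    @field_validator("adherence")
    @classmethod
    def _check_adherence(cls, v):
        if set(v) != set(PERIODS):
            raise ValueError(f"adherence must cover {PERIODS}")
        if any(not (0.0 <= p <= 1.0) for p in v.values()):
            raise ValueError("adherence probabilities must lie in [0, 1]")
        return v

    @model_validator(mode="after")
    def _check_rest(self):
        for key in self.pairwise_log_odds:
            a, _, b = key.partition("|")
            if a not in CATEGORIES or b not in CATEGORIES or a == b:
                raise ValueError(f"bad pairwise_log_odds key {key!r}")
        probs = self.pre_answer_probs
        if set(probs) != set(ANSWER_CATEGORIES):
            raise ValueError(f"pre_answer_probs must cover {ANSWER_CATEGORIES}")
        if any(p < 0 for p in probs.values()) or abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ValueError("pre_answer_probs must be a probability vector")
        NotificationPolicy(self.policy_label, self.min_measurements)  # validates
        return self

    def coupling_matrix(self) -> np.ndarray:
        J = np.zeros((len(CATEGORIES), len(CATEGORIES)))
        idx = {c: i for i, c in enumerate(CATEGORIES)}
        for key, value in self.pairwise_log_odds.items():
            a, _, b = key.partition("|")
            J[idx[a], idx[b]] = J[idx[b], idx[a]] = value
        return J


@dataclass
class SyntheticCohort:
    """The generated tables, keyed exactly to the pipeline's CSV schemas."""

    measurements: pd.DataFrame
    labs: pd.DataFrame
    questionnaire: pd.DataFrame
    ground_truth: pd.DataFrame

    def write(self, out_dir) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in (
            ("measurements", self.measurements),
            ("labs", self.labs),
            ("questionnaire", self.questionnaire),
            ("ground_truth", self.ground_truth),
        ):
            paths[name] = out / f"{name}.csv"
            df.to_csv(paths[name], index=False)
        return paths


# ---------------------------------------------------------------------------
# correlated category flags (pairwise log-linear model on 2^5 states)

_STATES = np.array(
    [[(s >> i) & 1 for i in range(len(CATEGORIES))] for s in range(2 ** len(CATEGORIES))],
    dtype=float,
)


def _state_distribution(h: np.ndarray, J: np.ndarray) -> np.ndarray:
    """Exact probabilities of the 2^5 joint flag states under
    P(x) ∝ exp(h·x + Σ_{i<j} J_ij x_i x_j)."""
    energy = _STATES @ h + 0.5 * np.einsum("si,ij,sj->s", _STATES, J, _STATES)
    energy -= energy.max()
    p = np.exp(energy)
    return p / p.sum()


def solve_fields(base_rates: np.ndarray, J: np.ndarray) -> np.ndarray:
    """Field terms h such that the model's marginals equal ``base_rates``."""

    def gap(h):
        return _STATES.T @ _state_distribution(h, J) - base_rates

    x0 = np.log(base_rates / (1.0 - base_rates))
    sol = optimize.root(gap, x0, method="hybr", tol=1e-12)
    if not sol.success or np.max(np.abs(gap(sol.x))) > 1e-8:
        raise RuntimeError("could not calibrate field terms to the base rates")
    return sol.x


def generate_category_flags(
    n: int,
    base_rates: dict[str, float],
    pairwise_log_odds: np.ndarray | None,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw n joint flag vectors from the calibrated log-linear model."""
    rates = np.array([base_rates[c] for c in CATEGORIES])
    J = np.zeros((5, 5)) if pairwise_log_odds is None else pairwise_log_odds
    h = solve_fields(rates, J)
    p = _state_distribution(h, J)
    draws = rng.choice(len(p), size=n, p=p)
    return pd.DataFrame(_STATES[draws].astype(bool), columns=list(CATEGORIES))


# ---------------------------------------------------------------------------
# lab panels consistent with the flags

#: analyte whose value encodes each category's abnormality (lipid excluded:
#: it is a direct boolean)
_CATEGORY_CARRIER = {
    "blood_sugar": "blood_sugar",
    "renal": "creatinine",
    "hematological": "hemoglobin",
    "liver": "ast",
}


def _panel_values(flags_row: pd.Series, sex: str, rng: np.random.Generator) -> dict:
    """Analyte values placed mid-range, except the carrier analyte of each
    abnormal category, which is placed just above its upper bound (below the
    lower bound for hemoglobin) within a 5-40% band."""
    registry = default_ranges()
    values: dict[str, float] = {}
    for analyte in (
        "crp", "hemoglobin", "platelets", "leukocytes", "blood_sugar",
        "ast", "alt", "creatinine", "bun", "uric_acid", "sodium",
    ):
        r = registry.lookup(analyte, sex)
        lo = r.low if r.low is not None else 0.0
        hi = r.high
        values[analyte] = lo + (hi - lo) * rng.uniform(0.35, 0.65)
    for cat, carrier in _CATEGORY_CARRIER.items():
        if not flags_row[cat]:
            continue
        r = registry.lookup(carrier, sex)
        width = r.high - (r.low or 0.0)
        if carrier == "hemoglobin":  # anemia: dip below the lower bound
            values[carrier] = r.low - width * rng.uniform(0.05, 0.40)
        else:
            values[carrier] = r.high + width * rng.uniform(0.05, 0.40)
    return {k: round(v, 2) for k, v in values.items()}


# ---------------------------------------------------------------------------
# generator


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort (measurements, labs, questionnaires,
    ground truth) from one seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    ids = [f"P{i:05d}" for i in range(n)]

    # demographics
    female = rng.random(n) < config.female_fraction
    component = rng.random(n) < config.age_weights[1] / sum(config.age_weights)
    ages = np.where(
        component,
        rng.normal(config.age_means[1], config.age_sds[1], n),
        rng.normal(config.age_means[0], config.age_sds[0], n),
    )
    ages = np.clip(ages, 20.0, 95.0)

    # latent hypertension grade and true BP
    grade_p = np.array([config.grade_prevalence[g] for g in GRADE_LABELS])
    grades = rng.choice(len(GRADE_LABELS), size=n, p=grade_p)
    true_sbp = np.empty(n)
    true_dbp = np.empty(n)
    for gi, g in enumerate(GRADE_LABELS):
        mask = grades == gi
        s_lo, s_hi, d_lo, d_hi = GRADE_BP_BANDS[g]
        true_sbp[mask] = rng.uniform(s_lo, s_hi, mask.sum())
        true_dbp[mask] = rng.uniform(d_lo, d_hi, mask.sum())

    # category flags and lab panels
    flags = generate_category_flags(
        n, config.category_base_rates, config.coupling_matrix(), rng
    )
    lab_rows = []
    for i, pid in enumerate(ids):
        sex = "female" if female[i] else "male"
        values = _panel_values(flags.iloc[i], sex, rng)
        lab_rows.append(
            {
                "participant_id": pid,
                "sex": sex,
                **values,
                "blast_cells": False,
                "atypical_cells": False,
                "erythroblasts_per_200": 0,
                "lipid_abnormal": bool(flags.iloc[i]["lipid"]),
            }
        )
    labs = pd.DataFrame(lab_rows, columns=LABS_CSV_COLUMNS)

    # 14 days of readings
    measurement_rows = []
    notified = np.zeros(n, dtype=bool)
    policy = NotificationPolicy(config.policy_label, config.min_measurements)
    thresholds = GradeThresholds()
    for i, pid in enumerate(ids):
        readings: list[BPMeasurement] = []
        for day in range(config.n_days):
            day_date = config.start_date + timedelta(days=day)
            for period in PERIODS:
                if rng.random() >= config.adherence[period]:
                    continue
                n_here = 1 + rng.poisson(config.repeat_rate)
                start_h, length_h = _PERIOD_CLOCK[period]
                offsets = np.sort(rng.uniform(0.0, length_h * 60.0, n_here))
                for off in offsets:
                    minutes = start_h * 60 + int(off)
                    ts = datetime.combine(day_date, time(0, 0)) + timedelta(
                        minutes=minutes
                    )
                    sbp = int(round(true_sbp[i] + rng.normal(0.0, config.bp_noise_sd)))
                    dbp = int(round(true_dbp[i] + rng.normal(0.0, config.bp_noise_sd)))
                    dbp = max(40, min(dbp, sbp - 5))
                    sbp = max(sbp, dbp + 5)
                    readings.append(BPMeasurement(pid, ts, sbp, dbp))
        readings.sort(key=lambda m: m.timestamp)
        for m in readings:
            measurement_rows.append(
                {
                    "participant_id": pid,
                    "timestamp": m.timestamp.strftime("%Y-%m-%dT%H:%M"),
                    "sbp": m.sbp,
                    "dbp": m.dbp,
                }
            )
        result = evaluate_notification(period_averages(readings), policy, thresholds)
        notified[i] = result.triggered
    measurements = pd.DataFrame(
        measurement_rows, columns=["participant_id", "timestamp", "sbp", "dbp"]
    )

    # questionnaires: pre answer, then a post answer whose switch to regular
    # treatment depends on notification
    pre_p = np.array([config.pre_answer_probs[c] for c in ANSWER_CATEGORIES])
    pre_idx = rng.choice(len(ANSWER_CATEGORIES), size=n, p=pre_p)
    pre_cat = [ANSWER_CATEGORIES[k] for k in pre_idx]
    post_cat = []
    for i in range(n):
        if pre_cat[i] == "regular_treatment":
            post_cat.append(
                "regular_treatment"
                if rng.random() < config.p_stay_regular
                else "lifestyle_precaution"
            )
        else:
            p_switch = (
                config.p_switch_to_regular_notified
                if notified[i]
                else config.p_switch_to_regular_unnotified
            )
            post_cat.append(
                "regular_treatment" if rng.random() < p_switch else pre_cat[i]
            )
    answered_pre = rng.random(n) < config.response_rate_pre
    answered_post = rng.random(n) < config.response_rate_post
    q_rows = []
    for i, pid in enumerate(ids):
        q_rows.append(
            {
                "participant_id": pid,
                "wave": "pre",
                "category": pre_cat[i] if answered_pre[i] else NO_ANSWER,
            }
        )
        q_rows.append(
            {
                "participant_id": pid,
                "wave": "post",
                "category": post_cat[i] if answered_post[i] else NO_ANSWER,
            }
        )
    questionnaire = pd.DataFrame(q_rows, columns=["participant_id", "wave", "category"])

    ground_truth = pd.DataFrame(
        {
            "participant_id": ids,
            "sex": ["female" if f else "male" for f in female],
            "age": np.round(ages, 1),
            "latent_grade": [GRADE_LABELS[g] for g in grades],
            "true_sbp": np.round(true_sbp, 1),
            "true_dbp": np.round(true_dbp, 1),
            **{f"true_{c}": flags[c].to_numpy() for c in CATEGORIES},
            "notified": notified,
            "pre_category": pre_cat,
            "post_category": post_cat,
            "answered_pre": answered_pre,
            "answered_post": answered_post,
        }
    )
    return SyntheticCohort(measurements, labs, questionnaire, ground_truth)


# ---------------------------------------------------------------------------
# parameter recovery


def odds_ratio_ci(a: int, b: int, c: int, d: int, level: float = 0.95) -> tuple[float, float, float]:
    """Sample odds ratio with a Woolf (log-normal) confidence interval;
    Haldane 0.5 correction when any cell is zero."""
    from scipy.stats import norm

    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_hat = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = norm.ppf(0.5 + level / 2)
    return or_hat, or_hat * np.exp(-z * se), or_hat * np.exp(z * se)


def _wilson(k: int, n: int, level: float = 0.95) -> tuple[float, float, float]:
    from scipy.stats import norm

    if n == 0:
        return float("nan"), 0.0, 1.0
    z = norm.ppf(0.5 + level / 2)
    p = k / n
    denom = 1 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return p, center - half, center + half


def recover_parameters(cohort: SyntheticCohort, config: SyntheticConfig) -> dict:
    """Compare what the pipeline recovers against the generator's ground truth.

    Reports per-grade notification sensitivity/specificity of the triage
    stage, pairwise odds ratios of the recovered category flags against the
    configured couplings, and the estimated care-seeking transition
    probabilities, each with a 95% interval.
    """
    from .labs import flags_frame, read_labs_csv  # local to avoid cycle at import

    gt = cohort.ground_truth
    report: dict = {}

    # (i) triage vs latent grade (notified column was produced by triage)
    min_rank = GRADE_LABELS.index(
        "grade2" if config.policy_label == "GRADE_II_PLUS" else "grade3"
    )
    should = gt["latent_grade"].map(lambda g: GRADE_LABELS.index(g) >= min_rank)
    notified = gt["notified"].astype(bool)
    tp = int((notified & should).sum())
    fn = int((~notified & should).sum())
    tn = int((~notified & ~should).sum())
    fp = int((notified & ~should).sum())
    report["triage"] = {
        "sensitivity": _wilson(tp, tp + fn),
        "specificity": _wilson(tn, tn + fp),
        "per_grade_notification_rate": {
            g: _wilson(
                int((notified & (gt["latent_grade"] == g)).sum()),
                int((gt["latent_grade"] == g).sum()),
            )
            for g in GRADE_LABELS
        },
    }

    # (ii) pairwise odds ratios on the true flags vs configured couplings
    J = config.coupling_matrix()
    pair_report = {}
    for i, j in combinations(range(len(CATEGORIES)), 2):
        ci_, cj = CATEGORIES[i], CATEGORIES[j]
        x = gt[f"true_{ci_}"].to_numpy(bool)
        y = gt[f"true_{cj}"].to_numpy(bool)
        a = int((x & y).sum())
        b = int((x & ~y).sum())
        c = int((~x & y).sum())
        d = int((~x & ~y).sum())
        or_hat, lo, hi = odds_ratio_ci(a, b, c, d)
        pair_report[f"{ci_}|{cj}"] = {
            "estimate": or_hat,
            "ci95": (lo, hi),
            "configured_conditional_or": float(np.exp(J[i, j])),
        }
    report["pairwise_odds_ratios"] = pair_report

    # (iii) care-seeking transitions
    pre = gt["pre_category"].to_numpy()
    post = gt["post_category"].to_numpy()
    non_regular = pre != "regular_treatment"
    for label, mask, configured in (
        ("switch_to_regular_notified", non_regular & notified.to_numpy(),
         config.p_switch_to_regular_notified),
        ("switch_to_regular_unnotified", non_regular & ~notified.to_numpy(),
         config.p_switch_to_regular_unnotified),
        ("stay_regular", ~non_regular, config.p_stay_regular),
    ):
        k = int((post[mask] == "regular_treatment").sum())
        m = int(mask.sum())
        est, lo, hi = _wilson(k, m)
        report[label] = {"estimate": est, "ci95": (lo, hi), "configured": configured, "n": m}
    return report
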