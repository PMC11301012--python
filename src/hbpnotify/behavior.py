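"""Questionnaire tabulation and the paired care-seeking change analysis.

Participants who received an urgent notification answered a hypertension
treatment-status questionnaire before (pre-survey) and after
(post-notification) the letter, choosing one of five categories; no answer is
tracked separately. Percentages are computed over respondents only, with
round-half-up to one decimal.

The change in care-seeking is tested on the paired subgroup (respondents to
both waves) with McNemar's chi-squared test on the dichotomy "under regular
treatment" vs the other four behaviors: with discordant counts b (regular ->
other) and c (other -> regular), the continuity-corrected statistic is
(|b - c| - 1)^2 / (b + c) on 1 df; for small discordance (b + c < 25) an
exact binomial p-value is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats

ANSWER_CATEGORIES = (
    "regular_treatment",
    "discontinued_followup",
    "lifestyle_precaution",
    "followup_no_medication",
    "never_pointed_out",
)
NO_ANSWER = "no_answer"
ALL_CATEGORIES = ANSWER_CATEGORIES + (NO_ANSWER,)
WAVES = ("pre", "post")

EXACT_BINOMIAL_LIMIT = 25  # below this discordance, also report the exact p


def percent_half_up(count: int, total: int) -> float:
    """count/total as a percentage, rounded half-up to one decimal."""
    if total == 0:
        raise ZeroDivisionError("no respondents")
    pct = Decimal(count * 100) / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class BehaviorSummary:
    """One wave's counts and respondent-relative percentages."""

    wave: str
    counts: Mapping[str, int]  # per answer category
    n_no_answer: int
    n_respondents: int
    percentages: Mapping[str, float]


def tabulate(responses: pd.DataFrame, wave: str) -> BehaviorSummary:
    """Tabulate one wave of questionnaire responses.

    ``responses`` has columns participant_id, wave, category. Percentages are
    relative to respondents (no_answer excluded). Duplicate responses for a
    participant within the wave are an error.
    """
    if wave not in WAVES:
        raise ValueError(f"wave must be one of {WAVES}")
    sub = responses[responses["wave"] == wave]
    dupes = sub["participant_id"][sub["participant_id"].duplicated()]
    if len(dupes):
        raise ValueError(
            f"duplicate {wave} responses for participants: {sorted(set(dupes))}"
        )
    unknown = set(sub["category"]) - set(ALL_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown answer categories: {sorted(unknown)}")
    counts = {cat: int((sub["category"] == cat).sum()) for cat in ANSWER_CATEGORIES}
    n_no_answer = int((sub["category"] == NO_ANSWER).sum())
    n_resp = sum(counts.values())
    percentages = {
        cat: percent_half_up(counts[cat], n_resp) for cat in ANSWER_CATEGORIES
    }
    return BehaviorSummary(wave, counts, n_no_answer, n_resp, percentages)


def tabulate_counts(counts: Sequence[int], wave: str = "pre", n_no_answer: int = 0) -> BehaviorSummary:
    """Tabulate directly from the five per-category counts (printed-table
    form), bypassing row-level responses."""
    counts_map = dict(zip(ANSWER_CATEGORIES, counts))
    n_resp = sum(counts_map.values())
    percentages = {
        cat: percent_half_up(counts_map[cat], n_resp) for cat in ANSWER_CATEGORIES
    }
    return BehaviorSummary(wave, counts_map, n_no_answer, n_resp, percentages)


def paired_subgroup(responses: pd.DataFrame) -> list[tuple[str, str, str]]:
    """Participants with substantive answers in both waves.

    Returns (participant_id, pre category, post category), ordered by
    participant id; no_answer in either wave excludes the participant.
    """
    by_wave = {}
    for wave in WAVES:
        sub = responses[
            (responses["wave"] == wave) & (responses["category"] != NO_ANSWER)
        ]
        by_wave[wave] = dict(zip(sub["participant_id"], sub["category"]))
    common = sorted(set(by_wave["pre"]) & set(by_wave["post"]))
    return [(pid, by_wave["pre"][pid], by_wave["post"][pid]) for pid in common]


@dataclass(frozen=True)
class McNemarResult:
    b: int  # positive pre, negative post
    c: int  # negative pre, positive post
    statistic: float | None
    p_value: float
    exact_p: float | None  # exact binomial p, reported when b + c < 25
    note: str = ""


def mcnemar_counts(b: int, c: int) -> McNemarResult:
    """McNemar's test from the two discordant counts."""
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be nonnegative")
    if b + c == 0:
        return McNemarResult(b, c, None, 1.0, None, note="no discordant pairs")
    stat = (abs(b - c) - 1) ** 2 / (b + c)
    p = float(stats.chi2.sf(stat, df=1))
    exact_p = None
    if b + c < EXACT_BINOMIAL_LIMIT:
        exact_p = float(stats.binomtest(b, b + c, 0.5).pvalue)
    return McNemarResult(b, c, stat, p, exact_p)


def mcnemar(
    pairs: Sequence[tuple[str, str, str]],
    positive: str = "regular_treatment",
) -> McNemarResult:
    """McNemar's test on paired pre/post answers dichotomized as
    ``positive`` vs everything else."""
    b = sum(1 for _, pre, post in pairs if pre == positive and post != positive)
    c = sum(1 for _, pre, post in pairs if pre != positive and post == positive)
    return mcnemar_counts(b, c)


def read_questionnaire_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing = {"participant_id", "wave", "category"} - set(df.columns)
    if missing:
        raise ValueError(f"questionnaire CSV missing columns: {sorted(missing)}")
    return df


def render_behavior_report(
    pre: BehaviorSummary,
    post: BehaviorSummary,
    paired_pre: BehaviorSummary | None = None,
    paired_post: BehaviorSummary | None = None,
    mcnemar_result: McNemarResult | None = None,
) -> str:
    """Text report: counts with percentages in parentheses, per wave, plus
    the McNemar block for the paired subgroup."""
    labels = {
        "regular_treatment": "Under regular treatment",
        "discontinued_followup": "Discontinuation of follow-up",
        "lifestyle_precaution": "Lifestyle precaution",
        "followup_no_medication": "Doctor's follow-up w/o medication",
        "never_pointed_out": "Never being pointed out",
    }

    def block(title: str, s: BehaviorSummary, show_no_answer: bool = True) -> list[str]:
        lines = [f"{title} (n = {s.n_respondents})"]
        for cat in ANSWER_CATEGORIES:
            lines.append(
                f"  {labels[cat]:<36}{s.counts[cat]:>5} ({s.percentages[cat]:.1f}%)"
            )
        if show_no_answer:
            lines.append(f"  {'No answer nor response':<36}{s.n_no_answer:>5}")
        return lines

    lines = ["Treatment-status questionnaire, notified participants", ""]
    lines += block("Pre-survey", pre)
    lines += [""]
    lines += block("Post-urgent-notification", post)
    if paired_pre and paired_post:
        lines += ["", "Respondents to both questionnaires:"]
        lines += block("  Pre-survey", paired_pre, show_no_answer=False)
        lines += block("  Post-urgent-notification", paired_post, show_no_answer=False)
    if mcnemar_result is not None:
        m = mcnemar_result
        lines += [
            "",
            "McNemar test (regular treatment vs other four behaviors):",
            f"  discordant pairs: b = {m.b} (regular -> other), c = {m.c} (other -> regular)",
            f"  statistic = {m.statistic if m.statistic is None else format(m.statistic, '.4g')}, "
            f"p = {m.p_value:.4g}"
            + (f", exact binomial p = {m.exact_p:.4g}" if m.exact_p is not None else "")
            + (f"  [{m.note}]" if m.note else ""),
        ]
    return "\n".join(lines) + "\n"
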