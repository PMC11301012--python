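"""Pairwise 2x2 association tests among abnormality categories.

Within notified participants, each unordered pair of the five abnormality
categories is cross-tabulated and tested for association:

* Yates continuity-corrected chi-squared,
  ``X^2 = n (max(|ad - bc| - n/2, 0))^2 / (r1 r2 c1 c2)`` on 1 df, when all
  cells are comfortably large;
* otherwise Fisher's exact test, two-sided by summation of hypergeometric
  point probabilities no greater than the observed table's (the common
  statistical-software convention), with a small relative tolerance for
  floating-point ties.

The selection rule — Fisher iff the smallest observed cell is <= 5 — and the
continuity correction reproduce the published pairwise p-values for this
analysis. Both the rule and the method can be overridden by the caller.

Significance is controlled family-wise by Bonferroni: with 10 pairs at family
level 0.05, each test is judged at alpha = 0.005.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .labs import CATEGORIES

FISHER_TIE_RTOL = 1e-7
SMALL_CELL_LIMIT = 5


@dataclass(frozen=True)
class Table2x2:
    """Counts a,b,c,d for (row+,col+), (row+,col-), (row-,col+), (row-,col-)."""

    a: int
    b: int
    c: int
    d: int
    row_label: str = "row"
    col_label: str = "col"

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be nonnegative")
        if self.n < 1:
            raise ValueError("table must contain at least one observation")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def margins(self) -> tuple[int, int, int, int]:
        """(row1, row2, col1, col2) totals."""
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)

    def transpose(self) -> "Table2x2":
        return Table2x2(self.a, self.c, self.b, self.d, self.col_label, self.row_label)


@dataclass(frozen=True)
class AssocTestResult:
    method: str  # "pearson_yates" or "fisher"
    statistic: float | None  # chi-squared value; None for fisher
    p_value: float
    alpha: float
    note: str = ""

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def yates_statistic(table: Table2x2) -> float:
    """Continuity-corrected chi-squared statistic (correction clamped at 0)."""
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.n
    r1, r2, c1, c2 = table.margins
    diff = max(abs(a * d - b * c) - n / 2.0, 0.0)
    return n * diff * diff / (r1 * r2 * c1 * c2)


def chisq_yates(table: Table2x2, alpha: float = 0.005) -> AssocTestResult:
    """Yates-corrected chi-squared test on a 2x2 table (1 df, upper tail).

    Requires all four margins positive; degenerate tables belong to
    :func:`fisher_exact`.
    """
    if min(table.margins) == 0:
        raise ValueError(
            "chi-squared test undefined with a zero margin; use fisher_exact"
        )
    stat = yates_statistic(table)
    p = float(stats.chi2.sf(stat, df=1))
    return AssocTestResult("pearson_yates", stat, p, alpha)


def fisher_exact(table: Table2x2, alpha: float = 0.005) -> AssocTestResult:
    """Two-sided Fisher exact test by point-probability summation.

    Conditions on both margins; p is the sum of hypergeometric probabilities
    of all tables whose point probability is <= the observed table's, with a
    1e-7 relative tolerance so equal-probability tables are included despite
    floating point.
    """
    r1, _, c1, _ = table.margins
    n = table.n
    # support of the (row+, col+) cell given the margins
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, c1, r1)
    p_obs = pmf[table.a - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + FISHER_TIE_RTOL)].sum())
    return AssocTestResult("fisher", None, min(p, 1.0), alpha)


def select_test(table: Table2x2) -> str:
    """'fisher' when the smallest observed cell is <= 5, else 'pearson_yates'."""
    return (
        "fisher"
        if min(table.a, table.b, table.c, table.d) <= SMALL_CELL_LIMIT
        else "pearson_yates"
    )


def test_table(table: Table2x2, alpha: float = 0.005, method: str | None = None) -> AssocTestResult:
    """Run the selected (or forced) association test on one table."""
    method = method or select_test(table)
    if method == "fisher":
        return fisher_exact(table, alpha)
    if method == "pearson_yates":
        return chisq_yates(table, alpha)
    raise ValueError(f"unknown method {method!r}")


def crosstab(flags: pd.DataFrame, row: str, col: str) -> Table2x2:
    """2x2 cross-tabulation of two boolean flag columns."""
    r = flags[row].astype(bool)
    c = flags[col].astype(bool)
    return Table2x2(
        a=int((r & c).sum()),
        b=int((r & ~c).sum()),
        c=int((~r & c).sum()),
        d=int((~r & ~c).sum()),
        row_label=row,
        col_label=col,
    )


@dataclass(frozen=True)
class PairAssociation:
    pair: tuple[str, str]
    table: Table2x2
    result: AssocTestResult


def pairwise_association(
    flags: pd.DataFrame,
    alpha_family: float = 0.05,
    categories: Sequence[str] = CATEGORIES,
) -> list[PairAssociation]:
    """All C(5,2)=10 pairwise association tests with Bonferroni control.

    ``flags`` holds one row per participant with boolean category columns.
    Pairs are ordered as the categories are (blood sugar, renal, lipid,
    hematological, liver). A pair in which either category shows no
    variation gets p = 1 with a degenerate-table note.
    """
    if len(flags) < 2:
        raise ValueError("need at least two participants")
    pairs = list(combinations(categories, 2))
    alpha = alpha_family / len(pairs)
    out = []
    for row, col in pairs:
        table = crosstab(flags, row, col)
        r1, r2, c1, c2 = table.margins
        if min(r1, r2) == 0 or min(c1, c2) == 0:
            result = AssocTestResult(
                "fisher", None, 1.0, alpha, note="degenerate table: a category has no variation"
            )
        else:
            result = test_table(table, alpha)
        out.append(PairAssociation((row, col), table, result))
    return out


def format_p(p: float) -> str:
    """P-value formatted to 4 significant decimals, '<0.0001' below that."""
    if p < 1e-4:
        return "<0.0001"
    return f"{p:.4g}"


def association_frame(results: list[PairAssociation]) -> pd.DataFrame:
    """Tidy report of the pairwise tests (counts, method, p, significance)."""
    rows = []
    for pa in results:
        t = pa.table
        rows.append(
            {
                "row_category": pa.pair[0],
                "col_category": pa.pair[1],
                "a": t.a,
                "b": t.b,
                "c": t.c,
                "d": t.d,
                "method": pa.result.method,
                "p_value": pa.result.p_value,
                "p_formatted": format_p(pa.result.p_value),
                "significant": pa.result.significant,
                "alpha": pa.result.alpha,
                "note": pa.result.note,
            }
        )
    return pd.DataFrame(rows)


def render_association_report(results: list[PairAssociation]) -> str:
    """Aligned text rendering of the pairwise co-occurrence tests."""
    lines = [
        "Pairwise association of abnormality categories (notified participants)",
        f"Bonferroni: family alpha 0.05 over {len(results)} tests -> per-test alpha "
        f"{results[0].result.alpha:g}" if results else "",
        "",
        f"{'pair':<32}{'a':>5}{'b':>5}{'c':>5}{'d':>5}  {'method':<14}{'p':>10}  sig",
    ]
    for pa in results:
        t = pa.table
        lines.append(
            f"{pa.pair[0] + ' x ' + pa.pair[1]:<32}"
            f"{t.a:>5}{t.b:>5}{t.c:>5}{t.d:>5}  "
            f"{pa.result.method:<14}{format_p(pa.result.p_value):>10}  "
            f"{'*' if pa.result.significant else ''}"
        )
    return "\n".join(lines) + "\n"
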