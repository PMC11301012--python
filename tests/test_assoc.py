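from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from hbpnotify.assoc import (
    Table2x2,
    association_frame,
    chisq_yates,
    fisher_exact,
    format_p,
    pairwise_association,
    select_test,
    yates_statistic,
)


def exact_fisher_oracle(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p by brute-force hypergeometric enumeration in exact
    rational arithmetic (independent of the implementation)."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    denom = comb(n, r1)
    probs = {
        k: Fraction(comb(c1, k) * comb(n - c1, r1 - k), denom)
        for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1)
    }
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs)


class TestPublishedTables:
    def test_printed_p_values_reproduce(self, published_tables):
        for (row, col), (cells, printed_p, method) in published_tables.items():
            table = Table2x2(*cells, row_label=row, col_label=col)
            assert select_test(table) == method, (row, col)
            if method == "fisher":
                result = fisher_exact(table)
                if printed_p == 1e-4:  # printed as "<0.0001"
                    assert result.p_value < 1e-4
                    assert format_p(result.p_value) == "<0.0001"
                else:
                    assert round(result.p_value, 4) == printed_p
            else:
                result = chisq_yates(table)
                # printed to 4 decimals (one value to 5 significant digits)
                assert result.p_value == pytest.approx(printed_p, abs=5e-5)

    def test_pairwise_association_reproduces_all_printed_p_values(
        self, published_tables, published_flags
    ):
        results = pairwise_association(published_flags, alpha_family=0.05)
        assert len(results) == 10
        assert {r.pair for r in results} == set(published_tables)
        for r in results:
            cells, printed_p, method = published_tables[r.pair]
            assert (r.table.a, r.table.b, r.table.c, r.table.d) == cells
            assert r.result.method == method
            assert r.result.alpha == pytest.approx(0.005)
            if printed_p == 1e-4:
                assert r.result.p_value < 1e-4
                assert r.result.significant  # the only Bonferroni-significant pair
            else:
                assert r.result.p_value == pytest.approx(printed_p, abs=5e-5)
                assert not r.result.significant


class TestChisqYates:
    def test_perfectly_balanced_table_has_zero_statistic(self):
        r = chisq_yates(Table2x2(10, 10, 10, 10))
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_zero_margin_directs_to_fisher(self):
        with pytest.raises(ValueError, match="fisher"):
            chisq_yates(Table2x2(0, 0, 5, 5))

    def test_matches_scipy_continuity_corrected(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            cells = rng.integers(1, 60, size=4)
            table = Table2x2(*map(int, cells))
            ours = chisq_yates(table)
            stat, p, dof, _ = stats.chi2_contingency(
                np.array(cells).reshape(2, 2), correction=True
            )
            assert dof == 1
            assert ours.statistic == pytest.approx(stat, rel=1e-12)
            assert ours.p_value == pytest.approx(p, rel=1e-12)

    def test_transpose_invariance(self):
        t = Table2x2(12, 5, 30, 44)
        assert chisq_yates(t).p_value == pytest.approx(
            chisq_yates(t.transpose()).p_value
        )

    @given(st.integers(30, 120), st.integers(30, 120))
    def test_p_monotone_in_cross_product_difference_at_fixed_margins(self, r1, c1):
        n = 240
        lo, hi = max(0, r1 + c1 - n), min(r1, c1)
        results = []
        for a in range(lo, hi + 1):
            t = Table2x2(a, r1 - a, c1 - a, n - r1 - c1 + a)
            results.append((abs(t.a * t.d - t.b * t.c), chisq_yates(t).p_value))
        results.sort()
        ps = [p for _, p in results]
        assert all(p1 >= p2 - 1e-12 for p1, p2 in zip(ps, ps[1:]))


class TestFisherExact:
    def test_full_enumeration_example(self):
        # all 6 tables with the margins of (2,3,4,5)
        p = fisher_exact(Table2x2(2, 3, 4, 5)).p_value
        assert p == pytest.approx(float(exact_fisher_oracle(2, 3, 4, 5)), rel=1e-10)

    def test_relabeling_symmetry(self):
        assert fisher_exact(Table2x2(0, 5, 5, 0)).p_value == pytest.approx(
            fisher_exact(Table2x2(5, 0, 0, 5)).p_value
        )

    def test_matches_scipy_two_sided(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            cells = rng.integers(0, 40, size=4)
            if cells.sum() == 0:
                continue
            table = Table2x2(*map(int, cells))
            assert fisher_exact(table).p_value == pytest.approx(
                stats.fisher_exact(np.array(cells).reshape(2, 2))[1], rel=1e-9
            )

    @given(st.integers(0, 12), st.integers(0, 12), st.integers(0, 12), st.integers(0, 12))
    def test_matches_exact_rational_enumeration(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        p = fisher_exact(Table2x2(a, b, c, d)).p_value
        assert p == pytest.approx(float(exact_fisher_oracle(a, b, c, d)), rel=1e-7)

    def test_zero_cell_tables_match_oracle(self):
        for cells in [(0, 5, 3, 7), (4, 0, 2, 9), (0, 1, 1, 0)]:
            p = fisher_exact(Table2x2(*cells)).p_value
            assert 0 < p <= 1
            assert p == pytest.approx(float(exact_fisher_oracle(*cells)), rel=1e-9)


class TestSelection:
    @pytest.mark.parametrize(
        "cells, expected",
        [
            ((85, 33, 5, 131), "fisher"),
            ((51, 67, 50, 86), "pearson_yates"),
            ((6, 50, 40, 100), "pearson_yates"),
            ((3, 39, 25, 187), "fisher"),
        ],
    )
    def test_small_cell_rule(self, cells, expected):
        assert select_test(Table2x2(*cells)) == expected


class TestPairwise:
    def test_bonferroni_alpha_is_family_over_ten(self):
        rng = np.random.default_rng(0)
        flags = pd.DataFrame(
            rng.random((50, 5)) < 0.4,
            columns=["blood_sugar", "renal", "lipid", "hematological", "liver"],
        )
        results = pairwise_association(flags, alpha_family=0.05)
        assert all(r.result.alpha == pytest.approx(0.005) for r in results)
        assert [r.pair for r in results] == list(
            combinations(["blood_sugar", "renal", "lipid", "hematological", "liver"], 2)
        )

    def test_degenerate_category_yields_p_one_with_note(self):
        flags = pd.DataFrame(
            {
                "blood_sugar": [True, False, True, False],
                "renal": [False, False, False, False],  # no variation
                "lipid": [True, True, False, False],
                "hematological": [True, False, False, True],
                "liver": [False, True, True, False],
            }
        )
        results = pairwise_association(flags)
        degenerate = [r for r in results if "renal" in r.pair]
        assert len(degenerate) == 4
        assert all(r.result.p_value == 1.0 and "degenerate" in r.result.note for r in degenerate)

    def test_requires_two_participants(self):
        flags = pd.DataFrame(
            [[True, False, True, False, True]],
            columns=["blood_sugar", "renal", "lipid", "hematological", "liver"],
        )
        with pytest.raises(ValueError):
            pairwise_association(flags)

    def test_association_frame_carries_counts_and_formatting(self, published_flags):
        df = association_frame(pairwise_association(published_flags))
        row = df[(df.row_category == "blood_sugar") & (df.col_category == "renal")].iloc[0]
        assert (row.a, row.b, row.c, row.d) == (51, 67, 50, 86)
        assert row.p_formatted == "0.3576"
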