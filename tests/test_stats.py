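"""Mutational index and Fisher's exact enrichment statistics."""

from __future__ import annotations

import math
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from trapscreen.stats import (
    compare_screens,
    fisher_exact_pvalue,
    fishtail_table,
    log2_mi,
    mutational_index,
    analyze_screen,
)


def fisher_enumeration_oracle(a: int, H: int, b: int, L: int) -> Fraction:
    """Exact rational two-sided Fisher P by full-support enumeration."""
    n = a + b
    obs = comb(H, a) * comb(L, b)
    total = 0
    for k in range(max(0, n - L), min(n, H) + 1):
        w = comb(H, k) * comb(L, n - k)
        if w <= obs:
            total += w
    denom = comb(H + L, n)
    return Fraction(total, denom) if denom else Fraction(1)


class TestMutationalIndex:
    @pytest.mark.parametrize(
        "a,H,b,L,expected",
        [
            (10, 1000, 5, 2000, Fraction(19950, 4950)),  # (10/990)/(5/1995)
            (7, 500, 7, 500, Fraction(1)),
            (4, 4, 1, 1, math.inf),  # a == H
        ],
    )
    def test_formula(self, a, H, b, L, expected):
        got = mutational_index(a, H, b, L, exact=True)
        assert got == expected
        if expected != math.inf:
            assert mutational_index(a, H, b, L) == pytest.approx(float(expected), rel=1e-12)

    def test_leave_one_out_value(self):
        # the headline worked example: enrichment of 10/1000 vs 5/2000
        assert mutational_index(10, 1000, 5, 2000) == pytest.approx(4.030303, abs=1e-6)

    def test_zero_count_policy(self):
        assert mutational_index(0, 100, 9, 100) == 0.0
        assert mutational_index(3, 100, 0, 100) == math.inf
        assert math.isnan(mutational_index(0, 100, 0, 100))

    @pytest.mark.parametrize("a,H,b,L", [(5, 3, 1, 10), (1, 10, 5, 3), (-1, 10, 0, 10)])
    def test_invalid_counts_rejected(self, a, H, b, L):
        with pytest.raises(ValueError):
            mutational_index(a, H, b, L)

    @given(
        a=st.integers(1, 50), extra_h=st.integers(1, 200),
        b=st.integers(1, 50), extra_l=st.integers(1, 200),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_antisymmetry_exact(self, a, extra_h, b, extra_l):
        """Swapping high and low inverts the MI exactly (rational arithmetic)."""
        H, L = a + extra_h, b + extra_l
        mi = mutational_index(a, H, b, L, exact=True)
        mi_swapped = mutational_index(b, L, a, H, exact=True)
        assert mi_swapped == 1 / mi

    def test_strictly_increasing_in_a(self):
        H, b, L = 500, 7, 600
        values = [mutational_index(a, H, b, L, exact=True) for a in range(1, H)]
        assert all(x < y for x, y in zip(values, values[1:]))


class TestFisherExact:
    def test_closed_form_diagonal(self):
        # [[3,0],[0,3]]: P(X=3)=P(X=0)=1/20, two-sided sum = 0.1
        assert fisher_exact_pvalue(3, 3, 0, 3) == pytest.approx(0.1, abs=1e-12)

    def test_balanced_table_is_one(self):
        assert fisher_exact_pvalue(5, 10, 5, 10) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("a,H,b,L", [(0, 0, 0, 0), (0, 0, 3, 5), (2, 2, 0, 0)])
    def test_degenerate_margins(self, a, H, b, L):
        assert fisher_exact_pvalue(a, H, b, L) == 1.0

    @given(
        a=st.integers(0, 40), extra_h=st.integers(0, 60),
        b=st.integers(0, 40), extra_l=st.integers(0, 60),
    )
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_matches_enumeration_and_scipy(self, a, extra_h, b, extra_l):
        H, L = a + extra_h, b + extra_l
        p = fisher_exact_pvalue(a, H, b, L)
        assert abs(p - float(fisher_enumeration_oracle(a, H, b, L))) <= 1e-9
        sp = scipy.stats.fisher_exact([[a, H - a], [b, L - b]], alternative="two-sided")[1]
        assert p == pytest.approx(sp, abs=1e-7)

    @given(
        a=st.integers(0, 30), extra_h=st.integers(0, 50),
        b=st.integers(0, 30), extra_l=st.integers(0, 50),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_swap_invariance_and_range(self, a, extra_h, b, extra_l):
        """Two-sided P is unchanged by swapping populations and lies in [0,1]."""
        H, L = a + extra_h, b + extra_l
        p = fisher_exact_pvalue(a, H, b, L)
        assert 0.0 <= p <= 1.0
        assert p == pytest.approx(fisher_exact_pvalue(b, L, a, H), abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_pvalue(-1, 5, 2, 5)


class TestScreenCalls:
    def counts(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "a", "b", "H", "L"])

    def test_alpha_cutoff_is_strict(self):
        # a table whose exact P equals the chosen alpha must NOT be significant
        p = fisher_exact_pvalue(3, 3, 0, 3)  # exactly 0.1
        res = analyze_screen(self.counts([("g", 3, 0, 3, 3)]), alpha=p)
        assert not res["significant"].iloc[0]
        res2 = analyze_screen(self.counts([("g", 3, 0, 3, 3)]), alpha=p + 1e-9)
        assert res2["significant"].iloc[0]

    def test_direction_and_regulator_labels(self):
        res = analyze_screen(
            self.counts([("up", 40, 2, 1000, 1000), ("down", 2, 40, 1000, 1000)])
        ).set_index("gene_id")
        assert res.loc["up", "direction"] == "enriched_high"
        assert res.loc["up", "regulator"] == "negative regulator"
        assert res.loc["down", "direction"] == "enriched_low"
        assert res.loc["down", "regulator"] == "positive regulator"

    def test_undefined_mi_never_called(self):
        res = analyze_screen(self.counts([("empty", 0, 0, 50, 60)]))
        assert not res["significant"].iloc[0]
        assert res["direction"].iloc[0] == "none"

    def test_fdr_column(self):
        res = analyze_screen(
            self.counts([("g1", 30, 2, 100, 100), ("g2", 5, 5, 100, 100)]), fdr=True
        )
        assert "q_value" in res
        assert (res["q_value"] >= res["p_value"] - 1e-15).all()


class TestFishtail:
    def test_mi_one_maps_to_zero(self):
        counts = pd.DataFrame([("g", 5, 5, 100, 100)], columns=["gene_id", "a", "b", "H", "L"])
        table = fishtail_table(analyze_screen(counts))
        assert table["y"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert table["x"].iloc[0] == 10

    def test_haldane_pseudocount_formula_for_infinite_mi(self):
        a, H, b, L = 12, 100, 0, 120
        counts = pd.DataFrame([("g", a, b, H, L)], columns=["gene_id", "a", "b", "H", "L"])
        table = fishtail_table(analyze_screen(counts), pseudocount="haldane")
        expected = math.log2(((a + 0.5) / (H - a)) * ((L - b) / 0.5))
        assert table["y"].iloc[0] == pytest.approx(expected, rel=1e-12)

    def test_undefined_mi_excluded_and_empty_ok(self):
        counts = pd.DataFrame(
            [("dead", 0, 0, 50, 50), ("live", 4, 2, 50, 50)],
            columns=["gene_id", "a", "b", "H", "L"],
        )
        table = fishtail_table(analyze_screen(counts))
        assert list(table["gene_id"]) == ["live"]
        empty = fishtail_table(analyze_screen(counts.iloc[:0]))
        assert empty.empty


class TestCompareScreens:
    def results(self, rows):
        counts = pd.DataFrame(rows, columns=["gene_id", "a", "b", "H", "L"])
        return analyze_screen(counts)

    def test_exact_log2_difference_on_powers_of_two(self):
        # MI = 8 vs MI = 2, both with clean power-of-two ratios
        r1 = self.results([("g", 8, 1, 108, 101)])    # (8/100)/(1/100) = 8
        r2 = self.results([("g", 2, 1, 102, 101)])    # (2/100)/(1/100) = 2
        cmp_ = compare_screens(r1, r2, min_insertions=1)
        assert cmp_["delta_log2_mi"].iloc[0] == pytest.approx(2.0, abs=1e-12)
        same = compare_screens(r1, r1, min_insertions=1)
        assert same["delta_log2_mi"].iloc[0] == 0.0

    def test_min_insertion_filter_requires_both_screens(self):
        r1 = self.results([("g", 15, 14, 500, 500)])   # 29 insertions
        r2 = self.results([("g", 200, 200, 5000, 5000)])  # 400 insertions
        cmp_ = compare_screens(r1, r2, min_insertions=30)
        assert not cmp_["passes_filter"].iloc[0]
        assert math.isnan(cmp_["delta_log2_mi"].iloc[0])

    def test_disjoint_gene_universes_rejected(self):
        r1 = self.results([("g1", 5, 5, 50, 50)])
        r2 = self.results([("g2", 5, 5, 50, 50)])
        with pytest.raises(ValueError):
            compare_screens(r1, r2)
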