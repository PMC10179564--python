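"""Hypothesis tests and FDR control: worked examples, oracles, invariants."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

import reachkin as rk
from reachkin.errors import ValidationError
from reachkin.features import FeatureMatrix


# ---------------------------------------------------------------------------
# Mann-Whitney U

def mwu_p_by_dp(x, y):
    """Exact two-sided Mann-Whitney p via the classic counting recursion
    over rank-sum distributions (independent of the combinations-based
    enumeration inside the implementation). Tie-free samples only."""
    n1, n2 = len(x), len(y)
    ranks = scipy.stats.rankdata(np.concatenate([x, y]))
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    # count subsets of {1..n} of size n1 by rank sum
    n = n1 + n2
    max_sum = n * (n + 1) // 2
    counts = np.zeros((n1 + 1, max_sum + 1), dtype=object)
    counts[0][0] = 1
    for r in range(1, n + 1):
        for k in range(min(r, n1), 0, -1):
            counts[k][r:] += counts[k - 1][:-r or None]
    total = comb(n, n1)
    mu = n1 * n2 / 2
    dev = abs(u_obs - mu)
    hits = 0
    for s in range(max_sum + 1):
        c = counts[n1][s]
        if c and abs((s - n1 * (n1 + 1) / 2) - mu) >= dev - 1e-12:
            hits += int(c)
    return hits / total


class TestMannWhitney:
    def test_fully_separated_small_samples(self):
        # all 20 assignments enumerated; only 2 reach |U - 4.5| >= 4.5
        assert rk.mann_whitney_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_symmetry_in_arguments(self, rng):
        x, y = rng.normal(size=8), rng.normal(size=5)
        assert rk.mann_whitney_p(x, y) == pytest.approx(rk.mann_whitney_p(y, x))

    def test_identical_samples_give_p_one(self):
        x = np.arange(20.0)
        assert rk.mann_whitney_p(x, x) == pytest.approx(1.0, abs=0.05)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            rk.mann_whitney_p([], [1.0])

    def test_exact_branch_equals_counting_recursion(self, rng):
        """All sample-size partitions with n1 + n2 <= 10."""
        for n1 in range(1, 10):
            for n2 in range(1, 11 - n1):
                x = rng.permutation(np.arange(n1 + n2, dtype=float))[:n1]
                y = np.setdiff1d(np.arange(n1 + n2, dtype=float), x)
                assert rk.mann_whitney_p(x, y) == pytest.approx(
                    mwu_p_by_dp(x, y), abs=1e-12), (n1, n2)

    def test_approximate_branch_tracks_reference(self, rng):
        """n=30 vs 30: within 0.01 of SciPy's tie-corrected asymptotic
        p-value and of a permutation Monte-Carlo estimate."""
        x = rng.normal(0.0, 1.0, 30)
        y = rng.normal(0.5, 1.0, 30)
        ours = rk.mann_whitney_p(x, y)
        ref = scipy.stats.mannwhitneyu(x, y, alternative="two-sided",
                                       method="asymptotic").pvalue
        assert ours == pytest.approx(ref, abs=1e-10)
        perm = scipy.stats.mannwhitneyu(
            x, y, alternative="two-sided",
            method=scipy.stats.PermutationMethod(n_resamples=10**5,
                                                 rng=np.random.default_rng(0))).pvalue
        assert ours == pytest.approx(perm, abs=0.01)

    def test_tied_data_uses_corrected_approximation(self):
        x = [1.0, 1.0, 2.0, 2.0, 3.0]
        y = [2.0, 3.0, 3.0, 4.0, 4.0]
        ref = scipy.stats.mannwhitneyu(x, y, alternative="two-sided",
                                       method="asymptotic").pvalue
        assert rk.mann_whitney_p(x, y) == pytest.approx(ref, abs=1e-10)


# ---------------------------------------------------------------------------
# Fisher exact

def fisher_p_by_enumeration(table):
    """Point-probability two-sided Fisher p with math.comb only."""
    (a, b), (c, d) = table
    n, r1, c1 = a + b + c + d, a + b, a + c
    denom = comb(n, c1)
    def pt(k):
        if k < 0 or k > r1 or c1 - k > n - r1:
            return 0.0
        return comb(r1, k) * comb(n - r1, c1 - k) / denom
    p_obs = pt(a)
    return sum(pt(k) for k in range(0, min(r1, c1) + 1)
               if pt(k) <= p_obs * (1 + 1e-7))


class TestFisherExact:
    @pytest.mark.parametrize("table,expected", [
        ([[2, 0], [0, 2]], 1 / 3),       # tails of the 2x2x2x2 hypergeometric
        ([[1, 1], [1, 1]], 1.0),         # observed table is the mode
        ([[5, 0], [0, 5]], 2 / 252),     # 2 / C(10, 5)
    ])
    def test_worked_examples(self, table, expected):
        assert rk.fisher_exact_p(table) == pytest.approx(expected, rel=1e-9)

    def test_matches_enumeration_and_scipy_on_random_tables(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 41))
            cells = rng.multinomial(n, [0.25] * 4)
            table = [[int(cells[0]), int(cells[1])], [int(cells[2]), int(cells[3])]]
            ours = rk.fisher_exact_p(table)
            assert ours == pytest.approx(fisher_p_by_enumeration(table), rel=1e-7)
            ref = scipy.stats.fisher_exact(table, alternative="two-sided")[1]
            assert ours == pytest.approx(ref, rel=1e-6, abs=1e-12)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValidationError):
            rk.fisher_exact_p([[1, -1], [0, 2]])

    def test_empty_table_rejected(self):
        with pytest.raises(ValidationError):
            rk.fisher_exact_p([[0, 0], [0, 0]])


# ---------------------------------------------------------------------------
# Benjamini-Yekutieli

def by_reject_by_scan(p, q):
    """Brute-force step-up: test every k directly."""
    p = np.asarray(p, dtype=float)
    m = p.size
    c = sum(1 / i for i in range(1, m + 1))
    order = np.argsort(p, kind="stable")
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / (m * c):
            k_star = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject


class TestBenjaminiYekutieli:
    def test_single_small_p_rejected(self):
        assert rk.benjamini_yekutieli([0.01], 0.05).tolist() == [True]

    def test_three_moderate_ps_all_kept(self):
        # thresholds k*0.05/(3*11/6): 0.00909, 0.01818, 0.02727
        assert rk.benjamini_yekutieli([0.01, 0.02, 0.04], 0.05).sum() == 0

    def test_only_leading_p_rejected(self):
        np.testing.assert_array_equal(
            rk.benjamini_yekutieli([0.001, 0.5, 0.9], 0.05), [True, False, False])

    def test_invalid_q_rejected(self):
        with pytest.raises(ValidationError):
            rk.benjamini_yekutieli([0.5], q=1.5)

    def test_nan_p_rejected(self):
        with pytest.raises(ValidationError):
            rk.benjamini_yekutieli([0.1, np.nan])

    @given(st.integers(0, 2**32 - 1), st.integers(1, 1000))
    @settings(derandomize=True, max_examples=40, deadline=None)
    def test_matches_scan_and_statsmodels(self, seed, m):
        p = np.random.default_rng(seed).uniform(size=m) ** 3
        ours = rk.benjamini_yekutieli(p, 0.05)
        np.testing.assert_array_equal(ours, by_reject_by_scan(p, 0.05))
        ref = multipletests(p, alpha=0.05, method="fdr_by")[0]
        np.testing.assert_array_equal(ours, ref)

    @given(st.integers(0, 2**32 - 1), st.integers(1, 300))
    @settings(derandomize=True, max_examples=30, deadline=None)
    def test_nested_in_bh_and_raw_rejections(self, seed, m):
        p = np.random.default_rng(seed).uniform(size=m) ** 2
        by = rk.benjamini_yekutieli(p, 0.05)
        bh = multipletests(p, alpha=0.05, method="fdr_bh")[0]
        raw = p <= 0.05
        assert not np.any(by & ~bh)
        assert not np.any(bh & ~raw)

    def test_monotone_in_single_p(self, rng):
        """Decreasing any one p-value never shrinks the rejection set."""
        p = rng.uniform(size=50) ** 2
        base = rk.benjamini_yekutieli(p, 0.05)
        for i in (0, 10, 49):
            p2 = p.copy()
            p2[i] = p2[i] / 10
            new = rk.benjamini_yekutieli(p2, 0.05)
            assert np.all(new[base])  # rejection set only grows


# ---------------------------------------------------------------------------
# matrix-level selection

def make_matrix(columns: dict, labels, kinds=None):
    values = pd.DataFrame(columns, dtype=float)
    values.index = pd.Index([f"r{i}" for i in range(len(values))], name="recording_id")
    kinds = kinds or {}
    return FeatureMatrix(
        values=values,
        value_kinds={c: kinds.get(c, "real") for c in values.columns},
        class_labels=pd.Series(list(labels), index=values.index),
    )


class TestSelectRelevant:
    def test_identical_column_not_rejected(self, rng):
        labels = ["G1"] * 10 + ["G0"] * 10
        m = make_matrix({"same": np.tile(np.arange(10.0), 2)}, labels)
        table = rk.select_relevant(m, rk.make_one_vs_rest(m.class_labels, "G1"))
        assert not table.table["rejected"].any()

    def test_perfect_binary_separation_rejected(self):
        labels = ["G1"] * 30 + ["G0"] * 30
        col = [1.0] * 30 + [0.0] * 30
        m = make_matrix({"sep": col}, labels, kinds={"sep": "binary"})
        table = rk.select_relevant(m, rk.make_one_vs_rest(m.class_labels, "G1"), q=0.05)
        row = table.table.iloc[0]
        assert row["test_name"] == "fisher_exact"
        assert row["rejected"]

    def test_rows_equal_testable_columns(self, rng):
        labels = ["G1"] * 8 + ["G0"] * 8
        cols = {
            "noise": rng.normal(size=16),
            "constant": np.ones(16),
            "all_nan": np.full(16, np.nan),
        }
        m = make_matrix(cols, labels)
        table = rk.select_relevant(m, rk.make_one_vs_rest(m.class_labels, "G1"))
        assert len(table.table) == 1
        assert table.n_skipped_constant == 1
        assert table.n_skipped_nan == 1
        assert table.m == 1

    def test_empty_label_group_rejected(self):
        with pytest.raises(ValidationError):
            rk.make_one_vs_rest(["G0", "G0"], "G1")


class TestOneVsRestCommon:
    def test_intersection_logic(self):
        tables = {}
        for cls, sig in (("G0", {"A", "B"}), ("G1", {"B", "C"}), ("G2", {"B"})):
            df = pd.DataFrame({
                "column_id": sorted(sig | {"Z"}),
                "problem": cls, "test_name": "mann_whitney_u",
                "p_value": 0.5, "rejected": [c in sig for c in sorted(sig | {"Z"})],
                "rank": 1,
            })
            tables[cls] = rk.RelevanceTable(positive_class=cls, q=0.05, table=df, m=len(df))
        common = rk.CommonFeatureSet(per_problem=tables)
        assert common.common == {"B"}
        assert common.per_problem_counts == {"G0": 2, "G1": 2, "G2": 1}

    def test_missing_class_rejected(self, rng):
        labels = ["G0"] * 5 + ["G1"] * 5
        m = make_matrix({"a": rng.normal(size=10)}, labels)
        with pytest.raises(ValidationError):
            rk.one_vs_rest_common(m)

    def test_strong_three_class_column_is_common(self, rng):
        """A column whose values are extreme for one class separates every
        one-vs-rest problem (directly for that class, via the shifted
        mixture for the others) and lands in the common set; null columns
        do not.  A rank test cannot distinguish a middle class from a
        symmetric mixture, so a common feature is two-level by nature."""
        labels = ["G0"] * 30 + ["G1"] * 30 + ["G2"] * 30
        strong = np.r_[np.zeros(30), np.ones(30) * 5, np.zeros(30)]
        strong += rng.normal(0, 0.1, 90)
        m = make_matrix({"strong": strong, "null": rng.normal(size=90)}, labels)
        common = rk.one_vs_rest_common(m, q=0.05)
        assert "strong" in common.common
        assert "null" not in common.common
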