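"""Ranked landscapes, quota curves, tail and rank tests.

The hypergeometric tail test is checked against exhaustive subset
enumeration and the Mann-Whitney exact p against full permutation
enumeration — oracles independent of the implementations they verify.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import fracrna as fr
from fracrna.landscape import hypergeom_upper_tail


def _landscape(ratios, classes=None):
    s = pd.Series(ratios, index=pd.Index(
        [f"g{i:03d}" for i in range(len(ratios))], name="gene_id"))
    cls = None
    if classes is not None:
        cls = pd.Series(classes, index=s.index)
    return fr.percentile_rank(s, cls)


def test_percentile_formula():
    ranked = _landscape([1.0, 2.0, 3.0, 4.0])
    assert list(ranked["percentile"]) == [12.5, 37.5, 62.5, 87.5]


def test_percentile_ties_broken_by_gene_id():
    s = pd.Series([2.0, 2.0, 2.0], index=["gc", "ga", "gb"])
    ranked = fr.percentile_rank(s)
    assert list(ranked.index) == ["ga", "gb", "gc"]


def test_percentile_order_invariant_to_input_order():
    s = pd.Series([3.0, 1.0, 2.0], index=["a", "b", "c"])
    r1 = fr.percentile_rank(s)
    r2 = fr.percentile_rank(s.iloc[::-1])
    pd.testing.assert_frame_equal(r1, r2)


def test_percentile_needs_two_genes():
    with pytest.raises(ValueError, match="2 genes"):
        fr.percentile_rank(pd.Series([1.0], index=["a"]))


def test_quota_all_genes_one_class_is_one():
    ranked = _landscape(np.arange(20.0), ["MPR"] * 20)
    quota = fr.quota_curve(ranked, ranked["loc_class"])
    assert (quota.loc[quota["loc_class"] == "MPR", "quota"] == 1.0).all()


def test_quota_top_decile_concentration():
    """10 MPRs among 100 genes, all in the top decile: quota 1 in the top
    window, 0 below the 80th percentile (brute-force window count)."""
    classes = ["CPR"] * 90 + ["MPR"] * 10
    ranked = _landscape(np.arange(100.0), classes)
    quota = fr.quota_curve(ranked, ranked["loc_class"], window_width=10, step=1)
    mpr = quota[quota["loc_class"] == "MPR"].set_index("center")["quota"]
    assert mpr.loc[100.0] == 1.0
    assert (mpr.loc[mpr.index <= 80.0] == 0.0).all()
    # independent brute-force count at one interior window
    c, w = 93.0, 10.0
    pct = ranked["percentile"].to_numpy()
    in_win = (pct >= c - w / 2) & (pct <= c + w / 2)
    expected = (ranked["loc_class"][in_win] == "MPR").mean()
    assert mpr.loc[c] == pytest.approx(expected)


def test_quota_window_wider_than_100_rejected():
    ranked = _landscape([1.0, 2.0])
    with pytest.raises(ValueError, match="width"):
        fr.quota_curve(ranked, ranked["ratio"], window_width=150)


def test_decile_counts_sum_to_class_size():
    rng = np.random.default_rng(0)
    classes = rng.choice(["MPR", "CPR"], size=57, p=[0.3, 0.7])
    ranked = _landscape(rng.lognormal(0, 1, 57), classes)
    edges = np.linspace(0, 100, 11)
    counts = sum(
        ((ranked["percentile"] > lo) & (ranked["percentile"] <= hi)
         & (ranked["loc_class"] == "MPR")).sum()
        for lo, hi in zip(edges[:-1], edges[1:]))
    assert counts == (classes == "MPR").sum()


# --------------------------------------------------------- hypergeometric

def test_hypergeom_worked_example():
    """N=10, n=4, K=5, k=4: 6 of the 252 possible tails hold all 4."""
    assert hypergeom_upper_tail(10, 4, 5, 4) == pytest.approx(6 / 252)


def test_hypergeom_k_zero_is_one():
    assert hypergeom_upper_tail(10, 4, 5, 0) == 1.0


def test_hypergeom_monotone_in_k():
    ps = [hypergeom_upper_tail(20, 8, 10, k) for k in range(9)]
    assert all(a >= b for a, b in zip(ps, ps[1:]))


def test_hypergeom_equals_subset_enumeration():
    """Exact summation agrees with exhaustive enumeration of all tails
    (every N <= 8, every n, K, k)."""
    for N in range(1, 9):
        for n in range(N + 1):
            cls = set(range(n))
            for K in range(N + 1):
                tally = np.zeros(min(n, K) + 1)
                for tail in itertools.combinations(range(N), K):
                    tally[len(cls & set(tail))] += 1
                total = math.comb(N, K)
                for k in range(min(n, K) + 1):
                    expected = tally[k:].sum() / total
                    assert hypergeom_upper_tail(N, n, K, k) == pytest.approx(
                        expected, abs=1e-12)


def test_tail_overrepresentation_counts():
    classes = ["MPR"] * 4 + ["CPR"] * 6
    # MPRs hold the 4 highest ratios
    ranked = _landscape(np.arange(10.0)[::-1], classes)
    res = fr.tail_overrepresentation(ranked, "MPR", tail_fraction=0.5, side="top")
    assert (res.n_total, res.class_size, res.n_tail, res.class_in_tail) == (10, 4, 5, 4)
    assert res.p_value == pytest.approx(6 / 252)
    bottom = fr.tail_overrepresentation(ranked, "MPR", 0.5, side="bottom")
    assert bottom.class_in_tail == 0 and bottom.p_value == 1.0


def test_tail_unknown_class_rejected():
    ranked = _landscape([1.0, 2.0], ["MPR", "MPR"])
    with pytest.raises(ValueError, match="CPR"):
        fr.tail_overrepresentation(ranked, "CPR")


# ------------------------------------------------------------------- FDR

def test_bh_step_up_hand_example():
    np.testing.assert_allclose(fr.bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])


def test_bh_single_and_equal_ps():
    assert fr.bh_fdr([0.2])[0] == pytest.approx(0.2)
    np.testing.assert_allclose(fr.bh_fdr([0.4, 0.4, 0.4]), [0.4, 0.4, 0.4])


def test_bh_rejects_bad_pvalues():
    with pytest.raises(ValueError):
        fr.bh_fdr([0.5, 1.5])


def test_adjust_tail_tests_q_at_least_p():
    classes = ["MPR"] * 5 + ["CPR"] * 15
    ranked = _landscape(np.arange(20.0)[::-1], classes)
    results = [fr.tail_overrepresentation(ranked, c, 0.3, s)
               for c in ("MPR", "CPR") for s in ("top", "bottom")]
    adjusted = fr.adjust_tail_tests(results)
    assert all(r.q_value >= r.p_value - 1e-15 for r in adjusted)


# ------------------------------------------------------------ rank tests

def _mw_permutation_p(a, b):
    """Full enumeration of group assignments (oracle)."""
    pooled = list(a) + list(b)
    n1 = len(a)
    ranks = pd.Series(pooled).rank().to_numpy()

    def u_stat(idx):
        r1 = ranks[list(idx)].sum()
        return r1 - n1 * (n1 + 1) / 2

    u_obs = u_stat(range(n1))
    mid = len(a) * len(b) / 2
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(u_stat(idx) - mid) >= abs(u_obs - mid) - 1e-12:
            hits += 1
    return hits / total


def test_mw_worked_example():
    res = fr.mann_whitney_test([1, 2], [3, 4])
    assert res.statistic == 0.0
    assert res.p_value == pytest.approx(2 / 6)
    assert res.method == "exact"


def test_mw_exact_matches_permutation_enumeration():
    rng = np.random.default_rng(7)
    for n1, n2 in [(2, 3), (3, 3), (4, 5), (6, 6)]:
        a = rng.normal(size=n1)
        b = rng.normal(0.5, size=n2)
        res = fr.mann_whitney_test(a, b)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(_mw_permutation_p(a, b), abs=1e-12)


def test_mw_symmetry():
    a, b = [1.0, 5.0, 2.0], [4.0, 3.0, 6.0]
    r1, r2 = fr.mann_whitney_test(a, b), fr.mann_whitney_test(b, a)
    assert r1.p_value == pytest.approx(r2.p_value)
    assert r1.statistic == pytest.approx(len(a) * len(b) - r2.statistic)


def test_mw_identical_samples_null():
    res = fr.mann_whitney_test([1, 2, 3], [1, 2, 3])
    assert res.p_value >= 0.99
    assert res.method == "asymptotic"  # ties force the approximation


def test_mw_empty_group_rejected():
    with pytest.raises(ValueError, match="non-empty"):
        fr.mann_whitney_test([], [1.0])


def test_ks_basic_properties():
    assert fr.ks_test([1, 2, 3], [1, 2, 3]).statistic == 0.0
    assert fr.ks_test([1, 2], [3, 4]).statistic == 1.0


def test_ks_invariant_under_monotone_transform():
    rng = np.random.default_rng(3)
    a, b = rng.normal(size=30), rng.normal(1.0, size=25)
    d1 = fr.ks_test(a, b).statistic
    d2 = fr.ks_test(np.exp(a), np.exp(b)).statistic
    assert d1 == pytest.approx(d2)


# ---------------------------------------------------------- class summary

def test_class_summary_percent_change():
    classes = ["MPR", "MPR", "CPR", "CPR"]
    ranked = _landscape([1.0, 3.0, 1.0, 1.0], classes)
    summary = fr.class_summary(ranked)
    overall = 1.5
    assert summary.loc["MPR", "mean_ratio"] == pytest.approx(2.0)
    assert summary.loc["MPR", "pct_change_vs_all"] == pytest.approx(
        100 * (2.0 - overall) / overall)
    all_one = fr.class_summary(_landscape([1.0, 2.0], ["MPR", "MPR"]))
    assert all_one.loc["MPR", "pct_change_vs_all"] == pytest.approx(0.0)
    assert fr.class_summary(
        _landscape([1.0, 2.0, 4.0], ["MPR"] * 3)).loc["MPR", "median_ratio"] == 2.0


# ---------------------------------------------------------- binder groups

def test_binder_groups_sizes_and_disjoint():
    rng = np.random.default_rng(5)
    n = 100
    ids = [f"g{i:03d}" for i in range(n)]
    ratios = pd.Series(rng.lognormal(0, 1, n), index=ids)
    classes = pd.Series(["MPR" if i % 2 == 0 else "CPR" for i in range(n)],
                        index=ids)
    weak, strong = fr.select_binder_groups(ratios, classes, "MPR",
                                           weak_fraction=0.3)
    assert len(weak) == len(strong)
    assert not set(weak) & set(strong)
    ranked = fr.percentile_rank(ratios, classes)
    bottom30 = set(ranked.head(30).index)
    assert all(g in bottom30 for g in weak)


def test_binder_groups_overlap_filtering():
    """Overlap sets shrink the groups the way the shared-detection filter
    does: removing 1 weak and 3 strong genes leaves 19 and 17."""
    n = 200
    ids = [f"g{i:03d}" for i in range(n)]
    ratios = pd.Series(np.arange(n, dtype=float) + 1, index=ids)
    # exactly 20 MPRs in the bottom 30%: place them at the very bottom
    classes = pd.Series(["MPR"] * 20 + ["CPR"] * 140 + ["MPR"] * 40, index=ids)
    weak, strong = fr.select_binder_groups(ratios, classes, "MPR",
                                           weak_fraction=0.3)
    assert len(weak) == 20 and len(strong) == 20
    detected = set(ids) - {weak[0]} - set(strong[:3])
    weak2, strong2 = fr.select_binder_groups(ratios, classes, "MPR", 0.3,
                                             overlap_sets=[detected])
    assert (len(weak2), len(strong2)) == (19, 17)


def test_binder_groups_empty_class_rejected():
    ratios = pd.Series([1.0, 2.0], index=["a", "b"])
    classes = pd.Series(["CPR", "CPR"], index=["a", "b"])
    with pytest.raises(ValueError, match="MPR"):
        fr.select_binder_groups(ratios, classes, "MPR")
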