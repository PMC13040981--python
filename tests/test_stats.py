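"""Unit and property tests for the rank tests, ANOVA/post hocs, 2x2 tests,
BH FDR and Spearman correlation, cross-checked against scipy where an
independent implementation exists."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from tedscore import stats


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("x, y, u_expected, p_expected", [
    ([1, 2, 3], [4, 5, 6], 9.0, 0.1),        # 2/C(6,3) both extremes
    ([5, 5, 5], [5, 5, 5], 4.5, 1.0),        # complete ties
    ([1, 2], [1, 2], 2.0, 1.0),              # identical samples
])
def test_mann_whitney_examples(x, y, u_expected, p_expected):
    res = stats.mann_whitney_u(x, y)
    assert res.statistic == pytest.approx(u_expected)
    assert res.p_value == pytest.approx(p_expected)


def test_mann_whitney_empty_input_rejected():
    with pytest.raises(ValueError):
        stats.mann_whitney_u([], [1.0])


def _mw_brute_force_p(x, y):
    """Two-sided exact p by enumerating every group assignment."""
    pooled = list(x) + list(y)
    nx, m = len(x), len(x) * len(y)

    def u_stat(xs, ys):
        return sum(1.0 for b in ys for a in xs if b > a)

    hi = max(u_stat(x, y), m - u_stat(x, y))
    n_extreme = total = 0
    for idx in itertools.combinations(range(len(pooled)), nx):
        chosen = set(idx)
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in chosen]
        u = u_stat(xs, ys)
        total += 1
        n_extreme += u >= hi or u <= m - hi
    return n_extreme / total


@given(st.sets(st.integers(-1000, 1000), min_size=4, max_size=10),
       st.integers(2, 8))
@settings(max_examples=30)
def test_mann_whitney_exact_matches_enumeration(values, nx):
    values = sorted(values)
    nx = min(nx, len(values) - 2)
    x, y = values[:nx], values[nx:]
    res = stats.mann_whitney_u(x, y, mode="exact")
    assert res.p_value == pytest.approx(_mw_brute_force_p(x, y))


def test_mann_whitney_normal_matches_scipy():
    rng = np.random.default_rng(0)
    x = rng.normal(size=30)
    y = rng.normal(0.8, size=25)
    res = stats.mann_whitney_u(x, y, mode="normal")
    ref = sps.mannwhitneyu(y, x, alternative="two-sided",
                           method="asymptotic", use_continuity=False)
    assert res.statistic == pytest.approx(float(ref.statistic))
    assert res.p_value == pytest.approx(float(ref.pvalue), rel=1e-10)


# ---------------------------------------------------------------------------
# Kruskal-Wallis and Dunn
# ---------------------------------------------------------------------------

def test_kruskal_wallis_identical_groups():
    res = stats.kruskal_wallis([[1.0, 1.0], [1.0, 1.0], [1.0, 1.0]])
    assert res.statistic == 0.0
    assert res.p_value == 1.0


def test_kruskal_wallis_hand_example():
    # rank means 2, 5, 8: H = 12/(9*10) * (3*4 + 3*25 + 3*64) - 3*10 = 7.2
    res = stats.kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
    assert res.statistic == pytest.approx(7.2)
    assert res.p_value == pytest.approx(float(sps.chi2.sf(7.2, 2)))


@given(st.integers(0, 1000))
@settings(max_examples=25)
def test_kruskal_wallis_two_groups_equals_z_squared(seed):
    rng = np.random.default_rng(seed)
    x = rng.choice(np.arange(20.0), size=rng.integers(3, 10))
    y = rng.choice(np.arange(20.0), size=rng.integers(3, 10))
    if np.concatenate([x, y]).std() == 0:
        return
    h = stats.kruskal_wallis([x, y]).statistic
    z = stats._mann_whitney_z(x, y)
    assert h == pytest.approx(z**2, abs=1e-10)


def test_kruskal_wallis_matches_scipy_with_ties():
    rng = np.random.default_rng(1)
    groups = [rng.integers(0, 6, size=n).astype(float) for n in (8, 12, 9)]
    res = stats.kruskal_wallis(groups)
    ref = sps.kruskal(*groups)
    assert res.statistic == pytest.approx(float(ref.statistic))
    assert res.p_value == pytest.approx(float(ref.pvalue))


def test_dunn_identical_groups_all_p_one():
    table = stats.dunn_posthoc([[2.0, 2.0]] * 3)
    assert all(p == 1.0 for p in table.p_adjusted)


def test_dunn_separated_groups_all_significant():
    # at n=10 per group every pairwise rank contrast clears 0.05; at n=5 the
    # adjacent-pair Dunn z (rank-mean gap 5, se sqrt(8)) is only 1.77, so
    # separation alone does not guarantee significance at tiny n
    groups = [list(range(1, 11)), list(range(21, 31)), list(range(41, 51))]
    table = stats.dunn_posthoc(groups)
    assert all(p < 0.05 for p in table.p_adjusted)
    small = stats.dunn_posthoc(
        [list(range(1, 6)), list(range(11, 16)), list(range(21, 26))])
    assert small.p_adjusted[small.pairs.index((0, 2))] < 0.05


def test_dunn_bh_never_below_raw():
    rng = np.random.default_rng(2)
    groups = [rng.normal(m, 1, size=6) for m in (0.0, 0.3, 0.6, 0.2)]
    table = stats.dunn_posthoc(groups, adjustment="bh")
    raw = stats.dunn_posthoc(groups, adjustment="none")
    assert table.p_raw == raw.p_adjusted
    for adj, p in zip(table.p_adjusted, table.p_raw):
        assert adj >= p - 1e-12


def test_dunn_needs_three_groups():
    with pytest.raises(ValueError):
        stats.dunn_posthoc([[1, 2], [3, 4]])


# ---------------------------------------------------------------------------
# ANOVA and Tukey
# ---------------------------------------------------------------------------

def test_anova_identical_groups():
    res = stats.anova_oneway([[3.0, 3.0], [3.0, 3.0]])
    assert res.statistic == 0.0
    assert res.p_value == 1.0


def test_anova_hand_example():
    # SSB = 1.5, SSW = 4, df (1, 4): F = 1.5
    res = stats.anova_oneway([[1, 2, 3], [2, 3, 4]])
    assert res.statistic == pytest.approx(1.5)
    ref = sps.f_oneway([1, 2, 3], [2, 3, 4])
    assert res.p_value == pytest.approx(float(ref.pvalue))


def test_anova_matches_scipy_random():
    rng = np.random.default_rng(3)
    groups = [rng.normal(m, 1.2, size=n)
              for m, n in ((0, 7), (0.5, 9), (1.0, 6))]
    res = stats.anova_oneway(groups)
    ref = sps.f_oneway(*groups)
    assert res.statistic == pytest.approx(float(ref.statistic))
    assert res.p_value == pytest.approx(float(ref.pvalue))


@pytest.mark.parametrize("q, k, df", [(3.5, 4, 20), (2.0, 3, 10), (5.0, 4, 6)])
def test_studentized_range_cdf_matches_scipy(q, k, df):
    ours = stats.studentized_range_cdf(q, k, df)
    ref = float(sps.studentized_range.cdf(q, k, df))
    assert ours == pytest.approx(ref, abs=1e-7)


def test_tukey_matches_scipy_and_is_monotone_in_q():
    rng = np.random.default_rng(4)
    groups = [rng.normal(m, 1.0, size=6) for m in (0.0, 0.8, 2.0)]
    table = stats.tukey_hsd(groups)
    ref = sps.tukey_hsd(*groups)
    for (i, j), p in zip(table.pairs, table.p_adjusted):
        assert p == pytest.approx(float(ref.pvalue[i, j]), abs=1e-6)
    # larger |q| never yields a larger p
    order = np.argsort(table.statistics)
    ps = np.array(table.p_adjusted)[order]
    assert np.all(np.diff(ps) <= 1e-12)


# ---------------------------------------------------------------------------
# 2x2 tables
# ---------------------------------------------------------------------------

def test_chi2_smoking_table_matches_printed_convention():
    # 31*(15-90)^2 / (21*10*8*23); uncorrected Pearson chi-square
    res = stats.chi2_2x2([[3, 18], [5, 5]])
    assert res.statistic == pytest.approx(174375 / 38640)
    assert res.p_value == pytest.approx(0.0337, abs=5e-4)


def test_chi2_balanced_table_null():
    res = stats.chi2_2x2([[10, 10], [10, 10]])
    assert res.statistic == 0.0
    assert res.p_value == 1.0


def test_chi2_invariant_under_transpose_and_swaps():
    base = stats.chi2_2x2([[3, 18], [5, 5]]).p_value
    assert stats.chi2_2x2([[18, 3], [5, 5]][::-1]).p_value == pytest.approx(base)
    assert stats.chi2_2x2([[3, 5], [18, 5]]).p_value == pytest.approx(base)
    assert stats.chi2_2x2([[5, 5], [3, 18]]).p_value == pytest.approx(base)


def test_chi2_yates_matches_scipy():
    table = [[7, 12], [9, 4]]
    res = stats.chi2_2x2(table, yates=True)
    chi2, p, _, _ = sps.chi2_contingency(table, correction=True)
    assert res.statistic == pytest.approx(float(chi2))
    assert res.p_value == pytest.approx(float(p))


def test_chi2_zero_margin_rejected():
    with pytest.raises(ValueError):
        stats.chi2_2x2([[0, 0], [5, 5]])


def test_fisher_exact_matches_scipy():
    for table in ([[3, 18], [5, 5]], [[2, 7], [8, 2]], [[1, 9], [11, 3]]):
        ours = stats.fisher_exact_2x2(table)
        ref = sps.fisher_exact(table)
        assert ours.p_value == pytest.approx(float(ref.pvalue), rel=1e-9)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("p, q_expected", [
    ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
    ([0.5, 0.5, 0.5], [0.5, 0.5, 0.5]),
    ([0.123], [0.123]),
])
def test_bh_fdr_examples(p, q_expected):
    assert stats.bh_fdr(p).q_values == pytest.approx(q_expected)


@given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40),
       st.randoms(use_true_random=False))
@settings(max_examples=50)
def test_bh_fdr_invariants(p, rnd):
    res = stats.bh_fdr(p)
    assert all(q >= pi - 1e-12 for q, pi in zip(res.q_values, res.p_values))
    assert all(q <= 1.0 for q in res.q_values)
    # permutation equivariance
    perm = list(range(len(p)))
    rnd.shuffle(perm)
    shuffled = stats.bh_fdr([p[i] for i in perm]).q_values
    for j, i in enumerate(perm):
        assert shuffled[j] == pytest.approx(res.q_values[i])


def test_bh_fdr_rejects_bad_p():
    with pytest.raises(ValueError):
        stats.bh_fdr([0.5, 1.5])


# ---------------------------------------------------------------------------
# Spearman and Welch
# ---------------------------------------------------------------------------

def test_spearman_monotone_extremes():
    assert stats.spearman([1, 2, 3, 4], [10, 20, 30, 40]).statistic == 1.0
    assert stats.spearman([1, 2, 3, 4], [8, 6, 4, 2]).statistic == -1.0


def test_spearman_hand_example_matches_scipy():
    # rank differences (0, -1, 1, -1, 1): rho = 1 - 6*4/120 = 0.8
    res = stats.spearman([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
    ref = sps.spearmanr([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
    assert res.statistic == pytest.approx(0.8)
    assert res.statistic == pytest.approx(float(ref.statistic))
    assert res.p_value == pytest.approx(float(ref.pvalue))


def test_spearman_constant_input_rejected():
    with pytest.raises(ValueError):
        stats.spearman([1, 1, 1], [1, 2, 3])


def test_welch_t_matches_scipy():
    rng = np.random.default_rng(5)
    x = rng.normal(0, 1, size=9)
    y = rng.normal(1, 2, size=7)
    res = stats.welch_t(x, y)
    ref = sps.ttest_ind(y, x, equal_var=False)
    assert res.statistic == pytest.approx(float(ref.statistic))
    assert res.p_value == pytest.approx(float(ref.pvalue))


# ---------------------------------------------------------------------------
# fuzz: p-values always land in [0, 1]
# ---------------------------------------------------------------------------

def test_p_values_in_unit_interval_fuzz():
    rng = np.random.default_rng(6)
    for _ in range(300):
        n1, n2 = rng.integers(2, 12, size=2)
        x = rng.choice(np.arange(8.0), size=n1)
        y = rng.choice(np.arange(8.0), size=n2) + rng.normal()
        for res in (stats.mann_whitney_u(x, y),
                    stats.welch_t(x, y),
                    stats.kruskal_wallis([x, y])):
            assert 0.0 <= res.p_value <= 1.0
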