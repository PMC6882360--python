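import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from circskin import differential as diff


# ----------------------------------------------------------------- t tests

def test_welch_identical_groups():
    res = diff.welch_t([1, 2, 3], [1, 2, 3])
    assert res.statistic == 0.0
    assert res.p_value == 1.0


def test_welch_matches_scipy():
    res = diff.welch_t([10, 11, 12], [0, 1, 2])
    ref = st.ttest_ind([10, 11, 12], [0, 1, 2], equal_var=False)
    assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)


def test_paired_t_constant_positive_differences():
    res = diff.paired_t([1.0] * 6)
    assert res.degenerate
    assert res.p_value < 1e-12


def test_paired_t_matches_scipy():
    rng = np.random.default_rng(42)
    a, b = rng.normal(size=8), rng.normal(size=8)
    res = diff.paired_t(x=a, y=b)
    ref = st.ttest_rel(a, b)
    assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)


# ---------------------------------------------------------------- wilcoxon

def test_wilcoxon_antisymmetric_differences():
    res = diff.wilcoxon_signed_rank([3, -3, 1, -1, 2, -2])
    assert res.p_value == pytest.approx(1.0)


def test_wilcoxon_exact_matches_scipy():
    rng = np.random.default_rng(1)
    d = rng.normal(size=12)
    res = diff.wilcoxon_signed_rank(d)
    ref = st.wilcoxon(d, mode="exact")
    assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)


def test_wilcoxon_normal_matches_scipy_on_ties():
    d = [1.0, 1.0, -1.0, 2.0, 3.0, -2.0, 4.0, 4.0, 5.0]
    res = diff.wilcoxon_signed_rank(d)
    ref = st.wilcoxon(d, mode="approx", correction=False)
    assert res.test == "wilcoxon_normal"
    assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)


def test_global_paired_wilcoxon_dominance_and_symmetry():
    a = np.arange(20, dtype=float)
    b = a + 1.0
    res = diff.global_paired_wilcoxon(a, b)
    assert res.p_value < 1e-3
    assert diff.global_paired_wilcoxon(b, a).p_value == pytest.approx(
        res.p_value)
    assert diff.global_paired_wilcoxon(a, a).degenerate


# ------------------------------------------------------------ mann-whitney

def test_mann_whitney_separated_groups_minimal_p():
    res = diff.mann_whitney_u([1, 2, 3], [101, 102, 103])
    assert res.statistic == 0.0
    # most extreme of C(6,3)=20 arrangements, doubled for two sides
    assert res.p_value == pytest.approx(2 / 20)


def test_mann_whitney_exact_matches_scipy():
    rng = np.random.default_rng(3)
    x, y = rng.normal(size=9), rng.normal(size=7)
    res = diff.mann_whitney_u(x, y)
    ref = st.mannwhitneyu(x, y, method="exact")
    assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)


def test_mann_whitney_asymptotic_matches_scipy_with_ties():
    x = [1, 2, 2, 3, 4, 5, 5, 6] * 4
    y = [2, 3, 3, 4, 5, 6, 7, 8] * 4
    res = diff.mann_whitney_u(x, y)
    ref = st.mannwhitneyu(x, y, method="asymptotic")
    assert res.test == "mann_whitney_normal"
    assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)


# ------------------------------------------------------------- chi-squared

def test_chi2_uniform_table():
    res = diff.chi2_independence([[10, 10], [10, 10]])
    assert res.statistic == 0.0
    assert res.p_value == pytest.approx(1.0)


def test_chi2_hand_arithmetic():
    res = diff.chi2_independence([[30, 10], [10, 30]])
    assert res.statistic == pytest.approx(20.0, abs=1e-12)
    ref = st.chi2_contingency([[30, 10], [10, 30]], correction=False)
    assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)


def test_chi2_zero_marginal_degenerate():
    res = diff.chi2_independence([[5, 7], [0, 0]])
    assert res.degenerate


# -------------------------------------------------------------- regression

def test_ols_matches_scipy_linregress():
    rng = np.random.default_rng(5)
    x = rng.normal(size=30)
    y = 2.0 * x + rng.normal(size=30)
    res = diff.ols_regression(x, y)
    ref = st.linregress(x, y)
    assert res.slope == pytest.approx(ref.slope, abs=1e-12)
    assert res.intercept == pytest.approx(ref.intercept, abs=1e-12)
    assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)
    assert res.slope_se == pytest.approx(ref.stderr, abs=1e-12)


def test_ols_ci_covers_iff_f_not_significant():
    rng = np.random.default_rng(6)
    for _ in range(50):
        x = rng.normal(size=12)
        y = rng.normal(size=12) + rng.uniform(-0.5, 0.5) * x
        res = diff.ols_regression(x, y)
        lo, hi = res.slope_ci95()
        assert (lo <= 0.0 <= hi) == (res.p_value >= 0.05)


def test_ols_exact_linear():
    x = np.arange(10, dtype=float)
    res = diff.ols_regression(x, 3.0 * x + 1.0)
    assert res.r_squared == pytest.approx(1.0)
    assert res.p_value == 0.0


# ----------------------------------------- size factors and classification

def test_sizefactors_scaling_identity():
    x = pd.DataFrame({"a": [2.0, 5.0, 9.0], "b": [4.0, 10.0, 18.0]})
    factors, normalized = diff.median_of_ratios_sizefactors(x)
    assert factors["b"] / factors["a"] == pytest.approx(2.0, abs=1e-12)
    assert np.allclose(normalized["a"], normalized["b"])


def test_sizefactors_hand_arithmetic():
    x = pd.DataFrame({"a": [2.0, 2.0, 2.0], "b": [4.0, 4.0, 4.0]})
    factors, _ = diff.median_of_ratios_sizefactors(x)
    assert factors["a"] == pytest.approx(1 / math.sqrt(2), abs=1e-12)
    assert factors["b"] == pytest.approx(math.sqrt(2), abs=1e-12)


def test_sizefactors_recover_planted_library_factors(default_sim):
    sim = default_sim
    factors, _ = diff.median_of_ratios_sizefactors(sim.counts.genes)
    planted = pd.Series(sim.truth.library_factors)
    ratio = factors / planted.loc[factors.index]
    # equal up to a common scale and counting noise
    rel = ratio / np.exp(np.mean(np.log(ratio)))
    assert float(np.abs(np.log(rel)).max()) < 0.05


def test_log_pseudo_value():
    assert diff.log_pseudo_value([0.0, 4.0, 8.0]) == 2.0
    with pytest.raises(ValueError):
        diff.log_pseudo_value([0.0, 0.0])


def test_host_independence_classification():
    assert diff.host_independence_classify(0.25, 0.25) == "host-independent"
    assert diff.host_independence_classify(0.25, 1.0) == "host-dependent"
    assert diff.host_independence_classify(0.25, 1.0,
                                           band=math.inf) == "host-independent"


def test_overlap_stats():
    res = diff.overlap_stats({1, 2, 3}, {2, 3, 4, 5})
    assert res["n_union"] == 5
    assert res["overlap_percent"] == 40.0
    assert diff.overlap_stats({1}, {2})["overlap_percent"] == 0.0


def test_benjamini_hochberg_monotone_and_manual():
    p = np.array([0.01, 0.04, 0.03, 0.20])
    adj = diff.benjamini_hochberg(p)
    # manual BH: sorted (0.01,0.03,0.04,0.20); step-up with monotone
    # enforcement gives (0.04, 0.0533.., 0.0533.., 0.20)
    assert adj[0] == pytest.approx(0.04)
    assert adj[1] == pytest.approx(0.04 * 4 / 3)
    assert adj[2] == pytest.approx(0.04 * 4 / 3)
    assert adj[3] == pytest.approx(0.20)
    assert np.all(adj >= p)
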