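"""Differential-expression statistics for the paired lesional/non-lesional design.

Implements the comparisons used throughout the pipeline: per-feature Welch
(unequal-variance) t tests for volcano plots, global Wilcoxon matched-pairs
signed-rank tests, paired t tests for individual genes, Mann-Whitney U,
Pearson chi-squared on 2x2 tables, ordinary least squares with an F test for
a non-zero slope, and DESeq2-style median-of-ratios size factors.

The test statistics are computed from their closed forms (with exact
small-sample null distributions for the rank tests built by dynamic
programming); only the reference distributions (t, normal, chi2, F) come
from scipy.  No multiple-testing correction is applied by default; a
Benjamini-Hochberg option exists but is off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _st

__all__ = [
    "DiffResult",
    "welch_t",
    "per_feature_welch",
    "paired_t",
    "wilcoxon_signed_rank",
    "global_paired_wilcoxon",
    "mann_whitney_u",
    "chi2_independence",
    "ols_regression",
    "median_of_ratios_sizefactors",
    "host_independence_classify",
    "overlap_stats",
    "benjamini_hochberg",
    "log_pseudo_value",
]


@dataclass
class DiffResult:
    """One feature's differential-expression summary."""

    feature: str
    mean_a: float  # lesional
    mean_b: float  # non-lesional
    fold_change: float  # mean_a / mean_b
    p_value: float
    test: str
    degenerate: bool = False

    @property
    def downregulated_gt2fold(self) -> bool:
        return self.fold_change < 0.5


@dataclass
class TestResult:
    statistic: float
    p_value: float
    test: str
    degenerate: bool = False


# --------------------------------------------------------------------------
# t tests
# --------------------------------------------------------------------------

def welch_t(x, y) -> TestResult:
    """Two-sample t test without assuming equal variances (Welch)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("welch_t requires at least 2 observations per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = len(x), len(y)
    se2 = vx / nx + vy / ny
    if se2 == 0.0:
        if x.mean() == y.mean():
            return TestResult(0.0, 1.0, "welch_t", degenerate=True)
        return TestResult(math.inf, 0.0, "welch_t", degenerate=True)
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * _st.t.sf(abs(t), df)
    return TestResult(t, p, "welch_t")


def paired_t(diffs=None, x=None, y=None) -> TestResult:
    """Classical paired t test on per-pair differences."""
    if diffs is None:
        diffs = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = np.asarray(diffs, dtype=float)
    n = len(d)
    if n < 3:
        raise ValueError("paired_t requires at least 3 pairs")
    sd = d.std(ddof=1)
    if sd == 0.0:
        if d.mean() == 0.0:
            return TestResult(0.0, 1.0, "paired_t", degenerate=True)
        return TestResult(math.inf if d.mean() > 0 else -math.inf, 0.0,
                          "paired_t", degenerate=True)
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * _st.t.sf(abs(t), n - 1)
    return TestResult(t, p, "paired_t")


def per_feature_welch(values: pd.DataFrame, condition: pd.Series,
                      group_a: str = "lesional",
                      group_b: str = "non-lesional") -> list[DiffResult]:
    """Welch t test per feature (row); no multiplicity correction.

    ``values`` is features x samples; ``condition`` maps sample -> group.
    Fold change is mean(group_a) / mean(group_b); a zero group_b mean gives
    inf, preserved in the output table.
    """
    cols_a = [s for s in values.columns if condition[s] == group_a]
    cols_b = [s for s in values.columns if condition[s] == group_b]
    results = []
    for feature, row in values.iterrows():
        xa = row[cols_a].to_numpy(dtype=float)
        xb = row[cols_b].to_numpy(dtype=float)
        res = welch_t(xa, xb)
        ma, mb = xa.mean(), xb.mean()
        fc = ma / mb if mb > 0 else math.inf if ma > 0 else math.nan
        results.append(
            DiffResult(str(feature), ma, mb, fc, res.p_value, "welch_t",
                       res.degenerate)
        )
    return results


def diff_results_frame(results: list[DiffResult]) -> pd.DataFrame:
    """Volcano-plot table: id, means, fc, log2fc, p."""
    frame = pd.DataFrame(
        {
            "feature": [r.feature for r in results],
            "mean_lesional": [r.mean_a for r in results],
            "mean_non_lesional": [r.mean_b for r in results],
            "fold_change": [r.fold_change for r in results],
            "p_value": [r.p_value for r in results],
            "degenerate": [r.degenerate for r in results],
        }
    ).set_index("feature")
    with np.errstate(divide="ignore", invalid="ignore"):
        frame["log2_fold_change"] = np.log2(frame["fold_change"])
    frame["downregulated_gt2fold"] = frame["fold_change"] < 0.5
    return frame


# --------------------------------------------------------------------------
# rank tests
# --------------------------------------------------------------------------

def _signed_rank_counts(n: int) -> np.ndarray:
    """Null distribution of W+ for n untied non-zero differences.

    counts[w] = number of sign assignments with positive-rank sum w.
    """
    max_w = n * (n + 1) // 2
    counts = np.zeros(max_w + 1, dtype=float)
    counts[0] = 1.0
    for rank in range(1, n + 1):
        shifted = np.zeros_like(counts)
        shifted[rank:] = counts[: max_w + 1 - rank]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank(x, y=None) -> TestResult:
    """Wilcoxon matched-pairs signed-rank test (two-sided).

    Zero differences are dropped.  The exact null distribution is used for
    n <= 25 pairs when there are no zeros and no tied absolute differences;
    otherwise the normal approximation with tie correction is applied.
    """
    d = np.asarray(x, dtype=float)
    if y is not None:
        d = d - np.asarray(y, dtype=float)
    n_zero = int(np.sum(d == 0))
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return TestResult(math.nan, math.nan, "wilcoxon", degenerate=True)
    ranks = _st.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    has_ties = len(np.unique(np.abs(d))) != n
    if n <= 25 and n_zero == 0 and not has_ties:
        counts = _signed_rank_counts(n)
        total = counts.sum()
        w = int(round(w_plus))
        p_le = counts[: w + 1].sum() / total
        p_ge = counts[w:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return TestResult(w_plus, p, "wilcoxon_exact")
    mean_w = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / 48.0
    var_w = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var_w == 0:
        return TestResult(w_plus, math.nan, "wilcoxon_normal", degenerate=True)
    z = (w_plus - mean_w) / math.sqrt(var_w)
    p = 2.0 * _st.norm.sf(abs(z))
    return TestResult(w_plus, min(1.0, p), "wilcoxon_normal")


def global_paired_wilcoxon(values_a, values_b) -> TestResult:
    """Global comparison of per-feature means between two conditions.

    Features are the pairing unit: for each feature its mean in condition A
    is compared to its mean in condition B with the signed-rank test.
    All-zero differences are flagged degenerate rather than tested.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    if np.all(a == b):
        return TestResult(math.nan, math.nan, "wilcoxon", degenerate=True)
    return wilcoxon_signed_rank(a, b)


def _mann_whitney_counts(n: int, m: int) -> np.ndarray:
    """Null distribution of U for group sizes n, m without ties.

    counts[u] = number of arrangements with U statistic u, via the standard
    recursion over partial sums.
    """
    # classical recurrence f(n, m, u) = f(n-1, m, u - m) + f(n, m-1, u)
    memo: dict[tuple[int, int], np.ndarray] = {}

    def f(a: int, b: int) -> np.ndarray:
        if (a, b) in memo:
            return memo[(a, b)]
        if a == 0 or b == 0:
            out = np.zeros(a * b + 1)
            out[0] = 1.0
        else:
            left = f(a - 1, b)
            right = f(a, b - 1)
            out = np.zeros(a * b + 1)
            out[b : b + len(left)] += left
            out[: len(right)] += right
        memo[(a, b)] = out
        return out

    return f(n, m)


def mann_whitney_u(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact null distribution when there are no ties and n*m <= 400 (matching
    the small-sample regimes in this pipeline); otherwise the normal
    approximation with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValueError("mann_whitney_u requires non-empty groups")
    combined = np.concatenate([x, y])
    ranks = _st.rankdata(combined)
    r_x = ranks[:n].sum()
    u_x = r_x - n * (n + 1) / 2.0
    has_ties = len(np.unique(combined)) != n + m
    if not has_ties and n * m <= 400:
        counts = _mann_whitney_counts(n, m)
        total = counts.sum()
        u = int(round(u_x))
        p_le = counts[: u + 1].sum() / total
        p_ge = counts[u:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return TestResult(u_x, p, "mann_whitney_exact")
    mean_u = n * m / 2.0
    nm = n + m
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (nm * (nm - 1))
    var_u = n * m / 12.0 * (nm + 1 - tie_term)
    if var_u == 0:
        return TestResult(u_x, 1.0, "mann_whitney_normal", degenerate=True)
    z = (u_x - mean_u - math.copysign(0.5, u_x - mean_u)) / math.sqrt(var_u)
    if u_x == mean_u:
        z = 0.0
    p = 2.0 * _st.norm.sf(abs(z))
    return TestResult(u_x, min(1.0, p), "mann_whitney_normal")


# --------------------------------------------------------------------------
# chi-squared, regression
# --------------------------------------------------------------------------

def chi2_independence(table, correction: bool = False) -> TestResult:
    """Pearson chi-squared test of independence on a 2x2 (or RxC) table.

    No Yates continuity correction by default.  A zero row or column
    marginal is flagged degenerate.
    """
    obs = np.asarray(table, dtype=float)
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    total = obs.sum()
    if np.any(row == 0) or np.any(col == 0):
        return TestResult(math.nan, math.nan, "chi2", degenerate=True)
    expected = np.outer(row, col) / total
    diff = np.abs(obs - expected)
    if correction:
        diff = np.maximum(diff - 0.5, 0.0)
    chi2 = float(np.sum(diff**2 / expected))
    dof = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(_st.chi2.sf(chi2, dof))
    return TestResult(chi2, p, "chi2")


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    f_statistic: float
    p_value: float
    n: int
    slope_se: float = math.nan
    degenerate: bool = False

    def slope_ci95(self) -> tuple[float, float]:
        """95% confidence interval for the slope (t-based)."""
        if not math.isfinite(self.slope_se):
            return (math.nan, math.nan)
        half = float(_st.t.ppf(0.975, self.n - 2)) * self.slope_se
        return (self.slope - half, self.slope + half)


def ols_regression(x, y) -> RegressionResult:
    """Simple least squares of y on x with an F test for non-zero slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("regression requires at least 3 points")
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx == 0:
        return RegressionResult(math.nan, math.nan, math.nan, math.nan,
                                math.nan, n, degenerate=True)
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - intercept - slope * x
    ss_res = np.sum(resid**2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        # y constant: slope is 0 exactly, nothing to test
        return RegressionResult(slope, intercept, 1.0, math.nan, math.nan, n,
                                degenerate=True)
    r2 = 1.0 - ss_res / ss_tot
    if ss_res == 0:
        return RegressionResult(slope, intercept, 1.0, math.inf, 0.0, n)
    f = (n - 2) * (ss_tot - ss_res) / ss_res
    p = float(_st.f.sf(f, 1, n - 2))
    se = math.sqrt(ss_res / (n - 2) / sxx)
    return RegressionResult(slope, intercept, r2, f, p, n, slope_se=se)


# --------------------------------------------------------------------------
# normalization, classification, set overlap
# --------------------------------------------------------------------------

def median_of_ratios_sizefactors(counts: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """DESeq2 median-of-ratios size factors and normalized counts.

    For every gene with non-zero counts in all samples, the ratio of its
    count to its geometric mean across samples is formed; each sample's
    size factor is the median of these ratios.  Raises when no gene is
    non-zero everywhere.
    """
    mat = counts.to_numpy(dtype=float)
    all_nonzero = np.all(mat > 0, axis=1)
    if not np.any(all_nonzero):
        raise ValueError("no gene with non-zero counts in every sample")
    ref = mat[all_nonzero]
    log_geomean = np.mean(np.log(ref), axis=1, keepdims=True)
    ratios = np.exp(np.log(ref) - log_geomean)
    factors = pd.Series(np.median(ratios, axis=0), index=counts.columns,
                        name="size_factor")
    normalized = counts / factors
    return factors, normalized


def log_pseudo_value(means) -> float:
    """Half the smallest non-zero value; substitute for zero means on log scales."""
    arr = np.asarray(means, dtype=float)
    nonzero = arr[arr > 0]
    if len(nonzero) == 0:
        raise ValueError("all means are zero")
    return float(nonzero.min() / 2.0)


def host_independence_classify(fc_rpm: float, fc_ctl: float,
                               band: float = 1.0) -> str:
    """Classify a circRNA's change as host-independent or host-dependent.

    A circRNA whose RPM fold change and CTL fold change sit within ``band``
    log2 units of the diagonal changed independently of its host gene.
    """
    if fc_rpm <= 0 or fc_ctl <= 0:
        raise ValueError("fold changes must be positive (apply a pseudo-value)")
    off_diagonal = abs(math.log2(fc_rpm) - math.log2(fc_ctl))
    return "host-independent" if off_diagonal <= band else "host-dependent"


def overlap_stats(set_a, set_b) -> dict:
    """Venn-diagram arithmetic: sizes, intersection, union, overlap percent."""
    a, b = set(set_a), set(set_b)
    if not a and not b:
        raise ValueError("both sets are empty")
    inter = a & b
    union = a | b
    return {
        "n_a": len(a),
        "n_b": len(b),
        "n_intersection": len(inter),
        "n_union": len(union),
        "overlap_percent": round(100.0 * len(inter) / len(union), 1),
    }


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted p values (optional; the default pipeline reports raw p)."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adjusted = np.empty(n)
    prev = 1.0
    for rank_idx in range(n - 1, -1, -1):
        i = order[rank_idx]
        val = min(prev, p[i] * n / (rank_idx + 1))
        adjusted[i] = val
        prev = val
    return adjusted
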