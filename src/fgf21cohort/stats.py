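"""Cohort statistics: Williams-corrected G-tests, normality-dispatched group
comparisons, Spearman correlation, and order-statistic median CIs.

Categorical variables are compared with the likelihood-ratio G-test,
G = 2 sum O ln(O/E), divided by Williams' (1976) correction factor q before
the chi-square tail is taken:

* goodness of fit (k cells, N observations):
  q = 1 + (k^2 - 1) / (6 N (k - 1))
* r x c independence:
  q = 1 + (N sum 1/row - 1)(N sum 1/col - 1) / (6 N (r - 1)(c - 1))

Multi-way comparisons use Bonferroni-style corrected alphas (.05/n_way,
reported to 3 dp: .017 for three-way, .025 for two-way).  Continuous
variables are dispatched on per-group Shapiro-Wilk normality (alpha .05):
all-normal goes to equal-variance t / ANOVA, otherwise Wilcoxon rank-sum /
Kruskal-Wallis.  The distribution-free median CI takes the j-th and k-th
order statistics with j the largest index whose Binomial(n, 1/2) lower tail
stays within (1 - level)/2, k = n + 1 - j.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from fgf21cohort.dge import rank_sum_test

logger = logging.getLogger("fgf21cohort")

SHAPIRO_ALPHA = 0.05


# ---------------------------------------------------------------------------
# G-test with Williams' correction
# ---------------------------------------------------------------------------

@dataclass
class GTestResult:
    G: float
    q_williams: float
    G_adj: float
    df: int
    p: float
    mode: str


def _g_statistic(observed: np.ndarray, expected: np.ndarray) -> float:
    if np.any(expected <= 0):
        raise ValueError("expected cell(s) of 0; cannot form G")
    mask = observed > 0
    return float(2.0 * np.sum(observed[mask] * np.log(observed[mask] / expected[mask])))


def g_test_gof(observed, expected_props=None) -> GTestResult:
    """Goodness-of-fit G-test of a k-cell count vector against expected
    proportions (equal by default), with Williams' correction."""
    obs = np.asarray(observed, dtype=float)
    if obs.ndim != 1 or len(obs) < 2:
        raise ValueError("goodness of fit needs a 1-d vector of >= 2 cells")
    n = obs.sum()
    if n == 0:
        raise ValueError("empty table (N = 0)")
    k = len(obs)
    if expected_props is None:
        props = np.full(k, 1.0 / k)
    else:
        props = np.asarray(expected_props, dtype=float)
        if len(props) != k or not np.isclose(props.sum(), 1.0):
            raise ValueError("expected proportions must match cells and sum to 1")
    expected = n * props
    g = _g_statistic(obs, expected)
    df = k - 1
    q = 1.0 + (k ** 2 - 1) / (6.0 * n * df)
    g_adj = g / q
    return GTestResult(G=g, q_williams=q, G_adj=g_adj, df=df,
                       p=float(sps.chi2.sf(g_adj, df)), mode="gof")


def g_test_independence(table) -> GTestResult:
    """r x c independence G-test with Williams' correction."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("independence test needs an r x c table with r, c >= 2")
    n = obs.sum()
    if n == 0:
        raise ValueError("empty table (N = 0)")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("zero row/column margin; expected cells would be 0")
    expected = np.outer(rows, cols) / n
    g = _g_statistic(obs, expected)
    r, c = obs.shape
    df = (r - 1) * (c - 1)
    q = 1.0 + ((n * np.sum(1.0 / rows) - 1) * (n * np.sum(1.0 / cols) - 1)
               / (6.0 * n * df))
    g_adj = g / q
    return GTestResult(G=g, q_williams=q, G_adj=g_adj, df=df,
                       p=float(sps.chi2.sf(g_adj, df)), mode="independence")


def g_test(table, mode: str = "gof", expected_props=None) -> GTestResult:
    if mode == "gof":
        return g_test_gof(table, expected_props)
    if mode in ("independence", "indep"):
        return g_test_independence(table)
    raise ValueError(f"unknown G-test mode {mode!r}")


@dataclass
class AlphaPolicy:
    """Bonferroni-style multi-way significance threshold (.05 / n_way)."""

    n_way: int
    base: float = 0.05

    def __post_init__(self):
        if self.n_way < 1:
            raise ValueError("n_way must be >= 1")

    @property
    def corrected(self) -> float:
        return self.base / self.n_way

    @property
    def corrected_rounded(self) -> float:
        return round(self.corrected, 3)


def alpha_threshold(n_way: int, base: float = 0.05) -> float:
    """Corrected alpha for an n-way comparison, rounded to 3 dp for
    reporting (.017 for 3, .025 for 2); use :class:`AlphaPolicy` for the
    unrounded internal value."""
    return AlphaPolicy(n_way=n_way, base=base).corrected_rounded


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and its chi-square p.

    All-identical data gives H = 0, p = 1 rather than an error.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups of >= 2 values")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


@dataclass
class DispatchResult:
    test: str                    # name of the test actually run
    statistic: float
    p: float
    normal: bool                 # whether the parametric branch was taken
    shapiro_p: list[float]
    note: str = ""


def dispatch_test(groups) -> DispatchResult:
    """Shapiro-Wilk-dispatched comparison of 2+ groups.

    Every group normal at alpha .05 -> equal-variance t-test (2 groups) or
    one-way ANOVA (3+); otherwise Wilcoxon rank-sum / Kruskal-Wallis.
    Groups too small for Shapiro-Wilk (n < 3) force the nonparametric branch.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    note = ""
    if any(len(g) < 3 for g in groups):
        normal = False
        shapiro_p: list[float] = []
        note = "group with n < 3: Shapiro-Wilk not applicable, nonparametric branch"
        logger.info(note)
    else:
        shapiro_p = []
        degenerate = False
        for g in groups:
            if np.all(g == g[0]):
                degenerate = True
                shapiro_p.append(0.0)
            else:
                shapiro_p.append(float(sps.shapiro(g).pvalue))
        normal = not degenerate and all(p > SHAPIRO_ALPHA for p in shapiro_p)
    if normal:
        if len(groups) == 2:
            stat, p = sps.ttest_ind(groups[0], groups[1], equal_var=True)
            test = "t-test (equal variances)"
        else:
            stat, p = sps.f_oneway(*groups)
            test = "ANOVA"
    else:
        if len(groups) == 2:
            stat, p = rank_sum_test(groups[0], groups[1])
            test = "Wilcoxon rank-sum"
        else:
            stat, p = kruskal_wallis(groups)
            test = "Kruskal-Wallis"
    return DispatchResult(test=test, statistic=float(stat), p=float(p),
                          normal=normal, shapiro_p=shapiro_p, note=note)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho (mid-rank ties) with the t-approximation p at n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors of >= 3 values")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("zero rank variance; Spearman rho undefined")
    rho, p = sps.spearmanr(x, y)
    if np.isnan(rho):
        raise ValueError("zero rank variance; Spearman rho undefined")
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# order-statistic median CI
# ---------------------------------------------------------------------------

@dataclass
class MedianCI:
    """Distribution-free CI for a population median from order statistics."""

    median: float
    lower: float
    upper: float
    j: int                        # 1-based order-statistic indices
    k: int
    coverage: float               # achieved coverage 1 - 2 P(Bin(n,1/2) <= j-1)
    attainable: bool              # nominal level attainable at this n


def median_ci(values, level: float = 0.95) -> MedianCI:
    """Conservative binomial order-statistic CI for the median.

    j is the largest index with P(Bin(n, 1/2) < j) <= (1 - level)/2 and
    k = n + 1 - j.  When even j = 1 overshoots the tail budget (tiny n),
    the widest interval (x(1), x(n)) is returned with ``attainable=False``.
    """
    vals = np.sort(np.asarray(values, dtype=float))
    n = len(vals)
    if n < 1:
        raise ValueError("need at least one value")
    med = float(np.median(vals))
    if n == 1:
        return MedianCI(median=med, lower=vals[0], upper=vals[0], j=1, k=1,
                        coverage=0.0, attainable=False)
    tail = (1.0 - level) / 2.0
    # largest j with P(Bin <= j-1) <= tail
    j = 0
    for cand in range(1, n // 2 + 1):
        if sps.binom.cdf(cand - 1, n, 0.5) <= tail:
            j = cand
        else:
            break
    attainable = j >= 1
    if not attainable:
        j = 1
    k = n + 1 - j
    coverage = float(1.0 - 2.0 * sps.binom.cdf(j - 1, n, 0.5))
    return MedianCI(median=med, lower=float(vals[j - 1]), upper=float(vals[k - 1]),
                    j=j, k=k, coverage=coverage, attainable=attainable)


def round_p(p: float) -> float:
    """Report-scale rounding of p values (3 dp); full precision is retained
    in the result objects."""
    return round(p, 3)
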