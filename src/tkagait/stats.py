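"""Group-comparison statistics.

Pooled-variance two-sample t-tests (with Bonferroni adjustment and Cohen's d
on the pooled SD), Pearson 2x2 chi-squared without continuity correction,
one-way ANOVA, and permutation-based one-dimensional statistical parametric
mapping (SPM) over time-normalized kinematic curves. The SPM null is the
distribution of the maximum absolute pointwise t statistic under group-label
permutations, which controls the family-wise error over the 101-point
domain with the same inference contract as random-field-theory SPM.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, sqrt

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "SPMCluster",
    "SPMResult",
    "t_test_pooled",
    "t_test_from_summary",
    "chi2_2x2",
    "anova_oneway",
    "bonferroni",
    "spm_ttest_1d",
]


class DegenerateVarianceError(ValueError):
    """Zero pooled variance with unequal means: the t statistic is undefined."""


@dataclass
class TestResult:
    statistic: float
    p_value: float
    df: float
    effect_size: float | None = None
    p_adjusted: float | None = None

    def adjust(self, family_size: int) -> "TestResult":
        """Return a copy with Bonferroni-adjusted p for a family of m tests."""
        return TestResult(
            statistic=self.statistic,
            p_value=self.p_value,
            df=self.df,
            effect_size=self.effect_size,
            p_adjusted=bonferroni(self.p_value, family_size),
        )


def bonferroni(p: float, family_size: int) -> float:
    """min(1, m*p); monotone in p, never exceeds 1."""
    if family_size < 1:
        raise ValueError("family size must be >= 1")
    return min(1.0, family_size * p)


# ---------------------------------------------------------------------------
# t-tests
# ---------------------------------------------------------------------------

def t_test_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> TestResult:
    """Pooled two-sample t-test from summary statistics (means, SDs, ns).

    Student's pooled-variance form, df = n1 + n2 - 2, two-sided p. Cohen's d
    uses the pooled SD. The pooled form is used throughout (not Welch): it is
    the form that reproduces the published clinical-score comparisons from
    their printed summary statistics.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    diff = mean1 - mean2
    if sp2 <= 0:
        if diff == 0:
            return TestResult(statistic=0.0, p_value=1.0, df=df, effect_size=0.0)
        raise DegenerateVarianceError(
            "zero pooled variance with unequal means; t is undefined"
        )
    sp = sqrt(sp2)
    t = diff / (sp * sqrt(1.0 / n1 + 1.0 / n2))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(statistic=float(t), p_value=float(p), df=df, effect_size=float(diff / sp))


def t_test_pooled(g1: np.ndarray, g2: np.ndarray) -> TestResult:
    """Pooled two-sample t-test on raw samples; see :func:`t_test_from_summary`."""
    x = np.asarray(g1, dtype=float)
    y = np.asarray(g2, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs n >= 2")
    return t_test_from_summary(
        float(x.mean()), float(x.std(ddof=1)), x.size,
        float(y.mean()), float(y.std(ddof=1)), y.size,
    )


# ---------------------------------------------------------------------------
# chi-squared
# ---------------------------------------------------------------------------

def chi2_2x2(table: np.ndarray) -> TestResult:
    """Pearson chi-squared for a 2x2 contingency table, df = 1, no Yates correction.

    statistic = N (ad - bc)^2 / (r1 r2 c1 c2). The uncorrected form is the
    documented choice: it reproduces the published cohort comparisons from
    their printed counts.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any() or not np.isfinite(t).all():
        raise ValueError("counts must be finite and non-negative")
    n = t.sum()
    if n < 1:
        raise ValueError("table total must be >= 1")
    r = t.sum(axis=1)
    c = t.sum(axis=0)
    denom = r[0] * r[1] * c[0] * c[1]
    if denom == 0:
        raise ValueError("chi-squared undefined: a row or column marginal is zero")
    a, b, cc, d = t.ravel()
    stat = n * (a * d - b * cc) ** 2 / denom
    p = sps.chi2.sf(stat, df=1)
    return TestResult(statistic=float(stat), p_value=float(p), df=1)


# ---------------------------------------------------------------------------
# one-way ANOVA
# ---------------------------------------------------------------------------

def anova_oneway(*groups: np.ndarray) -> TestResult:
    """Classic one-way ANOVA; df_between = g-1, df_within = N-g.

    With zero within-group variance: F = 0, p = 1 when all group means are
    equal, otherwise an explicit degenerate-variance error (matching the
    t-test convention). For two groups F equals the squared pooled t.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(g.size < 2 for g in gs):
        raise ValueError("need >= 2 groups with n >= 2 each")
    n_total = sum(g.size for g in gs)
    grand = np.concatenate(gs).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df_b = len(gs) - 1
    df_w = n_total - len(gs)
    if ss_within <= 0:
        if ss_between == 0:
            return TestResult(statistic=0.0, p_value=1.0, df=df_w)
        raise DegenerateVarianceError(
            "zero within-group variance with unequal means; F is undefined"
        )
    f = (ss_between / df_b) / (ss_within / df_w)
    p = sps.f.sf(f, df_b, df_w)
    return TestResult(statistic=float(f), p_value=float(p), df=df_w)


# ---------------------------------------------------------------------------
# permutation-based 1D SPM
# ---------------------------------------------------------------------------

@dataclass
class SPMCluster:
    start: int        # first node index of the suprathreshold run
    end: int          # last node index (inclusive)
    max_t: float
    p_value: float


@dataclass
class SPMResult:
    t_curve: np.ndarray
    threshold: float
    clusters: list[SPMCluster]
    alpha: float
    n_perm: int
    exact: bool       # True when all label permutations were enumerated

    @property
    def significant(self) -> bool:
        return len(self.clusters) > 0


def _t_curves(X: np.ndarray, sel: np.ndarray, n1: int, n2: int, ridge: float) -> np.ndarray:
    """Pointwise pooled t for each row of boolean selection matrix ``sel``.

    ``X`` is (n1+n2, T); sel (P, n1+n2) marks group-1 membership per
    permutation. Vectorized over permutations via sufficient statistics.
    """
    tot = X.sum(axis=0)
    tot2 = (X**2).sum(axis=0)
    s1 = sel.astype(float) @ X
    s1_2 = sel.astype(float) @ (X**2)
    s2 = tot - s1
    s2_2 = tot2 - s1_2
    m1 = s1 / n1
    m2 = s2 / n2
    ss1 = s1_2 - n1 * m1**2
    ss2 = s2_2 - n2 * m2**2
    sp2 = (ss1 + ss2) / (n1 + n2 - 2)
    sp2 = np.clip(sp2, 0.0, None) + ridge
    return (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))


def spm_ttest_1d(
    curves_g1: np.ndarray,
    curves_g2: np.ndarray,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int | None = None,
    ridge: float = 1e-10,
) -> SPMResult:
    """Permutation SPM{t} for two groups of 1-D curves (e.g. 101-point cycles).

    Pointwise pooled two-sample t trajectory; the null distribution of the
    maximum |t| over the domain is built from group-label permutations (all
    permutations when their number does not exceed ``n_perm``, otherwise a
    seeded Monte-Carlo subset that includes the observed labelling). The
    critical threshold is the (1-alpha) quantile of that null; suprathreshold
    clusters are maximal runs with |t| > threshold, each assigned the
    max-statistic permutation p of its peak |t|. ``ridge`` is a small
    variance floor guarding degenerate (zero-variance) nodes.
    """
    X1 = np.atleast_2d(np.asarray(curves_g1, dtype=float))
    X2 = np.atleast_2d(np.asarray(curves_g2, dtype=float))
    if X1.shape[1] != X2.shape[1]:
        raise ValueError("curves must share a common length")
    n1, n2 = X1.shape[0], X2.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >= 2 curves")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    X = np.vstack([X1, X2])
    n = n1 + n2

    n_all = comb(n, n1)
    if n_all <= n_perm:
        sel = np.zeros((n_all, n), dtype=bool)
        for i, idx in enumerate(combinations(range(n), n1)):
            sel[i, list(idx)] = True
        exact = True
    else:
        rng = np.random.default_rng(seed)
        sel = np.zeros((n_perm, n), dtype=bool)
        sel[0, :n1] = True  # observed labelling is always part of the null
        for i in range(1, n_perm):
            sel[i, rng.permutation(n)[:n1]] = True
        exact = False

    T = _t_curves(X, sel, n1, n2, ridge)
    obs_sel = np.zeros((1, n), dtype=bool)
    obs_sel[0, :n1] = True
    t_obs = _t_curves(X, obs_sel, n1, n2, ridge)[0]
    null_max = np.abs(T).max(axis=1)
    threshold = float(np.quantile(null_max, 1.0 - alpha, method="higher"))

    above = np.abs(t_obs) > threshold
    clusters: list[SPMCluster] = []
    i = 0
    while i < len(above):
        if above[i]:
            j = i
            while j + 1 < len(above) and above[j + 1]:
                j += 1
            peak = float(np.abs(t_obs[i : j + 1]).max())
            p = float(np.mean(null_max >= peak))
            clusters.append(SPMCluster(start=i, end=j, max_t=peak, p_value=p))
            i = j + 1
        else:
            i += 1
    return SPMResult(
        t_curve=t_obs,
        threshold=threshold,
        clusters=clusters,
        alpha=alpha,
        n_perm=len(sel),
        exact=exact,
    )
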