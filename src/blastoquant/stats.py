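"""Statistical layer: correlations and the classical group tests.

Thin, explicit wrappers around the standard machinery (scipy) with the
conventions used throughout the analyses fixed in one place: squared Pearson
correlation reported alongside r, coefficient of determination for the
multi-marker fit, classical equal-variance Student's t by default (Welch
behind a flag), one-way ANOVA with Bonferroni-adjusted pairwise t post-tests,
chi-square homogeneity without continuity correction, and a two-sided
Fisher's exact test defined as the sum of hypergeometric probabilities not
exceeding that of the observed table (computed here by direct pmf summation).
"""
from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln

__all__ = [
    "CorrelationResult",
    "GroupTestResult",
    "pearson_r2",
    "multiple_r2",
    "anova_bonferroni",
    "fisher_exact_2x2",
    "chi_square_homogeneity",
    "students_t",
]


@dataclass(frozen=True)
class CorrelationResult:
    r2: float
    n: int
    r: float = float("nan")
    slope: float | np.ndarray = float("nan")
    intercept: float = float("nan")

    def __post_init__(self) -> None:
        if not -1e-12 <= self.r2 <= 1 + 1e-12:
            raise ValueError("r2 outside [0, 1]")


@dataclass(frozen=True)
class GroupTestResult:
    statistic: float
    df: float | tuple
    p_value: float
    pairwise: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def _finite_1d(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite values")
    return a


def pearson_r2(x, y) -> CorrelationResult:
    """Squared sample Pearson correlation with the OLS line of y on x."""
    xa = _finite_1d(x, "x")
    ya = _finite_1d(y, "y")
    if len(xa) != len(ya):
        raise ValueError("x and y have different lengths")
    if len(xa) < 3:
        raise ValueError("need n >= 3")
    if np.std(xa) == 0 or np.std(ya) == 0:
        raise ValueError("zero variance in x or y")
    res = sps.linregress(xa, ya)
    return CorrelationResult(
        r2=float(res.rvalue**2),
        n=len(xa),
        r=float(res.rvalue),
        slope=float(res.slope),
        intercept=float(res.intercept),
    )


def multiple_r2(y, predictors) -> CorrelationResult:
    """Coefficient of determination of the OLS fit of y on the predictors.

    ``predictors`` is (n, p) (or a sequence of p vectors).  An intercept is
    always included.  Collinear predictors trigger a warning and drop to the
    minimum-norm least-squares solution; the R² is unaffected by which
    solution is reported.
    """
    ya = _finite_1d(y, "y")
    X = np.asarray(predictors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != len(ya):          # p vectors passed row-wise
        if X.shape[1] == len(ya):
            X = X.T
        else:
            raise ValueError("predictor shape does not match y")
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("need n > number of predictors + 1")
    design = np.column_stack([np.ones(n), X])
    rank = np.linalg.matrix_rank(design)
    if rank < p + 1:
        warnings.warn(
            "collinear predictors; using minimum-norm least squares",
            stacklevel=2,
        )
    beta, *_ = np.linalg.lstsq(design, ya, rcond=None)
    resid = ya - design @ beta
    tss = float(np.sum((ya - ya.mean()) ** 2))
    if tss == 0:
        raise ValueError("zero variance in y")
    r2 = 1.0 - float(np.sum(resid**2)) / tss
    r2 = min(max(r2, 0.0), 1.0)
    return CorrelationResult(
        r2=r2, n=n, r=math.sqrt(r2), slope=beta[1:], intercept=float(beta[0])
    )


def students_t(x, y, paired: bool = False, equal_var: bool = True) -> GroupTestResult:
    """Two-sided Student's t test (classical pooled-variance by default)."""
    xa = _finite_1d(x, "x")
    ya = _finite_1d(y, "y")
    if len(xa) < 2 or len(ya) < 2:
        raise ValueError("need n >= 2 per group")
    if paired:
        if len(xa) != len(ya):
            raise ValueError("paired test requires equal lengths")
        res = sps.ttest_rel(xa, ya)
        df = len(xa) - 1
    else:
        res = sps.ttest_ind(xa, ya, equal_var=equal_var)
        df = float(res.df)
    stat = float(res.statistic)
    p = float(res.pvalue)
    if not np.isfinite(stat):
        raise ValueError("zero pooled variance")
    return GroupTestResult(statistic=stat, df=df, p_value=p)


def anova_bonferroni(groups, labels=None) -> GroupTestResult:
    """One-way ANOVA plus all pairwise t tests with Bonferroni adjustment.

    The Bonferroni multiplier is the number of pairs; adjusted p-values are
    ``min(1, m * p_raw)``.  ``pairwise`` rows are
    (label_a, label_b, t, p_raw, p_adjusted).
    """
    arrays = [_finite_1d(g, f"group {i}") for i, g in enumerate(groups)]
    if len(arrays) < 2:
        raise ValueError("need >= 2 groups")
    if any(len(a) < 2 for a in arrays):
        raise ValueError("every group needs n >= 2")
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrays))]
    f_res = sps.f_oneway(*arrays)
    k = len(arrays)
    n = sum(len(a) for a in arrays)
    m = k * (k - 1) // 2
    pairwise = []
    for (i, a), (j, b) in itertools.combinations(enumerate(arrays), 2):
        t_res = sps.ttest_ind(a, b, equal_var=True)
        p_adj = min(1.0, m * float(t_res.pvalue))
        pairwise.append(
            (labels[i], labels[j], float(t_res.statistic),
             float(t_res.pvalue), p_adj)
        )
    stat = float(f_res.statistic)
    p = float(f_res.pvalue)
    if not np.isfinite(stat):  # all groups identical constants
        stat, p = 0.0, 1.0
        pairwise = [(a, b, 0.0, 1.0, 1.0) for a, b, *_ in pairwise]
    return GroupTestResult(
        statistic=stat, df=(k - 1, n - k), p_value=p, pairwise=pairwise
    )


def _log_comb(n: np.ndarray, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 count table.

    Conditions on both margins; the two-sided p-value is the total
    hypergeometric probability of all tables with the observed margins whose
    probability does not exceed that of the observed table (the conventional
    definition; competing two-sided rules exist).
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0):
        raise ValueError("counts must be nonnegative")
    if not np.all(np.equal(np.mod(t, 1), 0)):
        raise ValueError("counts must be integers")
    t = t.astype(np.int64)
    a = int(t[0, 0])
    r1 = int(t[0].sum())
    c1 = int(t[:, 0].sum())
    n = int(t.sum())
    if n == 0:
        return 1.0
    support = np.arange(max(0, c1 - (n - r1)), min(r1, c1) + 1)
    logp = (
        _log_comb(np.full_like(support, r1, dtype=float), support.astype(float))
        + _log_comb(float(n - r1), (c1 - support).astype(float))
        - _log_comb(float(n), float(c1))
    )
    probs = np.exp(logp)
    p_obs = probs[support == a][0]
    # relative tolerance well below the minimal gap between distinct
    # hypergeometric probabilities at these table sizes, but above the
    # accumulated rounding error of the log-gamma evaluation
    p = float(probs[probs <= p_obs * (1 + 1e-12)].sum())
    return min(p, 1.0)


def chi_square_homogeneity(observed) -> GroupTestResult:
    """Chi-square test of homogeneity on an r x c contingency table.

    Expected counts come from the margins; df = (r-1)(c-1); no continuity
    correction.  A warning is raised when any expected count is below 5.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.ndim != 2:
        raise ValueError("observed must be a 2-D table")
    if np.any(obs < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("zero row/column margin")
    chi2, p, dof, expected = sps.chi2_contingency(obs, correction=False)
    if np.any(expected < 5):
        warnings.warn(
            "expected count below 5; the chi-square approximation may be "
            "poor",
            stacklevel=2,
        )
    return GroupTestResult(statistic=float(chi2), df=dof, p_value=float(p))
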