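"""Classical statistics for the comparative analysis.

Pearson correlations (optionally through the origin for contrasts), ANCOVA
with a common slope for the within-species sampling-time effect, standardized
multiple regression, Welch/paired t-tests for lifestyle groups, and the
Fisher-z power analysis for the smallest reliably detectable correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "AncovaResult",
    "RegressionResult",
    "pearson",
    "correlation_through_origin",
    "ancova_common_slope",
    "multiple_regression_standardized",
    "detectable_correlation",
    "group_ttest",
]


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int


@dataclass
class AncovaResult:
    common_slope: float
    p: float
    group_intercepts: dict
    n: int
    n_groups: int


@dataclass
class RegressionResult:
    coefficients: pd.Series
    p_values: pd.Series
    n: int


def _pairwise_complete(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    ok = ~(np.isnan(x) | np.isnan(y))
    return x[ok], y[ok]


def pearson(x, y) -> CorrelationResult:
    """Pearson correlation with a two-sided t-test p-value, pairwise complete."""
    x, y = _pairwise_complete(x, y)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(r=float(r), p=float(p), n=n)


def correlation_through_origin(x, y) -> CorrelationResult:
    """Correlation for independent contrasts: regression forced through origin.

    Contrasts have arbitrary sign, so the association is summarized by the
    through-origin fit; r is the signed square root of its R^2.
    """
    x, y = _pairwise_complete(x, y)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    sxx = float(x @ x)
    if sxx == 0:
        raise ValueError("zero variance in x")
    beta = float(x @ y) / sxx
    resid = y - beta * x
    df = n - 1
    syy = float(y @ y)
    r2 = 1.0 - float(resid @ resid) / syy if syy > 0 else 0.0
    r = float(np.sign(beta) * np.sqrt(max(r2, 0.0)))
    se = np.sqrt(float(resid @ resid) / df / sxx)
    tstat = beta / se if se > 0 else np.inf
    p = float(2 * sps.t.sf(abs(tstat), df))
    return CorrelationResult(r=r, p=p, n=n)


def ancova_common_slope(groups: dict) -> AncovaResult:
    """Parallel-slopes ANCOVA: y ~ per-group intercept + common slope * x.

    ``groups`` maps group name -> (x, y) arrays.  Groups with fewer than two
    points are dropped with a warning.  Returns the common slope, its
    two-sided p-value and the fitted per-group intercepts.
    """
    usable = {}
    for name, (x, y) in groups.items():
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(x) < 2:
            warnings.warn(
                f"group {name!r} has < 2 points and was dropped", UserWarning,
                stacklevel=2,
            )
            continue
        usable[name] = (x, y)
    if len(usable) < 2:
        raise ValueError("ANCOVA needs at least two groups with >= 2 points")
    names = sorted(usable)
    x_all = np.concatenate([usable[g][0] for g in names])
    y_all = np.concatenate([usable[g][1] for g in names])
    labels = np.concatenate([[g] * len(usable[g][0]) for g in names])
    dummies = pd.get_dummies(pd.Series(labels), dtype=float)[names]
    X = np.column_stack([dummies.to_numpy(), x_all])
    fit = sm.OLS(y_all, X).fit()
    slope = float(fit.params[-1])
    p = float(fit.pvalues[-1])
    intercepts = {g: float(b) for g, b in zip(names, fit.params[:-1])}
    return AncovaResult(
        common_slope=slope, p=p, group_intercepts=intercepts,
        n=len(y_all), n_groups=len(names),
    )


def _find_collinear(X: pd.DataFrame) -> list[str]:
    cols = list(X.columns)
    bad = []
    for j, col in enumerate(cols):
        others = X.drop(columns=[col]).to_numpy()
        target = X[col].to_numpy()
        A = np.column_stack([np.ones(len(X)), others])
        resid = target - A @ np.linalg.lstsq(A, target, rcond=None)[0]
        denom = np.var(target) * len(target)
        if denom == 0 or float(resid @ resid) / denom < 1e-10:
            bad.append(col)
    return bad


def multiple_regression_standardized(X, y) -> RegressionResult:
    """OLS of z-scored y on z-scored predictors; standardized coefficients.

    Rows with any missing value are dropped (complete-case).  Raises on
    rank-deficient design, naming the collinear columns.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    if len(X) != len(y):
        raise ValueError("X and y must have the same length")
    ok = ~(X.isna().any(axis=1).to_numpy() | np.isnan(y))
    X, y = X.loc[ok], y[ok]
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 observations, got n={n}, p={p}")
    if (X.std(ddof=1) == 0).any():
        const = X.columns[(X.std(ddof=1) == 0)].tolist()
        raise ValueError(f"constant predictor column(s): {const}")
    Z = (X - X.mean()) / X.std(ddof=1)
    if np.linalg.matrix_rank(Z.to_numpy()) < p:
        raise ValueError(f"rank-deficient design; collinear columns: {_find_collinear(X)}")
    yz = (y - y.mean()) / y.std(ddof=1)
    design = sm.add_constant(Z.to_numpy())
    fit = sm.OLS(yz, design).fit()
    coef = pd.Series(fit.params[1:], index=X.columns)
    pvals = pd.Series(fit.pvalues[1:], index=X.columns)
    return RegressionResult(coefficients=coef, p_values=pvals, n=n)


def detectable_correlation(n: int, alpha: float = 0.05, power: float = 0.95) -> float:
    """Smallest true correlation detected with given power (Fisher-z).

    Solves atanh(r) = (z_{1-alpha/2} + z_{power}) / sqrt(n - 3) for a
    two-sided test at level ``alpha``.
    """
    if n < 4:
        raise ValueError("n must be >= 4")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    z = (sps.norm.ppf(1 - alpha / 2) + sps.norm.ppf(power)) / np.sqrt(n - 3)
    return float(np.tanh(z))


def group_ttest(values, labels, paired: bool = False) -> tuple[float, float]:
    """Two-group comparison: Welch's t-test, or a paired t-test.

    ``labels`` must define exactly two groups; for ``paired=True`` the groups
    must be equal-length and aligned in order.  Identical paired samples give
    (t=0, p=1) rather than NaN.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = sorted(set(labels.tolist()))
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {groups}")
    a = values[labels == groups[0]]
    b = values[labels == groups[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired test needs equal-length groups")
        if np.allclose(a, b):
            return 0.0, 1.0
        t, p = sps.ttest_rel(a, b)
    else:
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
            return 0.0, 1.0
        t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
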