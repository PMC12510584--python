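"""Shared statistical primitives: BH adjustment, Fisher tables, vectorized OLS.

These are the small building blocks every analysis module leans on. The
heavier lifting (mixed models, exact tests) is delegated to statsmodels and
scipy; what lives here is mostly glue with the conventions fixed once
(two-sided t p-values, BH step-up with cumulative minimum, percent rounding
to nearest integer).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "bh_adjust",
    "percent_significant",
    "fisher_2x2",
    "odds_ratio_from_counts",
    "ols_fit",
    "OlsResult",
]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN entries are ignored for the adjustment and returned as NaN.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def percent_significant(n_significant: int, n_tested: int, decimals: int = 0) -> float:
    """Percentage of tested features that were significant.

    Rounds half away from zero to ``decimals`` places (integer percent by
    default), matching how contingency summaries are reported.
    """
    if n_tested <= 0:
        raise ValueError("n_tested must be positive")
    pct = 100.0 * n_significant / n_tested
    scale = 10.0**decimals
    return float(np.floor(pct * scale + 0.5) / scale)


@dataclass
class Fisher2x2:
    table: np.ndarray
    odds_ratio: float
    p_value: float
    ci_low: float
    ci_high: float


def odds_ratio_from_counts(a: float, b: float, c: float, d: float) -> float:
    """Sample odds ratio (a/b)/(c/d); inf/0 propagated for zero cells."""
    a, b, c, d = np.float64(a), np.float64(b), np.float64(c), np.float64(d)
    with np.errstate(divide="ignore", invalid="ignore"):
        return float((a / b) / (c / d))


def fisher_2x2(a, b, c, d, alternative: str = "two-sided") -> Fisher2x2:
    """Fisher's exact test on [[a, b], [c, d]] with a Wald CI on the log OR.

    The reported odds ratio is the sample odds ratio (a*d)/(b*c); when a cell
    is zero the CI degenerates to (0, inf).
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    _, p = sps.fisher_exact(table, alternative=alternative)
    orr = odds_ratio_from_counts(a, b, c, d)
    if np.all(table > 0):
        se = float(np.sqrt((1 / table).sum()))
        lo = float(np.exp(np.log(orr) - 1.959963985 * se))
        hi = float(np.exp(np.log(orr) + 1.959963985 * se))
    else:
        lo, hi = 0.0, np.inf
    return Fisher2x2(table=table, odds_ratio=orr, p_value=float(p), ci_low=lo, ci_high=hi)


@dataclass
class OlsResult:
    """Per-feature OLS summaries for a shared design matrix.

    coef, se, t, p are (n_features, n_params) arrays; df is the residual
    degrees of freedom shared by all features.
    """

    coef: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    df: int


def ols_fit(y: np.ndarray, design: np.ndarray) -> OlsResult:
    """Fit ``y[f, :] ~ design`` for every feature f in one shot.

    y is (n_features, n_samples); design is (n_samples, n_params) and must
    have full column rank.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(design, dtype=float)
    n, k = X.shape
    if y.shape[1] != n:
        raise ValueError("y and design sample dimensions differ")
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("design matrix is rank-deficient (collinear columns)")
    xtx_inv = np.linalg.inv(X.T @ X)
    coef = y @ X @ xtx_inv  # (F, k)
    resid = y - coef @ X.T
    df = n - k
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    sigma2 = (resid**2).sum(axis=1) / df
    se = np.sqrt(sigma2[:, None] * np.diag(xtx_inv)[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = coef / se
    p = 2.0 * sps.t.sf(np.abs(t), df)
    return OlsResult(coef=coef, se=se, t=t, p=p, df=df)
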