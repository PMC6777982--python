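"""Statistical primitives of the cohort analysis.

Thin, contract-enforcing wrappers around scipy/statsmodels: pooled-variance
two-sample and paired t tests, Pearson/Spearman correlations, partial
correlation via covariate residualization, OLS variance explained, the
logarithmic lag remapping and Benjamini-Hochberg FDR control. Degenerate
inputs (zero variance, rank deficiency) raise typed errors instead of
propagating NaNs.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .exceptions import CollinearityError, DegenerateSignalError

__all__ = [
    "two_sample_t",
    "pearson",
    "spearman",
    "log_remap",
    "glm_r2",
    "partial_pearson",
    "fdr_bh",
]


def _asarray(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 1:
        raise ValueError(f"{name} must be 1-D")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite values")
    return a


def two_sample_t(x, y, paired: bool = False) -> tuple[float, float]:
    """Two-sided t test of equal means; pooled-variance Student if unpaired.

    Returns ``(t, p)``. Paired requires equal lengths and tests the mean of
    the differences; a zero-variance situation (both samples constant, or
    constant paired differences) raises :class:`DegenerateSignalError`.
    """
    x = _asarray(x, "x")
    y = _asarray(y, "y")
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 observations per sample")
    if paired:
        if x.size != y.size:
            raise ValueError("paired test requires equal lengths")
        d = x - y
        if np.ptp(d) == 0:
            raise DegenerateSignalError("paired differences have zero variance")
        res = sps.ttest_rel(x, y)
    else:
        if np.ptp(x) == 0 and np.ptp(y) == 0:
            if x.mean() == y.mean():
                return 0.0, 1.0
            raise DegenerateSignalError("both samples have zero variance")
        res = sps.ttest_ind(x, y, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def pearson(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with two-sided t-distributed p."""
    x = _asarray(x, "x")
    y = _asarray(y, "y")
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateSignalError("constant input has no correlation")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks on ties), two-sided p."""
    x = _asarray(x, "x")
    y = _asarray(y, "y")
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateSignalError("constant input has no correlation")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def log_remap(lags, floor: float | None = None) -> np.ndarray:
    """Natural-log remapping of lags; sub-second lags become negative.

    Zero lags are replaced by ``floor`` before the transform (pass e.g.
    TR/100); with ``floor=None`` zeros raise. Negative lags are invalid —
    remap magnitudes.
    """
    lags = _asarray(lags, "lags")
    if np.any(lags < 0):
        raise ValueError("lags must be non-negative; remap magnitudes")
    if np.any(lags == 0):
        if floor is None or floor <= 0:
            raise ValueError("zero lags present: provide a positive floor")
        lags = np.where(lags == 0, floor, lags)
    return np.log(lags)


def _design(predictors) -> np.ndarray:
    X = np.asarray(predictors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not np.all(np.isfinite(X)):
        raise ValueError("predictors contain non-finite values")
    return np.column_stack([np.ones(X.shape[0]), X])


def glm_r2(response, predictors) -> float:
    """Fraction of variance explained by an OLS fit with intercept.

    ``predictors`` is a vector or a column-stacked matrix. Rank-deficient
    designs raise :class:`CollinearityError`.
    """
    import statsmodels.api as sm

    y = _asarray(response, "response")
    X = _design(predictors)
    if y.size != X.shape[0]:
        raise ValueError("response and predictors must have equal length")
    if y.size < X.shape[1] + 1:
        raise ValueError("need at least predictors + 2 rows")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CollinearityError("design matrix is rank deficient")
    return float(sm.OLS(y, X).fit().rsquared)


def partial_pearson(x, y, covariates) -> tuple[float, float]:
    """Pearson correlation of x and y after removing covariate effects.

    Both variables are residualized on the covariates (with intercept) by
    OLS; the p-value uses ``df = n - 2 - n_covariates``.
    """
    x = _asarray(x, "x")
    y = _asarray(y, "y")
    Z = _design(covariates)
    k = Z.shape[1] - 1
    n = x.size
    if y.size != n or Z.shape[0] != n:
        raise ValueError("inputs must have equal length")
    if n < k + 3:
        raise ValueError("need n >= covariates + 3")
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise CollinearityError("covariate matrix is rank deficient")
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise DegenerateSignalError("a variable is fully explained by the covariates")
    r = float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
    df = n - 2 - k
    if df <= 0:
        raise ValueError("not enough degrees of freedom")
    r_ = min(max(r, -1.0), 1.0)
    if abs(r_) == 1.0:
        return r_, 0.0
    t = r_ * np.sqrt(df / (1.0 - r_**2))
    p = 2.0 * sps.t.sf(abs(t), df)
    return r_, float(p)


def fdr_bh(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up control of the false discovery rate.

    Returns ``(adjusted, reject)``; adjusted values are monotone after
    sorting and capped at 1, rejection is at level ``q``.
    """
    p = _asarray(p_values, "p_values")
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return adjusted, reject
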