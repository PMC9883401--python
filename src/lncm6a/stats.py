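"""Correlation and multiple-testing primitives shared across the pipeline."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


def pearson_r(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with its two-sided p-value.

    The p-value comes from t = r * sqrt((n-2) / (1-r^2)) referred to a
    t distribution with n-2 degrees of freedom.  Degenerate inputs raise
    instead of returning NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = np.sqrt((dx * dx).sum())
    sy = np.sqrt((dy * dy).sum())
    if sx == 0 or sy == 0:
        raise ValueError("zero-variance input vector")
    r = float((dx * dy).sum() / (sx * sy))
    r = max(-1.0, min(1.0, r))
    p = _pearson_p(np.array([r]), n)[0]
    return r, float(p)


def _pearson_p(r: np.ndarray, n: int) -> np.ndarray:
    """Vectorised two-sided p for Pearson r at sample size n."""
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = np.abs(r) * np.sqrt((n - 2) / np.maximum(1 - r * r, 1e-300))
    return 2.0 * sps.t.sf(t, df=n - 2)


def pearson_matrix(
    a: np.ndarray, b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """All pairwise Pearson r and p between rows of ``a`` and rows of ``b``.

    Both matrices share the sample axis (columns).  Rows with zero variance
    yield r = 0 and p = 1 (they can never pass a screen threshold) rather
    than NaN, so callers may mask them out explicitly.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape[1] != b.shape[1]:
        raise ValueError("sample dimension mismatch")
    n = a.shape[1]
    az = a - a.mean(axis=1, keepdims=True)
    bz = b - b.mean(axis=1, keepdims=True)
    sa = np.sqrt((az * az).sum(axis=1))
    sb = np.sqrt((bz * bz).sum(axis=1))
    denom = np.outer(sa, sb)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (az @ bz.T) / denom
    r = np.where(denom == 0, 0.0, r)
    r = np.clip(r, -1.0, 1.0)
    p = _pearson_p(r, n)
    p = np.where(denom == 0, 1.0, p)
    return r, p


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def hypergeom_upper_tail(k: int, M: int, K: int, n: int) -> float:
    """P(X >= k) for overlap X of an n-draw from M with K marked items."""
    if not (0 <= K <= M and 0 <= n <= M):
        raise ValueError("set sizes must satisfy 0 <= K, n <= M")
    if k < 0:
        k = 0
    return float(sps.hypergeom.sf(k - 1, M, K, n))
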