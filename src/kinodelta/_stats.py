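"""Shared statistical primitives.

Thin wrappers over scipy/statsmodels plus a vectorized pairwise-complete
Pearson correlation used by the covariance stage, where the number of
molecule pairs makes per-pair calls prohibitive.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


def pearson_r_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and two-sided p (t transform, n−2 df).

    Returns (0.0, 1.0) when either vector has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0 or y.std() == 0:
        return 0.0, 1.0
    r = float(stats.pearsonr(x, y).statistic)
    n = len(x)
    p = pearson_p_from_r(r, n)
    return r, p


def pearson_p_from_r(r, n):
    """Two-sided p for Pearson r via the t transform with n−2 df."""
    r = np.clip(r, -1.0, 1.0)
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(r) * np.sqrt((n - 2.0) / np.maximum(1.0 - r * r, 1e-300))
    p = 2.0 * stats.t.sf(t, n - 2.0)
    return np.minimum(p, 1.0)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pairwise_complete_pearson(X: np.ndarray):
    """All-pairs Pearson correlation of the rows of X with NaN handling.

    For every row pair the correlation is computed over the columns where
    both rows are observed ("pairwise complete"). Implemented with dense
    matrix products so the cost is O(m² s) in BLAS.

    Returns
    -------
    r : (m, m) array, NaN where fewer than 3 shared columns or a constant
        vector makes the correlation undefined.
    n : (m, m) integer array of shared observation counts.
    """
    X = np.asarray(X, dtype=float)
    M = (~np.isnan(X)).astype(float)
    X0 = np.where(np.isnan(X), 0.0, X)

    n = M @ M.T
    sx = X0 @ M.T           # sum of x_i over columns shared with j
    sxy = X0 @ X0.T
    sxx = (X0 * X0) @ M.T

    num = n * sxy - sx * sx.T
    den_i = n * sxx - sx * sx
    den_j = den_i.T
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / np.sqrt(den_i * den_j)
    bad = (n < 3) | (den_i <= 0) | (den_j <= 0)
    r[bad] = np.nan
    r = np.clip(r, -1.0, 1.0)
    return r, n.astype(np.int64)
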