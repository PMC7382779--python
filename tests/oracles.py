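"""Independent brute-force oracles used to cross-check the statistics.

These deliberately avoid the code paths of the implementation: Pearson r
from the raw covariance formula; its p-value through the regularized
incomplete beta function; the hypergeometric tail by exact rational
enumeration of the mass function; BH by a literal hand step-up.
"""

from fractions import Fraction
from math import comb, sqrt

import numpy as np
from scipy.special import betainc


def pearson_r_direct(x, y) -> float:
    """r = Σ(dx·dy) / sqrt(Σdx² · Σdy²)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    dx = x - x.mean()
    dy = y - y.mean()
    return float((dx * dy).sum() / sqrt((dx * dx).sum() * (dy * dy).sum()))


def pearson_p_direct(r: float, n: int) -> float:
    """Two-sided p via the t transform and the incomplete beta identity:
    P(|T| >= t) = I_{df/(df+t^2)}(df/2, 1/2)."""
    df = n - 2
    if abs(r) >= 1.0:
        return 0.0
    t2 = r * r * df / (1.0 - r * r)
    return float(betainc(df / 2.0, 0.5, df / (df + t2)))


def hypergeom_tail_enum(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by exact enumeration with rational arithmetic."""
    total = comb(N, n)
    acc = Fraction(0)
    for i in range(k, min(K, n) + 1):
        acc += Fraction(comb(K, i) * comb(N - K, n - i), total)
    return float(acc)


def bh_stepup_by_hand(pvalues):
    """Literal BH: sort, p·m/rank, enforce monotonicity from the largest."""
    p = list(map(float, pvalues))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adjusted[i] = running
    return adjusted
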