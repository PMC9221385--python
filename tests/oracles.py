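"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's code paths (and the library calls
behind them): Pearson r/p from the definitional formula, hypergeometric
tails and Fisher two-sided p by exact enumeration in rational arithmetic.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

from scipy.stats import t as _tdist


def pearson_brute(x, y) -> tuple[float, float]:
    """Pearson r from the definition plus the two-sided p of its
    t-transform, t = r * sqrt((n-2)/(1-r^2)) with n-2 df."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = (sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y)) ** 0.5
    r = num / den
    if abs(r) >= 1.0:
        return max(-1.0, min(1.0, r)), 0.0
    t = r * ((n - 2) / (1 - r * r)) ** 0.5
    return r, 2 * _tdist.sf(abs(t), n - 2)


def hypergeom_upper_tail_exact(k: int, M: int, K: int, n: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeometric(M, K, n), exact rational."""
    total = comb(M, n)
    lo = max(k, max(0, n - (M - K)))
    hi = min(K, n)
    num = sum(comb(K, i) * comb(M - K, n - i) for i in range(lo, hi + 1))
    return Fraction(num, total)


def fisher_two_sided_exact(table) -> Fraction:
    """Two-sided Fisher p: sum of point probabilities <= the observed
    table's, enumerated over all tables with the observed margins in exact
    rational arithmetic."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    N = r1 + r2
    total = comb(N, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = {x: Fraction(comb(r1, x) * comb(r2, c1 - x), total) for x in range(lo, hi + 1)}
    p_obs = probs[a]
    return sum((p for p in probs.values() if p <= p_obs), Fraction(0))
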