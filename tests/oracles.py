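"""Independent brute-force oracles used by the test suite.

These are deliberately naive (enumeration, closed forms) and share no
code with the implementation they check.
"""

from itertools import combinations
from math import comb, sqrt


def fisher_two_sided_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full hypergeometric enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = a + b + c + d

    def pmf(k: int) -> float:
        return comb(r1, k) * comb(r2, c1 - k) / comb(n, c1)

    p_obs = pmf(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs * (1 + 1e-12))


def mann_whitney_exact_p(x, y) -> float:
    """Two-sided exact Mann-Whitney p by enumerating all label assignments."""
    pooled = sorted(x) + sorted(y)
    n, m = len(x), len(y)
    ranks = {}
    s = sorted(pooled)

    def u_of(idx):
        xs = [pooled[i] for i in idx]
        u = 0
        for xi in xs:
            for yj in (pooled[i] for i in range(n + m) if i not in idx):
                u += (xi > yj) + 0.5 * (xi == yj)
        return u

    obs = u_of(tuple(range(n)))
    us = [u_of(idx) for idx in combinations(range(n + m), n)]
    mid = n * m / 2
    dev = abs(obs - mid)
    return sum(1 for u in us if abs(u - mid) >= dev - 1e-12) / len(us)


def pearson_r(x, y) -> float:
    """Closed-form Pearson correlation."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    den = sqrt(sum((xi - mx) ** 2 for xi in x) * sum((yi - my) ** 2 for yi in y))
    return num / den
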