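"""Independent brute-force oracles used by unit and acceptance tests.

Each routine recomputes a statistic from its definition (enumeration, pmf
summation, closed form) without touching the package's implementation path.
"""

from itertools import combinations
from math import comb, exp, log, sqrt

import numpy as np


def mannwhitney_exact_p(x, y) -> float:
    """Two-sided Mann-Whitney P by exhaustive enumeration of all
    C(n1+n2, n1) group assignments of the pooled (tie-free) values."""
    pooled = list(x) + list(y)
    n1 = len(x)
    u_obs = sum(1 for xi in x for yj in y if xi > yj) \
        + 0.5 * sum(1 for xi in x for yj in y if xi == yj)
    u_all = []
    idx = range(len(pooled))
    for grp in combinations(idx, n1):
        gx = [pooled[i] for i in grp]
        gy = [pooled[i] for i in idx if i not in grp]
        u = sum(1 for xi in gx for yj in gy if xi > yj) \
            + 0.5 * sum(1 for xi in gx for yj in gy if xi == yj)
        u_all.append(u)
    u_all = np.array(u_all)
    eps = 1e-12
    p_ge = np.mean(u_all >= u_obs - eps)
    p_le = np.mean(u_all <= u_obs + eps)
    return float(min(1.0, 2.0 * min(p_ge, p_le)))


def binom_upper_tail_p(n: int, k: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p) by direct log-pmf summation."""
    if k <= 0:
        return 1.0
    total = 0.0
    lp, lq = log(p), log(1 - p)
    for j in range(k, n + 1):
        total += exp(log(comb(n, j)) + j * lp + (n - j) * lq)
    return min(total, 1.0)


def spearman_rho(x, y) -> float:
    """Spearman correlation from its definition: Pearson correlation of
    average ranks."""

    def avg_ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / sqrt((rx**2).sum() * (ry**2).sum()))


def odds_ratio_woolf(a, b, c, d):
    """Closed-form OR and Woolf 95% CI."""
    orr = a * d / (b * c)
    se = sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return orr, (orr * exp(-1.959963985 * se), orr * exp(1.959963985 * se))
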