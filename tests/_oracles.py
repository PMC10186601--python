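"""Independent brute-force oracles used to check the package's statistics.

Everything here is coded directly from first principles (factorial
enumeration, explicit variance-component sums, pairwise-difference counting)
and deliberately shares no code path with the implementation under test.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np

# scipy applies a (1 + 1e-7) slack when collecting outcomes "at least as
# extreme"; the oracles mirror that convention so comparisons are exact.
_REL = 1 + 1e-7


def fisher_two_sided_enum(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x: int) -> float:
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
            if 0 <= c1 - x <= r2
            else 0.0
        )

    p_obs = prob(a)
    return min(1.0, sum(prob(x) for x in range(min(r1, c1) + 1) if prob(x) <= p_obs * _REL))


def binom_two_sided_enum(x: int, n: int, p: float) -> float:
    """Two-sided binomial p (minlike ordering) by summing the full pmf."""
    pmf = [math.comb(n, k) * p**k * (1 - p) ** (n - k) for k in range(n + 1)]
    return min(1.0, sum(q for q in pmf if q <= pmf[x] * _REL))


def bh_stepup(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values via the direct min-over-tail formula."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[idx] * m / rank)
        adjusted[idx] = running
    return adjusted


def wc_fst_components(n1: int, p1: float, h1: float, n2: int, p2: float, h2: float):
    """Weir & Cockerham (1984) a, b, c for two populations, coded literally.

    n_i are individual counts, p_i alt-allele frequencies, h_i observed
    heterozygote proportions.  Written as explicit sums (no vectorization) to
    stay independent of the implementation.
    """
    r = 2
    ns = [n1, n2]
    ps = [p1, p2]
    hs = [h1, h2]
    nbar = sum(ns) / r
    nc = (r * nbar - sum(x * x for x in ns) / (r * nbar)) / (r - 1)
    pbar = sum(n * p for n, p in zip(ns, ps)) / (r * nbar)
    s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
    hbar = sum(n * h for n, h in zip(ns, hs)) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    return a, b, c


def tajimas_d_direct(derived_counts, n: int) -> float:
    """Tajima's D from an explicit haplotype matrix and rational constants.

    pi is counted as the literal average pairwise Hamming distance over all
    C(n,2) haplotype pairs; the normalizing constants are assembled with
    exact Fraction arithmetic before one final float conversion.
    """
    counts = [int(c) for c in derived_counts if 0 < c < n]
    S = len(counts)
    if S == 0:
        raise ValueError("D undefined for monomorphic window")
    # explicit 0/1 haplotype matrix: site j has counts[j] carriers
    matrix = np.zeros((n, S), dtype=int)
    for j, c in enumerate(counts):
        matrix[:c, j] = 1
    total_diff = 0
    for i in range(n):
        for j in range(i + 1, n):
            total_diff += int(np.sum(matrix[i] != matrix[j]))
    pi = total_diff / math.comb(n, 2)

    a1 = sum(Fraction(1, i) for i in range(1, n))
    a2 = sum(Fraction(1, i * i) for i in range(1, n))
    b1 = Fraction(n + 1, 3 * (n - 1))
    b2 = Fraction(2 * (n * n + n + 3), 9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - Fraction(n + 2, n) / a1 + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    var = float(e1) * S + float(e2) * S * (S - 1)
    return (pi - S / float(a1)) / math.sqrt(var)


def hudson_fst_ratio(p1: np.ndarray, p2: np.ndarray) -> float:
    """Hudson-style FST as a ratio of averages over sites (true frequencies)."""
    num = np.mean((p1 - p2) ** 2)
    den = np.mean(p1 * (1 - p2) + p2 * (1 - p1))
    return float(num / den)
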