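"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's code paths: exhaustive
enumeration for splice candidates and Fisher/Wilcoxon p-values, and
direct threshold scans for FDR.
"""

from __future__ import annotations

import itertools
import math


def splice_pairs_bruteforce(peptide: str, parent: str, min_len: int = 2,
                            il_equivalent: bool = False) -> set[tuple]:
    """All fragment-pair explanations by exhaustive scan over all
    (start1, end1, start2, end2)."""
    def eq(a: str, b: str) -> bool:
        if il_equivalent:
            a = a.replace("L", "I")
            b = b.replace("L", "I")
        return a == b

    m, L = len(peptide), len(parent)
    out = set()
    for s1, e1 in itertools.combinations(range(L + 1), 2):
        l1 = e1 - s1
        if l1 < min_len or m - l1 < min_len:
            continue
        if not eq(parent[s1:e1], peptide[:l1]):
            continue
        l2 = m - l1
        for s2 in range(L - l2 + 1):
            e2 = s2 + l2
            if not eq(parent[s2:e2], peptide[l1:]):
                continue
            if e1 < s2:
                order = "forward"
            elif e2 <= s1:
                order = "reverse"
            else:
                continue
            out.add((s1, e1, s2, e2, order))
    return out


def fisher_exact_bruteforce(table) -> float:
    """Two-sided Fisher exact p by exhaustive hypergeometric summation."""
    (a, b), (c, d) = table
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def log_comb(nn: int, kk: int) -> float:
        return math.lgamma(nn + 1) - math.lgamma(kk + 1) - math.lgamma(nn - kk + 1)

    def pmf(k: int) -> float:
        return math.exp(log_comb(row1, k) + log_comb(row2, col1 - k) - log_comb(n, col1))

    p_obs = pmf(a)
    lo, hi = max(0, col1 - row2), min(row1, col1)
    return min(1.0, sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs * (1 + 1e-10)))


def wilcoxon_signed_rank_bruteforce(x, y) -> tuple[float, float]:
    """Exact two-sided signed-rank test by enumerating all sign vectors.

    Assumes no zero differences and no tied absolute differences.
    Returns (W+, p).
    """
    d = [b - a for a, b in zip(x, y)]
    assert all(v != 0 for v in d)
    ad = sorted((abs(v), i) for i, v in enumerate(d))
    ranks = [0.0] * len(d)
    for r, (_, i) in enumerate(ad, start=1):
        ranks[i] = float(r)
    w_plus = sum(r for r, v in zip(ranks, d) if v > 0)
    n = len(d)
    dist = []
    for signs in itertools.product((0, 1), repeat=n):
        dist.append(sum(r for r, s in zip(ranks, signs) if s))
    total = len(dist)
    le = sum(1 for w in dist if w <= w_plus) / total
    ge = sum(1 for w in dist if w >= w_plus) / total
    return w_plus, min(1.0, 2 * min(le, ge))


def fdr_threshold_bruteforce(scores, is_decoy, level: float):
    """Lowest candidate threshold with decoy/target ratio <= level."""
    best = None
    for t in sorted(set(scores)):
        targets = sum(1 for s, d in zip(scores, is_decoy) if s >= t and not d)
        decoys = sum(1 for s, d in zip(scores, is_decoy) if s >= t and d)
        if targets and decoys / targets <= level:
            if best is None or t < best:
                best = t
    return best
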