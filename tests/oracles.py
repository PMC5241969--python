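"""Independent exact oracles used to cross-check the statistics.

These deliberately avoid the code paths (and, where possible, the
algorithms) of the package: exact Fraction arithmetic, full enumeration
of outcomes, and brute-force per-base-pair counting.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction
from typing import List, Sequence, Tuple


def odds_ratio_oracle(
    n_mut_region: int, n_mut_total: int, n_res_region: int, n_res_total: int
) -> Tuple[float, float, float]:
    """(OR, SE_ln, Z) from exact proportion arithmetic."""
    p1 = Fraction(n_mut_region, n_mut_total)
    p2 = Fraction(n_res_region, n_res_total)
    odds = (p1 / (1 - p1)) / (p2 / (1 - p2))
    se = math.sqrt(
        Fraction(1, n_mut_region)
        + Fraction(1, n_mut_total - n_mut_region)
        + Fraction(1, n_res_region)
        + Fraction(1, n_res_total - n_res_region)
    )
    z = math.log(odds) / se
    return float(odds), se, z


def enrichment_oracle(
    n_region: int, n_total: int, l_region: int, l_total: int
) -> Tuple[float, float, float]:
    """(enrichment, SE_ln, Z) from exact arithmetic."""
    est = Fraction(n_region * l_total, n_total * l_region)
    se = math.sqrt(
        Fraction(1, n_region)
        - Fraction(1, n_total)
        + Fraction(1, l_region)
        - Fraction(1, l_total)
    )
    z = math.log(est) / se
    return float(est), se, z


def binom_upper_tail_oracle(k: int, n: int, p0: Fraction) -> float:
    """P(X >= k) by exact summation of binomial terms."""
    p0 = Fraction(p0)
    total = Fraction(0)
    for i in range(k, n + 1):
        total += math.comb(n, i) * p0**i * (1 - p0) ** (n - i)
    return float(total)


def _u_by_counting(x: Sequence[float], y: Sequence[float]) -> float:
    """U statistic via win counting (independent of rank arithmetic)."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def mann_whitney_exact_oracle(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """(U, two-sided p) by enumerating all group labelings."""
    pooled = list(x) + list(y)
    n1 = len(x)
    mu = n1 * len(y) / 2.0
    u_obs = _u_by_counting(x, y)
    dev = abs(u_obs - mu)
    hits = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        in_first = set(comb)
        gx = [pooled[i] for i in in_first]
        gy = [pooled[i] for i in range(len(pooled)) if i not in in_first]
        if abs(_u_by_counting(gx, gy) - mu) >= dev - 1e-9:
            hits += 1
        total += 1
    return u_obs, hits / total


def brute_force_union_length(intervals: Sequence[Tuple[int, int]], limit: int) -> int:
    """Per-bp union size of [start, end) intervals within [0, limit)."""
    covered = [False] * limit
    for s, e in intervals:
        for b in range(max(s, 0), min(e, limit)):
            covered[b] = True
    return sum(covered)


def brute_force_scan(
    seq: str, matrix, background, threshold: float, pseudocount: float = 0.01
) -> List[Tuple[int, str, float]]:
    """All (start, strand, score) PWM hits by direct per-window scoring."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    bases = "ACGT"
    mat = [list(row) for row in matrix]
    if any(v == 0 for row in mat for v in row):
        mat = [[v + pseudocount for v in row] for row in mat]
        mat = [[v / sum(row) for v in row] for row in mat]
    w = len(mat)
    out = []
    seq = seq.upper()
    for i in range(len(seq) - w + 1):
        window = seq[i : i + w]
        if any(b not in bases for b in window):
            continue
        fwd = sum(
            math.log(mat[k][bases.index(b)] / background[bases.index(b)])
            for k, b in enumerate(window)
        )
        rc = "".join(comp[b] for b in reversed(window))
        rev = sum(
            math.log(mat[k][bases.index(b)] / background[bases.index(b)])
            for k, b in enumerate(rc)
        )
        if fwd >= threshold:
            out.append((i, "+", fwd))
        if rev >= threshold:
            out.append((i, "-", rev))
    return out
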