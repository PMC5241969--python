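"""Shared statistical primitives.

The tests compare each of these against independent exact oracles
(Fraction arithmetic / full enumeration), so the implementations here
stay deliberately close to the printed formulas.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .core_model.types import EnrichmentResult

__all__ = [
    "two_sided_normal_p",
    "log_ratio_result",
    "binomial_upper_tail",
    "MannWhitneyResult",
    "mann_whitney",
]


def two_sided_normal_p(z: float) -> float:
    p = 2.0 * sps.norm.sf(abs(z))
    # clamp into (0, 1]: underflow to exactly 0 would violate the contract
    return min(max(p, 5e-324), 1.0)


def log_ratio_result(estimate: float, se_log: float) -> EnrichmentResult:
    """Z-test on the natural log of a ratio estimate."""
    if estimate <= 0:
        raise ValueError(f"estimate must be positive, got {estimate}")
    if not (se_log > 0) or not math.isfinite(se_log):
        raise ValueError(f"se_log must be positive and finite, got {se_log}")
    z = math.log(estimate) / se_log
    return EnrichmentResult(estimate=estimate, se_log=se_log, z=z, p=two_sided_normal_p(z))


def binomial_upper_tail(k: int, n: int, p0: float) -> float:
    """Upper-tail cumulative binomial P(X >= k) for X ~ Bin(n, p0)."""
    if not (0 <= k <= n):
        raise ValueError(f"k={k} outside [0, {n}]")
    if not (0.0 <= p0 <= 1.0):
        raise ValueError(f"p0={p0} outside [0, 1]")
    if k == 0:
        return 1.0
    return float(sps.binom.sf(k - 1, n, p0))


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float                       # U statistic of the first group
    p: float                       # two-sided
    method: str                    # "asymptotic" or "exact"
    mean_x: float
    mean_y: float
    median_x: float
    median_y: float


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Rank-based U of group x (ties share ranks)."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = ranks[: len(x)].sum()
    n1 = len(x)
    return float(r1 - n1 * (n1 + 1) / 2.0)


def mann_whitney(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "auto",
    exact_limit: int = 12,
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    ``asymptotic`` uses the normal approximation with tie correction (no
    continuity correction, so identical groups give p = 1 exactly);
    ``exact`` enumerates every assignment of the pooled values to the two
    group sizes, which also handles ties correctly.  ``auto`` picks exact
    when n1 + n2 <= ``exact_limit``.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(x), len(y)
    n = n1 + n2
    u_obs = _u_statistic(x, y)
    mu = n1 * n2 / 2.0

    if method == "auto":
        method = "exact" if n <= exact_limit else "asymptotic"

    if method == "exact":
        pooled = np.concatenate([x, y])
        dev = abs(u_obs - mu)
        hits = 0
        total = 0
        idx = np.arange(n)
        for comb in itertools.combinations(idx, n1):
            mask = np.zeros(n, dtype=bool)
            mask[list(comb)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u - mu) >= dev - 1e-9:
                hits += 1
        p = hits / total
    elif method == "asymptotic":
        pooled = np.concatenate([x, y])
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = (counts**3 - counts).sum()
        if n > 1:
            var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        else:
            var = 0.0
        if var <= 0:
            p = 1.0
        else:
            z = (u_obs - mu) / math.sqrt(var)
            p = two_sided_normal_p(z)
    else:
        raise ValueError(f"unknown method {method!r}")

    return MannWhitneyResult(
        u=u_obs,
        p=p,
        method=method,
        mean_x=float(np.mean(x)),
        mean_y=float(np.mean(y)),
        median_x=float(np.median(x)),
        median_y=float(np.median(y)),
    )
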