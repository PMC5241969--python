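"""Classification of non-coding mutation pairs against the chromatin
interaction network, with disease-concordance and contact-frequency
statistics.

Category precedence: different chromosomes first; then ``same_anchor``
(both mutations inside one shared anchor — no distance filter); then
``interacting`` (one mutation in an anchor, the other inside a target
linked to that anchor, in either direction); else
``non_interacting_same_chrom``.  The interacting and non-interacting
categories are kept only when ``min_bp < |pos_a - pos_b| < max_bp``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from enum import Enum
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .core_model.types import ChromatinNet, ContactMatrix, GenomicInterval, Mutation
from .stats import MannWhitneyResult, binomial_upper_tail, mann_whitney

__all__ = [
    "PairCategory",
    "DistanceFilter",
    "classify_pair",
    "ClassifiedPair",
    "classify_pairs",
    "CategoryConcordance",
    "concordance_by_category",
    "normalized_contact",
    "ContactComparison",
    "contact_comparison",
]


class PairCategory(str, Enum):
    SAME_ANCHOR = "same_anchor"
    INTERACTING = "interacting"
    NON_INTERACTING_SAME_CHROM = "non_interacting_same_chrom"
    DIFFERENT_CHROMOSOMES = "different_chromosomes"


#: distance thresholds used in the published analyses (bp)
MIN_BP_GRID = (0, 2000, 5000, 20000, 50000)


@dataclass(frozen=True)
class DistanceFilter:
    """Distance window applied to interacting / non-interacting pairs."""

    max_bp: int = 2_000_000
    min_bp: int = 0

    def __post_init__(self) -> None:
        if self.min_bp < 0 or self.max_bp <= self.min_bp:
            raise ValueError(f"need 0 <= min_bp < max_bp, got {self}")

    def admits(self, distance: int) -> bool:
        return self.min_bp < distance < self.max_bp


def _in_anchor_targets(net: ChromatinNet, anchor_ids: Sequence[str], other: Mutation) -> bool:
    for aid in anchor_ids:
        for target in net.targets_of(aid):
            if target.contains_pos(other.chrom, other.pos):
                return True
    return False


def classify_pair(
    a: Mutation,
    b: Mutation,
    net: ChromatinNet,
    f: DistanceFilter = DistanceFilter(),
) -> Optional[PairCategory]:
    """Category of one unordered mutation pair, or ``None`` if excluded
    by the distance filter.  Symmetric in ``a`` and ``b``."""
    if a.chrom != b.chrom:
        return PairCategory.DIFFERENT_CHROMOSOMES
    anchors_a = net.anchors_containing(a.chrom, a.pos)
    anchors_b = net.anchors_containing(b.chrom, b.pos)
    if set(anchors_a) & set(anchors_b):
        return PairCategory.SAME_ANCHOR
    distance = abs(a.pos - b.pos)
    if _in_anchor_targets(net, anchors_a, b) or _in_anchor_targets(net, anchors_b, a):
        return PairCategory.INTERACTING if f.admits(distance) else None
    return PairCategory.NON_INTERACTING_SAME_CHROM if f.admits(distance) else None


@dataclass(frozen=True)
class ClassifiedPair:
    a: Mutation
    b: Mutation
    category: PairCategory


def classify_pairs(
    muts: Sequence[Mutation],
    net: ChromatinNet,
    f: DistanceFilter = DistanceFilter(),
    include_cross_chrom: bool = False,
) -> List[ClassifiedPair]:
    """Classify all unordered pairs, efficiently.

    Same-chromosome candidates are found with a sorted sweep (only pairs
    closer than ``max_bp`` plus pairs sharing an anchor can be
    classified as anything but excluded, so the sweep is sufficient).
    Cross-chromosome pairs are enumerated only on request; use
    ``count_cross_chrom_pairs`` when only their number is needed.
    """
    pairs: List[ClassifiedPair] = []
    by_chrom: Dict[str, List[Mutation]] = {}
    for m in muts:
        by_chrom.setdefault(m.chrom, []).append(m)

    for chrom, group in by_chrom.items():
        group = sorted(group, key=lambda m: m.pos)
        n = len(group)
        seen: set = set()
        # sweep: pairs within max_bp
        for i in range(n):
            for j in range(i + 1, n):
                if group[j].pos - group[i].pos >= f.max_bp:
                    break
                cat = classify_pair(group[i], group[j], net, f)
                if cat is not None:
                    pairs.append(ClassifiedPair(group[i], group[j], cat))
                seen.add((id(group[i]), id(group[j])))
        # same-anchor pairs beyond the sweep (anchors wider than max_bp)
        anchor_members: Dict[str, List[Mutation]] = {}
        for m in group:
            for aid in net.anchors_containing(m.chrom, m.pos):
                anchor_members.setdefault(aid, []).append(m)
        for members in anchor_members.values():
            for a, b in itertools.combinations(members, 2):
                key = (id(a), id(b)) if a.pos <= b.pos else (id(b), id(a))
                if key in seen or abs(a.pos - b.pos) < f.max_bp:
                    continue
                seen.add(key)
                pairs.append(ClassifiedPair(a, b, PairCategory.SAME_ANCHOR))

    if include_cross_chrom:
        chroms = sorted(by_chrom)
        for ca, cb in itertools.combinations(chroms, 2):
            for a in by_chrom[ca]:
                for b in by_chrom[cb]:
                    pairs.append(ClassifiedPair(a, b, PairCategory.DIFFERENT_CHROMOSOMES))
    return pairs


def count_cross_chrom_pairs(muts: Sequence[Mutation]) -> int:
    """Number of mutation pairs on different chromosomes (combinatorial)."""
    sizes: Dict[str, int] = {}
    for m in muts:
        sizes[m.chrom] = sizes.get(m.chrom, 0) + 1
    total = sum(sizes.values())
    return (total * (total - 1) - sum(k * (k - 1) for k in sizes.values())) // 2


@dataclass(frozen=True)
class CategoryConcordance:
    n_pairs: int
    n_same_disease: int
    fraction: Optional[float]
    sem: Optional[float]
    p: Optional[float] = None


def concordance_by_category(
    pairs: Iterable[ClassifiedPair],
    reference: PairCategory = PairCategory.NON_INTERACTING_SAME_CHROM,
) -> Dict[PairCategory, CategoryConcordance]:
    """Same-disease fraction per category, with upper-tail cumulative
    binomial p-values against the reference category's fraction.

    Pairs where either mutation lacks disease annotations are dropped.
    """
    tallies: Dict[PairCategory, List[int]] = {c: [0, 0] for c in PairCategory}
    for cp in pairs:
        if not cp.a.diseases or not cp.b.diseases:
            continue
        tallies[cp.category][0] += 1
        tallies[cp.category][1] += int(cp.a.shares_disease(cp.b))
    n_ref, k_ref = tallies[reference]
    if n_ref == 0:
        raise ValueError(f"reference category {reference.value!r} has no pairs")
    p0 = k_ref / n_ref
    out: Dict[PairCategory, CategoryConcordance] = {}
    for cat, (n, k) in tallies.items():
        if n == 0:
            out[cat] = CategoryConcordance(0, 0, None, None, None)
            continue
        frac = k / n
        sem = math.sqrt(frac * (1 - frac) / n)
        p = binomial_upper_tail(k, n, p0) if cat is not reference else None
        out[cat] = CategoryConcordance(n, k, frac, sem, p)
    return out


def normalized_contact(cm: ContactMatrix, pos_a: int, pos_b: int) -> float:
    """SQRTVC-normalized contact count: raw(i, j) / (v_i * v_j)."""
    i, j = cm.bin_of(pos_a), cm.bin_of(pos_b)
    for b in (i, j):
        if b >= len(cm.normvec):
            raise ValueError(
                f"bin {b} outside normalization vector of length {len(cm.normvec)}"
            )
        v = cm.normvec[b]
        if not (v > 0) or not math.isfinite(v):
            raise ValueError(f"nonpositive normalization value {v} at bin {b}")
    raw = cm.raw(i, j)
    if raw == 0.0:
        return 0.0
    return raw / (cm.normvec[i] * cm.normvec[j])


@dataclass(frozen=True)
class ContactComparison:
    """Mann-Whitney comparison of normalized contacts: same- vs
    different-disease mutation pairs."""

    n_same: int
    n_diff: int
    u: float
    p: float
    method: str
    mean_same: float
    mean_diff: float
    median_same: float
    median_diff: float


def contact_comparison(
    pairs: Iterable[Tuple[Mutation, Mutation]],
    cm: ContactMatrix,
    exact_limit: int = 12,
) -> ContactComparison:
    """Compare contact frequency between same-disease and
    different-disease mutation pairs on ``cm.chrom``.

    Uses the asymptotic Mann-Whitney U test with tie correction, or the
    exact permutation distribution when the total sample is small.
    """
    same: List[float] = []
    diff: List[float] = []
    for a, b in pairs:
        if a.chrom != cm.chrom or b.chrom != cm.chrom:
            raise ValueError(
                f"pair ({a.id}, {b.id}) not on contact-matrix chromosome {cm.chrom}"
            )
        if not a.diseases or not b.diseases:
            continue
        value = normalized_contact(cm, a.pos, b.pos)
        (same if a.shares_disease(b) else diff).append(value)
    if not same or not diff:
        raise ValueError("both disease groups must be non-empty")
    res = mann_whitney(same, diff, method="auto", exact_limit=exact_limit)
    return ContactComparison(
        n_same=len(same),
        n_diff=len(diff),
        u=res.u,
        p=res.p,
        method=res.method,
        mean_same=res.mean_x,
        mean_diff=res.mean_y,
        median_same=res.median_x,
        median_diff=res.median_y,
    )
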