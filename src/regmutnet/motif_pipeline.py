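"""PWM motif scanning and the motif-localized mutation-pair analyses.

The scanner scores every window of a sequence with the summed
log-likelihood ratio of motif vs background base probabilities, on both
strands, and reports windows at or above the threshold.  Default knobs
(natural log, pseudocount 0.01, uniform background) are configurable.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .chromatin_pairs import ClassifiedPair, DistanceFilter, PairCategory, classify_pairs
from .core_model.types import (
    BASE_INDEX,
    ChromatinNet,
    GenomicInterval,
    MotifHit,
    Mutation,
    PWM,
    TFNetwork,
)
from .stats import binomial_upper_tail, log_ratio_result, two_sided_normal_p

__all__ = [
    "ScanConfig",
    "scan_motifs",
    "MotifPairCategory",
    "classify_motif_pair",
    "scramble_chromatin_network",
    "MotifPairEnrichment",
    "motif_pair_interaction_enrichment",
    "chromatin_motif_pair_analysis",
    "MotifCategoryConcordance",
    "concordance_by_motif_category",
]

#: threshold grids used for motif mapping and for the interacting-TF
#: motif-pair analysis respectively
MAPPING_THRESHOLDS = (6.0, 7.0, 8.0, 9.0)
PAIRING_THRESHOLDS = (8.0, 9.0, 10.0)


@dataclass(frozen=True)
class ScanConfig:
    threshold: float = 6.0
    window: int = 4000
    pseudocount: float = 0.01
    log_base: float = math.e
    both_strands: bool = True

    def __post_init__(self) -> None:
        if self.window <= 0 or self.window % 2:
            raise ValueError(f"window must be positive and even, got {self.window}")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")


def _log_odds(pwm: PWM, cfg: ScanConfig) -> np.ndarray:
    mat = pwm.matrix
    if np.any(mat == 0):
        if cfg.pseudocount == 0:
            raise ValueError(
                f"PWM {pwm.tf!r} has zero probabilities and pseudocount is 0"
            )
        mat = mat + cfg.pseudocount
        mat = mat / mat.sum(axis=1, keepdims=True)
    if np.any(pwm.background <= 0):
        raise ValueError(f"PWM {pwm.tf!r}: background must be strictly positive")
    return np.log(mat / pwm.background) / math.log(cfg.log_base)


def _encode(seq: str) -> np.ndarray:
    out = np.full(len(seq), -1, dtype=np.int8)
    for base, idx in BASE_INDEX.items():
        out[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = idx
    return out


def scan_motifs(
    seq: str,
    pwm: PWM,
    cfg: ScanConfig = ScanConfig(),
    chrom: str = "chrseq",
    offset: int = 0,
) -> List[MotifHit]:
    """All windows of ``seq`` scoring >= threshold for ``pwm``.

    Windows containing any non-ACGT character are skipped.  With
    ``both_strands`` the reverse strand is scanned by scoring the
    reverse-complement PWM on the forward sequence; minus-strand hits
    are reported on forward coordinates.  ``offset`` shifts reported
    intervals (hit start = offset + window index, 0-based).
    """
    seq = seq.upper()
    w = pwm.width
    if w > len(seq):
        return [] if seq == "" else _raise_width(pwm, seq)
    codes = _encode(seq)
    n_win = len(seq) - w + 1
    valid = np.ones(n_win, dtype=bool)
    bad = codes < 0
    if bad.any():
        # window i is invalid if any of codes[i:i+w] is bad
        cum = np.concatenate([[0], np.cumsum(bad)])
        valid = (cum[w:] - cum[:-w]) == 0
    safe_codes = np.where(bad, 0, codes)

    strands: List[Tuple[str, np.ndarray]] = [("+", _log_odds(pwm, cfg))]
    if cfg.both_strands:
        strands.append(("-", _log_odds(pwm.reverse_complement(), cfg)))

    hits: List[MotifHit] = []
    idx = np.arange(n_win)
    for strand, lo in strands:
        scores = np.zeros(n_win)
        for k in range(w):
            scores += lo[k, safe_codes[k : k + n_win]]
        for i in idx[valid & (scores >= cfg.threshold)]:
            hits.append(
                MotifHit(
                    tf=pwm.tf,
                    interval=GenomicInterval(chrom, offset + int(i), offset + int(i) + w),
                    strand=strand,
                    score=float(scores[i]),
                )
            )
    hits.sort(key=lambda h: (h.interval.start, h.strand))
    return hits


def _raise_width(pwm: PWM, seq: str):
    raise ValueError(f"PWM {pwm.tf!r} wider ({pwm.width}) than sequence ({len(seq)})")


class MotifPairCategory(str, Enum):
    SAME_MOTIF_SAME_POSITION = "same_motif_same_position"
    SAME_MOTIF_DIFFERENT_POSITION = "same_motif_different_position"
    DIFFERENT_MOTIFS_TFS_INTERACT = "different_motifs_tfs_interact"
    DIFFERENT_MOTIFS_TFS_DO_NOT_INTERACT = "different_motifs_tfs_do_not_interact"


def classify_motif_pair(
    hits_a: Sequence[MotifHit],
    hits_b: Sequence[MotifHit],
    tfnet: TFNetwork,
) -> Optional[MotifPairCategory]:
    """Best category over all hit combinations of a mutation pair.

    Precedence: identical binding site > same TF elsewhere > TFs
    interact > TFs do not interact.  Returns ``None`` (excluded) unless
    both mutations have at least one hit.  Symmetric in its arguments.
    """
    if not hits_a or not hits_b:
        return None
    sites_a = {h.site_key() for h in hits_a}
    sites_b = {h.site_key() for h in hits_b}
    if sites_a & sites_b:
        return MotifPairCategory.SAME_MOTIF_SAME_POSITION
    tfs_a = {h.tf for h in hits_a}
    tfs_b = {h.tf for h in hits_b}
    if tfs_a & tfs_b:
        return MotifPairCategory.SAME_MOTIF_DIFFERENT_POSITION
    for x in tfs_a:
        for y in tfs_b:
            if tfnet.has_edge(x, y):
                return MotifPairCategory.DIFFERENT_MOTIFS_TFS_INTERACT
    return MotifPairCategory.DIFFERENT_MOTIFS_TFS_DO_NOT_INTERACT


# ---------------------------------------------------------------------------
# degree-preserving scramble of the chromatin network
# ---------------------------------------------------------------------------

def scramble_chromatin_network(
    net: ChromatinNet,
    seed: int,
    swaps_per_edge: int = 10,
) -> ChromatinNet:
    """Randomize anchor->target edges by double-edge swaps.

    Swaps exchange the targets of two edges on the same chromosome, so
    every anchor keeps its degree, the multiset of target intervals per
    chromosome is preserved, and edges stay intra-chromosomal.  Swaps
    that would duplicate an existing edge are rejected.
    """
    rng = np.random.default_rng(seed)
    by_chrom: Dict[str, List[int]] = {}
    edges = list(net.edges)
    for i, (aid, target) in enumerate(edges):
        by_chrom.setdefault(target.chrom, []).append(i)
    edge_set = {(aid, t) for aid, t in edges}
    for chrom, idxs in by_chrom.items():
        if len(idxs) < 2:
            continue
        n_swaps = swaps_per_edge * len(idxs)
        for _ in range(n_swaps):
            i, j = rng.choice(len(idxs), size=2, replace=False)
            ei, ej = idxs[i], idxs[j]
            (a1, t1), (a2, t2) = edges[ei], edges[ej]
            if a1 == a2 or t1 == t2:
                continue
            new1, new2 = (a1, t2), (a2, t1)
            if new1 in edge_set or new2 in edge_set:
                continue
            edge_set.discard((a1, t1))
            edge_set.discard((a2, t2))
            edge_set.update((new1, new2))
            edges[ei], edges[ej] = new1, new2
    return ChromatinNet(net.anchors, edges)


# ---------------------------------------------------------------------------
# interacting-TF motif-pair enrichment
# ---------------------------------------------------------------------------

def _cross_region_tf_pairs(
    region_pairs: Iterable[Tuple[str, str]],
    hits_by_region: Mapping[str, Iterable[MotifHit]],
    include_self_pairs: bool,
) -> List[Tuple[str, str]]:
    """Unordered TF pairs across each interacting region pair (each
    distinct TF pair counted once per region pair)."""
    out: List[Tuple[str, str]] = []
    for ra, rb in region_pairs:
        tfs_a = {h.tf for h in hits_by_region.get(ra, ())}
        tfs_b = {h.tf for h in hits_by_region.get(rb, ())}
        pairs = set()
        for x in tfs_a:
            for y in tfs_b:
                if x == y and not include_self_pairs:
                    continue
                pairs.add((x, y) if x <= y else (y, x))
        out.extend(sorted(pairs))
    return out


def interacting_tf_baseline(tfnet: TFNetwork, include_self_pairs: bool = True) -> float:
    """Expected interacting fraction: edges over all possible pairs of
    TFs that have at least one interaction."""
    eligible = sorted(n for n, d in tfnet.degrees().items() if d >= 1)
    t = len(eligible)
    if t == 0:
        raise ValueError("TF network has no interacting TFs")
    denom = t * (t - 1) // 2 + (t if include_self_pairs else 0)
    eligible_set = set(eligible)
    num = 0
    for a, b in tfnet.edges:
        if a in eligible_set and b in eligible_set:
            if a == b and not include_self_pairs:
                continue
            num += 1
    if denom == 0:
        raise ValueError("no eligible TF pairs")
    return num / denom


@dataclass(frozen=True)
class MotifPairEnrichment:
    n_pairs: int
    n_interacting: int
    observed_fraction: float
    baseline: float
    enrichment: float
    se_log: Optional[float]
    z: Optional[float]
    p: Optional[float]
    # scrambled-network null (empirical), when computed
    null_fractions: Optional[Tuple[float, ...]] = None
    scramble_baseline: Optional[float] = None
    scramble_enrichment: Optional[float] = None
    scramble_p: Optional[float] = None


def motif_pair_interaction_enrichment(
    region_pairs: Sequence[Tuple[str, str]],
    hits_by_region: Mapping[str, Iterable[MotifHit]],
    tfnet: TFNetwork,
    include_self_pairs: bool = True,
    null_fractions: Optional[Sequence[float]] = None,
) -> MotifPairEnrichment:
    """Enrichment of interacting-TF motif pairs across region pairs.

    The analytic baseline is the interacting fraction of all possible
    TF pairs (see :func:`interacting_tf_baseline`); significance is a
    Z-test on the log enrichment.  When ``null_fractions`` from a
    scrambled network are supplied, an empirical-rank p-value and a
    second enrichment against the mean null fraction are also reported.
    """
    tf_pairs = _cross_region_tf_pairs(region_pairs, hits_by_region, include_self_pairs)
    n = len(tf_pairs)
    if n == 0:
        raise ValueError("no cross-region TF pairs (no motif hits?)")
    k = sum(1 for x, y in tf_pairs if tfnet.has_edge(x, y))
    observed = k / n
    baseline = interacting_tf_baseline(tfnet, include_self_pairs)

    se_log = z = p = None
    enrichment = observed / baseline
    if k > 0:
        # SE of ln(observed fraction) via the binomial delta method; the
        # baseline is a network constant with no sampling variance
        se_sq = (1.0 / k) - (1.0 / n)
        if se_sq > 0:
            se_log = math.sqrt(se_sq)
            z = math.log(enrichment) / se_log
            p = two_sided_normal_p(z)

    scr_base = scr_enr = scr_p = None
    nulls = None
    if null_fractions is not None and len(null_fractions) > 0:
        nulls = tuple(float(v) for v in null_fractions)
        scr_base = sum(nulls) / len(nulls)
        scr_enr = observed / scr_base if scr_base > 0 else math.inf
        n_ge = sum(1 for v in nulls if v >= observed)
        scr_p = (1 + n_ge) / (1 + len(nulls))

    return MotifPairEnrichment(
        n_pairs=n,
        n_interacting=k,
        observed_fraction=observed,
        baseline=baseline,
        enrichment=enrichment,
        se_log=se_log,
        z=z,
        p=p,
        null_fractions=nulls,
        scramble_baseline=scr_base,
        scramble_enrichment=scr_enr,
        scramble_p=scr_p,
    )


def chromatin_motif_pair_analysis(
    muts: Sequence[Mutation],
    net: ChromatinNet,
    hits_by_mutation: Mapping[str, Sequence[MotifHit]],
    tfnet: TFNetwork,
    f: DistanceFilter = DistanceFilter(),
    include_self_pairs: bool = True,
    n_scrambles: int = 100,
    swaps_per_edge: int = 10,
    seed: int = 0,
) -> MotifPairEnrichment:
    """End-to-end interacting-TF motif-pair enrichment.

    Region pairs are the interacting mutation pairs under ``net``; the
    scrambled-network null recomputes the interacting pairs and their
    TF-pair fraction on each degree-preserving scramble of ``net``.
    """

    def interacting_pairs(network: ChromatinNet) -> List[Tuple[str, str]]:
        return [
            (cp.a.id, cp.b.id)
            for cp in classify_pairs(muts, network, f)
            if cp.category is PairCategory.INTERACTING
        ]

    observed_pairs = interacting_pairs(net)
    nulls: List[float] = []
    for s in range(n_scrambles):
        scrambled = scramble_chromatin_network(net, seed=seed + s, swaps_per_edge=swaps_per_edge)
        pairs_s = _cross_region_tf_pairs(
            interacting_pairs(scrambled), hits_by_mutation, include_self_pairs
        )
        if pairs_s:
            nulls.append(
                sum(1 for x, y in pairs_s if tfnet.has_edge(x, y)) / len(pairs_s)
            )
    return motif_pair_interaction_enrichment(
        observed_pairs,
        hits_by_mutation,
        tfnet,
        include_self_pairs=include_self_pairs,
        null_fractions=nulls if n_scrambles > 0 else None,
    )


# ---------------------------------------------------------------------------
# disease concordance by motif-pair category
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifCategoryConcordance:
    n_pairs: int
    n_same_disease: int
    fraction: Optional[float]
    sem: Optional[float]
    p: Optional[float] = None


MOTIF_SCOPES = ("all", "same_chromosome", "same_anchor", "interacting")


def concordance_by_motif_category(
    pairs: Iterable[Tuple[Mutation, Mutation, MotifPairCategory]],
    reference: MotifPairCategory = MotifPairCategory.DIFFERENT_MOTIFS_TFS_DO_NOT_INTERACT,
) -> Dict[MotifPairCategory, MotifCategoryConcordance]:
    """Same-disease fraction per motif-pair category with cumulative
    binomial p-values against the reference category."""
    tallies: Dict[MotifPairCategory, List[int]] = {c: [0, 0] for c in MotifPairCategory}
    for a, b, cat in pairs:
        if not a.diseases or not b.diseases:
            continue
        tallies[cat][0] += 1
        tallies[cat][1] += int(a.shares_disease(b))
    n_ref, k_ref = tallies[reference]
    if n_ref == 0:
        raise ValueError(f"reference category {reference.value!r} has no pairs")
    p0 = k_ref / n_ref
    out: Dict[MotifPairCategory, MotifCategoryConcordance] = {}
    for cat, (n, k) in tallies.items():
        if n == 0:
            out[cat] = MotifCategoryConcordance(0, 0, None, None, None)
            continue
        frac = k / n
        sem = math.sqrt(frac * (1 - frac) / n)
        p = binomial_upper_tail(k, n, p0) if cat is not reference else None
        out[cat] = MotifCategoryConcordance(n, k, frac, sem, p)
    return out


def motif_pair_concordance(
    muts: Sequence[Mutation],
    hits_by_mutation: Mapping[str, Sequence[MotifHit]],
    tfnet: TFNetwork,
    scope: str = "all",
    net: Optional[ChromatinNet] = None,
    f: DistanceFilter = DistanceFilter(),
) -> Dict[MotifPairCategory, MotifCategoryConcordance]:
    """Scope-filtered motif-pair concordance.

    ``scope`` restricts the mutation pairs considered: ``all`` (every
    unordered pair), ``same_chromosome``, or the chromatin categories
    ``same_anchor`` / ``interacting`` (these require ``net``).  Pairs
    where either mutation has no motif hit are excluded.
    """
    if scope not in MOTIF_SCOPES:
        raise ValueError(f"scope {scope!r} not in {MOTIF_SCOPES}")
    selected: List[Tuple[Mutation, Mutation]] = []
    if scope == "all":
        selected = list(itertools.combinations(muts, 2))
    elif scope == "same_chromosome":
        selected = [
            (a, b) for a, b in itertools.combinations(muts, 2) if a.chrom == b.chrom
        ]
    else:
        if net is None:
            raise ValueError(f"scope {scope!r} requires a chromatin network")
        want = PairCategory.SAME_ANCHOR if scope == "same_anchor" else PairCategory.INTERACTING
        selected = [
            (cp.a, cp.b) for cp in classify_pairs(muts, net, f) if cp.category is want
        ]
    classified = []
    for a, b in selected:
        cat = classify_motif_pair(
            hits_by_mutation.get(a.id, ()), hits_by_mutation.get(b.id, ()), tfnet
        )
        if cat is not None:
            classified.append((a, b, cat))
    return concordance_by_motif_category(classified)
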