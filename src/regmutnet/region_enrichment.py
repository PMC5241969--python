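"""Enrichment of non-coding mutations in chromatin-state segments and in
TF binding-motif territory.

Length-normalized enrichment for a merged region set:

    Enrichment = (n_mut_region * l_total) / (n_mut_total * l_region)
    SE_ln      = sqrt(1/n_mut_region - 1/n_mut_total
                      + 1/l_region - 1/l_total)
    Z          = ln(Enrichment) / SE_ln
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .core_model.types import (
    EnrichmentResult,
    GenomicInterval,
    MotifHit,
    Mutation,
    normalize_chrom,
)
from .stats import log_ratio_result

__all__ = [
    "SCHEME_LABEL_MAPS",
    "SegmentationTrack",
    "merge_intervals",
    "total_length",
    "merge_cell_lines",
    "RegionSet",
    "RegionEnrichment",
    "segment_enrichment",
    "motif_territory_enrichment",
]

# raw segmentation label -> derived class, per annotation scheme
SCHEME_LABEL_MAPS: Dict[str, Dict[str, str]] = {
    "chromhmm": {
        "Tss": "TSS", "TssF": "TSS",
        "Enh": "enhancer", "EnhF": "enhancer",
    },
    "segway": {
        "Tss": "TSS", "TssF": "TSS",
        "Enh": "enhancer", "Enh1": "enhancer", "Enh2": "enhancer",
        "EnhF": "enhancer", "EnhF1": "enhancer", "EnhF2": "enhancer",
        "EnhF3": "enhancer", "EnhP": "enhancer", "EnhPr": "enhancer",
    },
    "combined": {
        "TSS": "TSS", "E": "enhancer",
    },
}


@dataclass
class SegmentationTrack:
    """One cell line's chromatin-state segmentation."""

    scheme: str
    segments: List[Tuple[GenomicInterval, str]]

    def __post_init__(self) -> None:
        if self.scheme not in SCHEME_LABEL_MAPS:
            raise ValueError(
                f"unknown scheme {self.scheme!r}; expected one of {sorted(SCHEME_LABEL_MAPS)}"
            )

    def class_of(self, raw_label: str) -> str:
        return SCHEME_LABEL_MAPS[self.scheme].get(raw_label, "other")

    def intervals_of_class(self, cls: str) -> List[GenomicInterval]:
        return [iv for iv, label in self.segments if self.class_of(label) == cls]


def merge_intervals(intervals: Iterable[GenomicInterval]) -> List[GenomicInterval]:
    """Union of intervals as disjoint sorted intervals (touching merge)."""
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    merged: List[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        spans = sorted(by_chrom[chrom])
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return merged


def total_length(intervals: Iterable[GenomicInterval]) -> int:
    return sum(len(iv) for iv in intervals)


def merge_cell_lines(tracks: Sequence[SegmentationTrack], cls: str) -> List[GenomicInterval]:
    """Union of one derived class's intervals across cell lines."""
    if not tracks:
        raise ValueError("no tracks given")
    schemes = {t.scheme for t in tracks}
    if len(schemes) > 1:
        raise ValueError(f"mixed segmentation schemes {sorted(schemes)}")
    ivs: List[GenomicInterval] = []
    for t in tracks:
        ivs.extend(t.intervals_of_class(cls))
    return merge_intervals(ivs)


class RegionSet:
    """Merged disjoint intervals with fast point-membership queries."""

    def __init__(self, intervals: Iterable[GenomicInterval]) -> None:
        self.intervals = merge_intervals(intervals)
        self._index: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
        for iv in self.intervals:
            self._index.setdefault(iv.chrom, ([], []))  # type: ignore[arg-type]
        by_chrom: Dict[str, List[Tuple[int, int]]] = {}
        for iv in self.intervals:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self._index = {
            chrom: (
                np.array([s for s, _ in spans], dtype=np.int64),
                np.array([e for _, e in spans], dtype=np.int64),
            )
            for chrom, spans in by_chrom.items()
        }

    @property
    def length(self) -> int:
        return total_length(self.intervals)

    def contains(self, chrom: str, pos: int) -> bool:
        """Membership of a 1-based position."""
        chrom = normalize_chrom(chrom)
        if chrom not in self._index:
            return False
        starts, ends = self._index[chrom]
        p = pos - 1
        i = int(np.searchsorted(starts, p, side="right")) - 1
        return i >= 0 and p < ends[i]


@dataclass(frozen=True)
class RegionEnrichment:
    """Counts/lengths behind a length-normalized enrichment estimate."""

    n_mut_region: int
    n_mut_total: int
    l_region: int
    l_total: int
    result: EnrichmentResult


def segment_enrichment(
    muts: Sequence[Mutation],
    region_set: RegionSet | Iterable[GenomicInterval],
    l_total: int,
) -> RegionEnrichment:
    """Mutation enrichment in a merged region set vs the whole territory.

    ``l_total`` is the summed length of all chromosomes considered.
    With zero mutations in the region the estimate is 0 and SE/Z/p are
    undefined (``None``).
    """
    if not isinstance(region_set, RegionSet):
        region_set = RegionSet(region_set)
    l_region = region_set.length
    if l_region <= 0:
        raise ValueError("region set has zero length")
    if l_total < l_region:
        raise ValueError(f"l_total={l_total} smaller than l_region={l_region}")
    n_total = len(muts)
    if n_total == 0:
        raise ValueError("no mutations given")
    n_region = sum(1 for m in muts if region_set.contains(m.chrom, m.pos))
    if n_region == 0:
        return RegionEnrichment(
            0, n_total, l_region, l_total,
            EnrichmentResult(estimate=0.0, se_log=None, z=None, p=None),
        )
    estimate = (n_region * l_total) / (n_total * l_region)
    se_sq = (1.0 / n_region) - (1.0 / n_total) + (1.0 / l_region) - (1.0 / l_total)
    if se_sq <= 0:
        # degenerate when region == whole territory and all muts inside;
        # an exact-null estimate still gets z = 0
        if estimate == 1.0:
            return RegionEnrichment(
                n_region, n_total, l_region, l_total,
                EnrichmentResult(estimate=1.0, se_log=None, z=0.0, p=1.0),
            )
        return RegionEnrichment(
            n_region, n_total, l_region, l_total,
            EnrichmentResult(estimate=estimate, se_log=None, z=None, p=None),
        )
    return RegionEnrichment(
        n_region, n_total, l_region, l_total, log_ratio_result(estimate, math.sqrt(se_sq))
    )


def motif_territory_enrichment(
    variants: Sequence[Mutation],
    hits: Iterable[MotifHit],
    window: int = 4000,
) -> RegionEnrichment:
    """Enrichment of variants inside TF binding motifs.

    Search regions are ``window``-bp intervals centred at each variant.
    The estimate is the fraction of variants inside at least one motif
    divided by the motif footprint fraction of the search territory;
    uniform random placement therefore gives 1.  Overlapping motif hits
    are merged into a footprint before measuring length, and the
    footprint is clipped to the search regions.
    """
    if window <= 0 or window % 2:
        raise ValueError(f"window must be positive and even, got {window}")
    if not variants:
        raise ValueError("no variants given")
    half = window // 2
    search_ivs = []
    for v in variants:
        start = max(0, v.pos - 1 - half)
        search_ivs.append(GenomicInterval(v.chrom, start, v.pos - 1 + half))
    hit_set = RegionSet(h.interval for h in hits)
    n_total = len(variants)
    n_in_motif = sum(1 for v in variants if hit_set.contains(v.chrom, v.pos))

    # footprint of motifs restricted to the union of search regions;
    # search-region length is summed per variant (windows may overlap)
    l_search = sum(len(iv) for iv in search_ivs)
    search_set = RegionSet(search_ivs)
    l_motifs = 0
    for m_iv in hit_set.intervals:
        starts, ends = search_set._index.get(m_iv.chrom, (None, None))
        if starts is None:
            continue
        lo = np.searchsorted(ends, m_iv.start, side="right")
        hi = np.searchsorted(starts, m_iv.end, side="left")
        for k in range(lo, hi):
            l_motifs += max(0, min(m_iv.end, int(ends[k])) - max(m_iv.start, int(starts[k])))

    if l_motifs == 0:
        raise ValueError("zero motif footprint inside the search regions")
    if n_in_motif == 0:
        return RegionEnrichment(
            0, n_total, l_motifs, l_search,
            EnrichmentResult(estimate=0.0, se_log=None, z=None, p=None),
        )
    estimate = (n_in_motif * l_search) / (n_total * l_motifs)
    se_sq = (1.0 / n_in_motif) - (1.0 / n_total) + (1.0 / l_motifs) - (1.0 / l_search)
    if se_sq <= 0:
        z, p = (0.0, 1.0) if estimate == 1.0 else (None, None)
        return RegionEnrichment(
            n_in_motif, n_total, l_motifs, l_search,
            EnrichmentResult(estimate=estimate, se_log=None, z=z, p=p),
        )
    return RegionEnrichment(
        n_in_motif, n_total, l_motifs, l_search, log_ratio_result(estimate, math.sqrt(se_sq))
    )
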