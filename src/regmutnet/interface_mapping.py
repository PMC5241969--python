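"""Interface classification of coding missense mutations and odds-ratio
enrichment, plus disease concordance of mutation pairs across TFs.

The odds ratio contrasts the fraction of mutations falling in one
interface class (p1) with the fraction of residues belonging to that
class (p2):

    OR       = (p1 / (1 - p1)) / (p2 / (1 - p2))
    SE_lnOR  = sqrt(1/n_mut_region + 1/n_mut_other
                    + 1/n_res_region + 1/n_res_other)
    Z        = ln(OR) / SE_lnOR
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .core_model.types import (
    EnrichmentResult,
    InterfaceClass,
    InterfaceMap,
    Mutation,
    MutationClass,
    TFNetwork,
)
from .stats import binomial_upper_tail, log_ratio_result

logger = logging.getLogger(__name__)

__all__ = [
    "InterfaceCounts",
    "classify_mutation_interface",
    "build_interface_counts",
    "interface_odds_ratio",
    "TFPairConcordance",
    "same_disease_fraction_tf_pairs",
]

COUNT_CLASSES = (
    InterfaceClass.DOUBLE,
    InterfaceClass.PROTEIN_BINDING,
    InterfaceClass.DNA_BINDING,
    InterfaceClass.NONE,
)


@dataclass
class InterfaceCounts:
    """Mutation and residue counts per mutually exclusive interface class."""

    n_mut: Dict[InterfaceClass, int]
    n_res: Dict[InterfaceClass, int]

    @property
    def n_mut_total(self) -> int:
        return sum(self.n_mut.values())

    @property
    def n_res_total(self) -> int:
        return sum(self.n_res.values())


def classify_mutation_interface(m: Mutation, imap: InterfaceMap) -> InterfaceClass:
    """Interface class of a coding missense mutation's residue."""
    if m.protein != imap.protein:
        raise ValueError(
            f"mutation {m.id!r} is on {m.protein!r}, not {imap.protein!r}"
        )
    if m.residue is None:
        raise ValueError(f"mutation {m.id!r} has no residue index")
    return imap.residue_class(m.residue)


def build_interface_counts(
    muts: Sequence[Mutation],
    imaps: Mapping[str, InterfaceMap],
    restrict: bool = False,
) -> InterfaceCounts:
    """Tally mutations and residues per interface class.

    With ``restrict=True``, proteins lacking either a protein-binding or
    a DNA-binding interface (``double`` counts as both) are excluded
    entirely, along with their mutations.  Mutations on proteins absent
    from ``imaps`` are skipped with a logged count.  Residues of each
    included protein are counted exactly once.
    """
    if not muts or not imaps:
        raise ValueError("mutations and interface maps must be non-empty")
    included = {}
    for protein, im in imaps.items():
        if restrict and not (
            im.has_raw_class(InterfaceClass.PROTEIN_BINDING)
            and im.has_raw_class(InterfaceClass.DNA_BINDING)
        ):
            continue
        included[protein] = im

    n_res = {c: 0 for c in COUNT_CLASSES}
    for im in included.values():
        for cls, count in im.residue_counts().items():
            n_res[cls] += count

    n_mut = {c: 0 for c in COUNT_CLASSES}
    skipped = 0
    for m in muts:
        if m.mclass is not MutationClass.CODING_MISSENSE:
            continue
        if m.protein not in included:
            skipped += 1
            continue
        n_mut[classify_mutation_interface(m, included[m.protein])] += 1
    if skipped:
        logger.info("build_interface_counts: skipped %d mutations on excluded proteins", skipped)
    return InterfaceCounts(n_mut=n_mut, n_res=n_res)


def interface_odds_ratio(counts: InterfaceCounts, cls: InterfaceClass) -> EnrichmentResult:
    """Odds-ratio enrichment of mutations in one interface class."""
    n_mut_region = counts.n_mut[cls]
    n_mut_other = counts.n_mut_total - n_mut_region
    n_res_region = counts.n_res[cls]
    n_res_other = counts.n_res_total - n_res_region
    for name, v in (
        ("n_mut_region", n_mut_region),
        ("n_mut_other", n_mut_other),
        ("n_res_region", n_res_region),
        ("n_res_other", n_res_other),
    ):
        if v <= 0:
            raise ValueError(
                f"{name} = {v}: odds ratio SE undefined with an empty cell; "
                "collapse classes or add data (no automatic continuity correction)"
            )
    odds_ratio = (n_mut_region / n_mut_other) / (n_res_region / n_res_other)
    se = math.sqrt(
        1.0 / n_mut_region + 1.0 / n_mut_other + 1.0 / n_res_region + 1.0 / n_res_other
    )
    return log_ratio_result(odds_ratio, se)


@dataclass(frozen=True)
class TFPairConcordance:
    """Same-disease fraction of mutation pairs in one pair category."""

    n_pairs: int
    n_same_disease: int
    fraction: Optional[float]        # None when the category is empty
    sem: Optional[float]
    p: Optional[float] = None        # only on the tested category


def same_disease_fraction_tf_pairs(
    muts: Sequence[Mutation],
    tfnet: TFNetwork,
) -> Dict[str, TFPairConcordance]:
    """Disease concordance of mutation pairs across two distinct TFs.

    Pairs are unordered pairs of coding missense mutations (with at
    least one disease ID each) whose proteins differ.  A pair is
    ``across_interacting`` iff the TF network has the edge.  The p-value
    is an upper-tail cumulative binomial for the interacting category's
    same-disease count under the non-interacting fraction as null.
    """
    eligible = [
        m
        for m in muts
        if m.mclass is MutationClass.CODING_MISSENSE and m.diseases and m.protein
    ]
    tallies = {
        "across_interacting": [0, 0],
        "across_non_interacting": [0, 0],
    }
    for a, b in itertools.combinations(eligible, 2):
        if a.protein == b.protein:
            continue
        key = (
            "across_interacting"
            if tfnet.has_edge(a.protein, b.protein)
            else "across_non_interacting"
        )
        tallies[key][0] += 1
        tallies[key][1] += int(a.shares_disease(b))

    out: Dict[str, TFPairConcordance] = {}
    null_fraction: Optional[float] = None
    n_ref, k_ref = tallies["across_non_interacting"]
    if n_ref > 0:
        null_fraction = k_ref / n_ref
    for key, (n, k) in tallies.items():
        if n == 0:
            out[key] = TFPairConcordance(0, 0, None, None, None)
            continue
        frac = k / n
        sem = math.sqrt(frac * (1 - frac) / n)
        p = None
        if key == "across_interacting" and null_fraction is not None:
            p = binomial_upper_tail(k, n, null_fraction)
        out[key] = TFPairConcordance(n, k, frac, sem, p)
    return out
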