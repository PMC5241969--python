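"""Seeded generators for every pipeline input, with planted effect sizes.

All generators are pure functions of :class:`SimConfig` (the seed is part
of the config), so the same config always yields the identical dataset.

Layout of the chromatin simulation
----------------------------------
Chromosomes are divided into 4-Mb *slots*.  Each planted mutation pair
lives inside a single slot, and every placement stays within the first
~1 Mb of its slot, so any two mutations from different slots are more
than 2 Mb apart and fall outside the distance window used by the pair
classifier.  Per-category concordance rates therefore recover the
planted θ values without cross-pair dilution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .core_model.types import (
    BASES,
    ChromatinNet,
    ContactMatrix,
    GenomicInterval,
    InterfaceClass,
    InterfaceMap,
    Mutation,
    MutationClass,
    PWM,
    TFNetwork,
)

__all__ = [
    "SimConfig",
    "simulate_interface_dataset",
    "simulate_chromatin_dataset",
    "simulate_motif_dataset",
    "SimChromatinData",
    "SimMotifData",
]

SLOT_BP = 4_000_000
PLACEMENT_SPAN = 1_000_000  # all placements stay within this span of a slot


def _default_interface_fraction() -> Dict[InterfaceClass, float]:
    return {
        InterfaceClass.DOUBLE: 0.05,
        InterfaceClass.PROTEIN_BINDING: 0.10,
        InterfaceClass.DNA_BINDING: 0.10,
    }


@dataclass(frozen=True)
class SimConfig:
    """Knobs for all three generators; unused fields are ignored."""

    seed: int = 0
    # --- coding / interface simulation ---
    n_proteins: int = 40
    protein_length_range: Tuple[int, int] = (200, 600)
    interface_fraction: Mapping[InterfaceClass, float] = field(
        default_factory=_default_interface_fraction
    )
    n_mut_coding: int = 3000
    planted_log_or: Mapping[InterfaceClass, float] = field(default_factory=dict)
    # --- chromatin simulation ---
    n_chroms: int = 1
    chrom_length: int = 8_000_000_000
    n_anchors: Optional[int] = None  # default: one per planted anchored pair
    anchor_length: int = 10_000
    edges_per_anchor: int = 2
    n_pairs_same_anchor: int = 100
    n_pairs_interacting: int = 150
    n_pairs_non_interacting: int = 500
    n_diseases: int = 500
    theta_same_anchor: float = 0.8
    theta_int: float = 0.4
    theta_bg: float = 0.05
    contact_mu: float = 50.0
    contact_dispersion: float = 5.0
    contact_boost: float = 3.0
    contact_decay: float = -1.0
    resolution: int = 5000
    # --- motif simulation ---
    motif_set_size: int = 20
    motif_width: int = 10
    n_region_pairs: int = 60
    region_length: int = 4000
    motif_plant_prob: float = 1.0
    motif_interacting_prob: float = 0.75

    def __post_init__(self) -> None:
        for name in ("theta_same_anchor", "theta_int", "theta_bg",
                     "motif_plant_prob", "motif_interacting_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        fracs = dict(self.interface_fraction)
        if any(v < 0 for v in fracs.values()) or sum(fracs.values()) > 1.0:
            raise ValueError(f"interface fractions must be >= 0 and sum <= 1: {fracs}")
        lo, hi = self.protein_length_range
        if not (1 <= lo <= hi):
            raise ValueError(f"bad protein_length_range {self.protein_length_range}")

    @property
    def n_mut_noncoding(self) -> int:
        return 2 * (
            self.n_pairs_same_anchor
            + self.n_pairs_interacting
            + self.n_pairs_non_interacting
        )


# ---------------------------------------------------------------------------
# interface / coding simulation
# ---------------------------------------------------------------------------

def simulate_interface_dataset(
    cfg: SimConfig,
) -> Tuple[Dict[str, InterfaceMap], List[Mutation]]:
    """Interface maps plus coding missense mutations with planted odds.

    Residues are assigned to classes at the configured fractions as
    contiguous blocks.  Each mutation picks a class with probability
    proportional to ``n_res[class] * exp(planted_log_or[class])`` and a
    uniform residue within that class, which makes the odds-ratio
    estimator's expectation equal ``exp(planted_log_or)`` for a class
    whose θ is the only nonzero one.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.protein_length_range
    lengths = rng.integers(lo, hi + 1, size=cfg.n_proteins)

    imaps: Dict[str, InterfaceMap] = {}
    # residue pools per class: parallel arrays (protein index, residue)
    pools: Dict[InterfaceClass, List[Tuple[int, int, int]]] = {
        c: [] for c in (InterfaceClass.DOUBLE, InterfaceClass.PROTEIN_BINDING,
                        InterfaceClass.DNA_BINDING, InterfaceClass.NONE)
    }
    fracs = dict(cfg.interface_fraction)
    for pi in range(cfg.n_proteins):
        name = f"P{pi:04d}"
        length = int(lengths[pi])
        sizes = {c: int(round(fracs.get(c, 0.0) * length)) for c in fracs}
        if sum(sizes.values()) >= length:
            raise ValueError(f"interface fractions leave no unannotated residues for length {length}")
        intervals = []
        cursor = 1
        for cls in (InterfaceClass.DOUBLE, InterfaceClass.PROTEIN_BINDING, InterfaceClass.DNA_BINDING):
            sz = sizes.get(cls, 0)
            if sz > 0:
                intervals.append((cursor, cursor + sz - 1, cls))
                pools[cls].append((pi, cursor, cursor + sz - 1))
                cursor += sz
        pools[InterfaceClass.NONE].append((pi, cursor, length))
        imaps[name] = InterfaceMap(name, length, intervals)

    class_order = list(pools)
    n_res = {
        c: sum(e - s + 1 for _, s, e in blocks) for c, blocks in pools.items()
    }
    weights = np.array(
        [n_res[c] * math.exp(cfg.planted_log_or.get(c, 0.0)) for c in class_order],
        dtype=float,
    )
    weights /= weights.sum()

    muts: List[Mutation] = []
    class_draws = rng.choice(len(class_order), size=cfg.n_mut_coding, p=weights)
    for k, ci in enumerate(class_draws):
        cls = class_order[ci]
        blocks = pools[cls]
        block_sizes = np.array([e - s + 1 for _, s, e in blocks], dtype=float)
        bi = rng.choice(len(blocks), p=block_sizes / block_sizes.sum())
        pi, s, e = blocks[bi]
        residue = int(rng.integers(s, e + 1))
        muts.append(
            Mutation(
                id=f"CM{k:05d}",
                chrom="chr1",
                pos=k + 1,
                mclass=MutationClass.CODING_MISSENSE,
                protein=f"P{pi:04d}",
                residue=residue,
                diseases=frozenset({f"D{int(rng.integers(cfg.n_diseases)):04d}"}),
            )
        )
    return imaps, muts


# ---------------------------------------------------------------------------
# chromatin simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimChromatinData:
    net: ChromatinNet
    mutations: List[Mutation]
    contacts: ContactMatrix
    #: planted pair categories: list of (id_a, id_b, category_name)
    planted_pairs: List[Tuple[str, str, str]]


def _draw_disease_pair(rng: np.random.Generator, theta: float, n_diseases: int) -> Tuple[str, str]:
    if rng.random() < theta:
        d = f"D{int(rng.integers(n_diseases)):04d}"
        return d, d
    a = f"D{int(rng.integers(n_diseases)):04d}"
    b = f"D{int(rng.integers(n_diseases)):04d}"
    return a, b


def simulate_chromatin_dataset(cfg: SimConfig) -> SimChromatinData:
    """Chromatin network, non-coding mutations with diseases, contacts.

    Anchors are non-overlapping (one per slot).  Disease labels are
    drawn so the category-conditional same-disease probability equals
    the planted θ up to the small chance collision of two independent
    draws (~1/n_diseases).
    """
    rng = np.random.default_rng(cfg.seed)
    n_sa, n_int, n_bg = (
        cfg.n_pairs_same_anchor,
        cfg.n_pairs_interacting,
        cfg.n_pairs_non_interacting,
    )
    n_anchors = cfg.n_anchors if cfg.n_anchors is not None else n_sa + n_int
    if n_anchors < n_sa + n_int:
        raise ValueError(
            f"n_anchors={n_anchors} cannot host {n_sa}+{n_int} anchored pairs"
        )
    slots_per_chrom = cfg.chrom_length // SLOT_BP
    n_slots_needed = n_anchors + n_bg
    if n_slots_needed > cfg.n_chroms * slots_per_chrom:
        raise ValueError(
            f"anchors cannot fit: need {n_slots_needed} slots, have "
            f"{cfg.n_chroms * slots_per_chrom} "
            f"({cfg.n_chroms} chroms x {slots_per_chrom})"
        )

    def slot_location(s: int) -> Tuple[str, int]:
        chrom = f"chr{s // slots_per_chrom + 1}"
        return chrom, (s % slots_per_chrom) * SLOT_BP

    anchors: Dict[str, GenomicInterval] = {}
    edges: List[Tuple[str, GenomicInterval]] = []
    target_span = 10_000
    for a in range(n_anchors):
        chrom, start = slot_location(a)
        aid = f"A{a:05d}"
        anchors[aid] = GenomicInterval(chrom, start, start + cfg.anchor_length)
        for j in range(cfg.edges_per_anchor):
            t_start = start + 200_000 * (j + 1)
            if t_start + target_span > start + PLACEMENT_SPAN:
                raise ValueError("edges_per_anchor too large for slot placement span")
            edges.append((aid, GenomicInterval(chrom, t_start, t_start + target_span)))
    net = ChromatinNet(anchors, edges)

    muts: List[Mutation] = []
    planted: List[Tuple[str, str, str]] = []
    mut_idx = 0

    def add_mut(chrom: str, pos: int, disease: str) -> str:
        nonlocal mut_idx
        mid = f"M{mut_idx:05d}"
        muts.append(
            Mutation(
                id=mid, chrom=chrom, pos=pos,
                mclass=MutationClass.NON_CODING,
                diseases=frozenset({disease}),
            )
        )
        mut_idx += 1
        return mid

    # same-anchor pairs: both mutations inside the pair's own anchor
    for k in range(n_sa):
        chrom, start = slot_location(k)
        p1 = start + 1 + int(rng.integers(cfg.anchor_length // 2))
        p2 = start + 1 + cfg.anchor_length // 2 + int(rng.integers(cfg.anchor_length // 2))
        d1, d2 = _draw_disease_pair(rng, cfg.theta_same_anchor, cfg.n_diseases)
        planted.append((add_mut(chrom, p1, d1), add_mut(chrom, p2, d2), "same_anchor"))

    # interacting pairs: one mutation in the anchor, one in its first target
    for k in range(n_int):
        s = n_sa + k
        chrom, start = slot_location(s)
        p1 = start + 1 + int(rng.integers(cfg.anchor_length))
        t_start = start + 200_000
        p2 = t_start + 1 + int(rng.integers(target_span))
        d1, d2 = _draw_disease_pair(rng, cfg.theta_int, cfg.n_diseases)
        planted.append((add_mut(chrom, p1, d1), add_mut(chrom, p2, d2), "interacting"))

    # non-interacting pairs: anchor-free slots, ~100 kb apart
    for k in range(n_bg):
        s = n_anchors + k
        chrom, start = slot_location(s)
        p1 = start + 400_000 + 1 + int(rng.integers(50_000))
        p2 = start + 500_000 + 1 + int(rng.integers(50_000))
        d1, d2 = _draw_disease_pair(rng, cfg.theta_bg, cfg.n_diseases)
        planted.append((add_mut(chrom, p1, d1), add_mut(chrom, p2, d2), "non_interacting"))

    # contact matrix for chr1: NB counts with distance decay, boosted for
    # same-disease pairs, plus per-bin diagonal mass so row sums vary
    entries: Dict[Tuple[int, int], float] = {}
    mut_by_id = {m.id: m for m in muts}
    for ida, idb, _cat in planted:
        a, b = mut_by_id[ida], mut_by_id[idb]
        if a.chrom != "chr1" or b.chrom != "chr1":
            continue
        i, j = (a.pos - 1) // cfg.resolution, (b.pos - 1) // cfg.resolution
        dist = max(abs(i - j), 1)
        mean = cfg.contact_mu * dist ** cfg.contact_decay
        if a.shares_disease(b):
            mean *= cfg.contact_boost
        r = cfg.contact_dispersion
        count = rng.negative_binomial(r, r / (r + mean))
        key = (i, j) if i <= j else (j, i)
        entries[key] = entries.get(key, 0.0) + float(count)
        for b_ in (i, j):
            diag = float(rng.poisson(cfg.contact_mu))
            entries[(b_, b_)] = entries.get((b_, b_), 0.0) + diag

    max_bin = max((k[1] for k in entries), default=0)
    row_sums = np.zeros(max_bin + 1)
    for (i, j), v in entries.items():
        row_sums[i] += v
        if j != i:
            row_sums[j] += v
    normvec = np.where(row_sums > 0, np.sqrt(np.maximum(row_sums, 1e-12)), 1.0)
    cm = ContactMatrix("chr1", cfg.resolution, entries, normvec)

    return SimChromatinData(net=net, mutations=muts, contacts=cm, planted_pairs=planted)


# ---------------------------------------------------------------------------
# motif simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimMotifData:
    sequences: Dict[str, str]
    pwms: List[PWM]
    tfnet: TFNetwork
    #: region id -> list of (tf, planted 0-based start)
    planted_sites: Dict[str, List[Tuple[str, int]]]
    region_pairs: List[Tuple[str, str]]


def simulate_motif_dataset(cfg: SimConfig) -> SimMotifData:
    """Sequences with embedded consensus sites, consensus-heavy PWMs, a
    TF network, and region pairs with a planted excess of interacting-TF
    motif co-occurrence.

    Each region pair receives (with probability ``motif_plant_prob``)
    one consensus site on each side; with probability
    ``motif_interacting_prob`` the two TFs are an edge of the network,
    otherwise a uniform random TF pair.
    """
    if cfg.motif_width > cfg.region_length:
        raise ValueError(
            f"motif width {cfg.motif_width} exceeds region length {cfg.region_length}"
        )
    rng = np.random.default_rng(cfg.seed)
    tfs = [f"TF{t:03d}" for t in range(cfg.motif_set_size)]
    if len(tfs) < 4:
        raise ValueError("motif_set_size must be >= 4")

    pwms: List[PWM] = []
    consensus: Dict[str, str] = {}
    for tf in tfs:
        cons = "".join(BASES[i] for i in rng.integers(4, size=cfg.motif_width))
        consensus[tf] = cons
        mat = np.full((cfg.motif_width, 4), 0.01)
        for k, base in enumerate(cons):
            mat[k, BASES.index(base)] = 0.97
        pwms.append(PWM(tf, mat))

    # sparse ring network: TF_i -- TF_{i+1}
    ring_edges = [(tfs[i], tfs[(i + 1) % len(tfs)]) for i in range(len(tfs))]
    tfnet = TFNetwork(tfs, ring_edges)
    edge_list = sorted(tfnet.edges)

    sequences: Dict[str, str] = {}
    planted: Dict[str, List[Tuple[str, int]]] = {}
    region_pairs: List[Tuple[str, str]] = []

    def random_seq(n: int) -> str:
        return "".join(BASES[i] for i in rng.integers(4, size=n))

    for k in range(cfg.n_region_pairs):
        ra, rb = f"R{k:04d}a", f"R{k:04d}b"
        sequences[ra] = random_seq(cfg.region_length)
        sequences[rb] = random_seq(cfg.region_length)
        planted[ra] = []
        planted[rb] = []
        region_pairs.append((ra, rb))
        if rng.random() >= cfg.motif_plant_prob:
            continue
        if rng.random() < cfg.motif_interacting_prob:
            x, y = edge_list[int(rng.integers(len(edge_list)))]
        else:
            x, y = (tfs[i] for i in rng.choice(len(tfs), size=2, replace=False))
        for rid, tf in ((ra, x), (rb, y)):
            start = int(rng.integers(cfg.region_length - cfg.motif_width + 1))
            seq = sequences[rid]
            sequences[rid] = seq[:start] + consensus[tf] + seq[start + cfg.motif_width :]
            planted[rid].append((tf, start))

    return SimMotifData(
        sequences=sequences,
        pwms=pwms,
        tfnet=tfnet,
        planted_sites=planted,
        region_pairs=region_pairs,
    )
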