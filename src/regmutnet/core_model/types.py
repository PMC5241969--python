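"""Domain types shared across the analysis modules.

Coordinate conventions
----------------------
* Mutations carry **1-based** genomic positions (``pos``) and 1-based
  amino-acid residue indices, matching the conventions of curated
  mutation tables.
* All genomic intervals are **0-based, half-open** internally.  A
  mutation at 1-based position ``p`` lies inside interval ``[s, e)``
  iff ``s <= p - 1 < e``.
* Chromosome names are normalized to a ``chr`` prefix at construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "normalize_chrom",
    "MutationClass",
    "Mutation",
    "InterfaceClass",
    "InterfaceMap",
    "TemplateCandidate",
    "GenomicInterval",
    "ChromatinNet",
    "ContactMatrix",
    "TFNetwork",
    "PWM",
    "MotifHit",
    "EnrichmentResult",
]

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}


def normalize_chrom(name: str) -> str:
    """Normalize a chromosome name to the ``chr``-prefixed form."""
    name = name.strip()
    if not name:
        raise ValueError("empty chromosome name")
    if not name.startswith("chr"):
        name = "chr" + name
    return name


class MutationClass(str, Enum):
    CODING_MISSENSE = "coding_missense"
    NON_CODING = "non_coding"


@dataclass(frozen=True)
class Mutation:
    """A single disease-associated variant.

    ``pos`` is the 1-based genomic position.  Coding missense mutations
    must carry a ``protein`` identifier and a 1-based ``residue`` index.
    ``diseases`` may be empty; such mutations are excluded from
    concordance analyses.
    """

    id: str
    chrom: str
    pos: int
    mclass: MutationClass
    ref: Optional[str] = None
    alt: Optional[str] = None
    protein: Optional[str] = None
    residue: Optional[int] = None
    diseases: FrozenSet[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        object.__setattr__(self, "mclass", MutationClass(self.mclass))
        object.__setattr__(self, "diseases", frozenset(self.diseases))
        if self.pos < 1:
            raise ValueError(f"mutation {self.id!r}: pos must be >= 1, got {self.pos}")
        if self.mclass is MutationClass.CODING_MISSENSE:
            if self.protein is None or self.residue is None:
                raise ValueError(
                    f"mutation {self.id!r}: coding_missense requires protein and residue"
                )
            if self.residue < 1:
                raise ValueError(f"mutation {self.id!r}: residue must be >= 1")

    def shares_disease(self, other: "Mutation") -> bool:
        """Two mutations cause the same disease iff their ID sets intersect."""
        return bool(self.diseases & other.diseases)


class InterfaceClass(str, Enum):
    PROTEIN_BINDING = "protein_binding"
    DNA_BINDING = "dna_binding"
    DOUBLE = "double"
    NONE = "none"


#: numeric codes used in the per-residue class array
_CLASS_CODE = {
    InterfaceClass.NONE: 0,
    InterfaceClass.PROTEIN_BINDING: 1,
    InterfaceClass.DNA_BINDING: 2,
    InterfaceClass.DOUBLE: 3,
}
_CODE_CLASS = {v: k for k, v in _CLASS_CODE.items()}


class InterfaceMap:
    """Residue-interval interface annotation for one protein.

    Intervals are 1-based inclusive ``(start, end, class)``.  A residue
    annotated both ``protein_binding`` and ``dna_binding`` (by distinct
    intervals) is reassigned to ``double`` at construction time, so the
    three interface classes are mutually exclusive afterwards.
    """

    def __init__(
        self,
        protein: str,
        length: int,
        intervals: Sequence[Tuple[int, int, InterfaceClass]],
    ) -> None:
        if length < 1:
            raise ValueError(f"protein {protein!r}: length must be >= 1")
        self.protein = protein
        self.length = int(length)
        self.intervals: List[Tuple[int, int, InterfaceClass]] = []
        pb = np.zeros(length, dtype=bool)
        db = np.zeros(length, dtype=bool)
        dd = np.zeros(length, dtype=bool)
        for start, end, cls in intervals:
            cls = InterfaceClass(cls)
            if not (1 <= start <= end <= length):
                raise ValueError(
                    f"protein {protein!r}: interval ({start},{end}) outside [1,{length}]"
                )
            self.intervals.append((int(start), int(end), cls))
            sl = slice(start - 1, end)
            if cls is InterfaceClass.PROTEIN_BINDING:
                pb[sl] = True
            elif cls is InterfaceClass.DNA_BINDING:
                db[sl] = True
            elif cls is InterfaceClass.DOUBLE:
                dd[sl] = True
            else:
                raise ValueError(f"protein {protein!r}: class 'none' not allowed in intervals")
        codes = np.zeros(length, dtype=np.int8)
        codes[pb] = _CLASS_CODE[InterfaceClass.PROTEIN_BINDING]
        codes[db] = _CLASS_CODE[InterfaceClass.DNA_BINDING]
        codes[pb & db] = _CLASS_CODE[InterfaceClass.DOUBLE]
        codes[dd] = _CLASS_CODE[InterfaceClass.DOUBLE]
        self._codes = codes

    def residue_class(self, residue: int) -> InterfaceClass:
        """Interface class of a 1-based residue after the double-merge rule."""
        if not (1 <= residue <= self.length):
            raise ValueError(
                f"protein {self.protein!r}: residue {residue} outside [1,{self.length}]"
            )
        return _CODE_CLASS[int(self._codes[residue - 1])]

    def residue_counts(self) -> Dict[InterfaceClass, int]:
        """Number of residues per (mutually exclusive) class."""
        out = {}
        for cls, code in _CLASS_CODE.items():
            out[cls] = int(np.count_nonzero(self._codes == code))
        return out

    def has_raw_class(self, cls: InterfaceClass) -> bool:
        """Whether any interval was annotated with ``cls`` before merging.

        ``double`` intervals count as both protein- and DNA-binding.
        """
        for _, _, c in self.intervals:
            if c is cls or c is InterfaceClass.DOUBLE:
                return True
        return False

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, InterfaceMap)
            and self.protein == other.protein
            and self.length == other.length
            and sorted(self.intervals) == sorted(other.intervals)
        )

    def __repr__(self) -> str:
        return f"InterfaceMap({self.protein!r}, length={self.length}, {len(self.intervals)} intervals)"


@dataclass(frozen=True)
class TemplateCandidate:
    """Sequence identity/coverage of a putative structural template."""

    seqid1: float
    cov1: float
    seqid2: float
    cov2: float

    def __post_init__(self) -> None:
        for name in ("seqid1", "cov1", "seqid2", "cov2"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")

    @property
    def m(self) -> float:
        return self.seqid1 * self.cov1 + self.seqid2 * self.cov2


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def contains_pos(self, chrom: str, pos: int) -> bool:
        """Whether a 1-based position lies in this interval."""
        return normalize_chrom(chrom) == self.chrom and self.start <= pos - 1 < self.end


class ChromatinNet:
    """Intra-chromosomal chromatin interaction network.

    ``anchors`` maps anchor ID to interval; ``edges`` is a list of
    ``(anchor_id, target_interval)`` pairs.  Every edge must be
    intra-chromosomal.
    """

    def __init__(
        self,
        anchors: Mapping[str, GenomicInterval],
        edges: Iterable[Tuple[str, GenomicInterval]],
    ) -> None:
        self.anchors: Dict[str, GenomicInterval] = dict(anchors)
        self.edges: List[Tuple[str, GenomicInterval]] = []
        for aid, target in edges:
            if aid not in self.anchors:
                raise ValueError(f"edge references unknown anchor {aid!r}")
            if self.anchors[aid].chrom != target.chrom:
                raise ValueError(
                    f"edge {aid!r} -> {target} is not intra-chromosomal"
                )
            self.edges.append((aid, target))
        self._anchor_index: Optional[Dict[str, Tuple[np.ndarray, np.ndarray, List[str]]]] = None
        self._targets_by_anchor: Optional[Dict[str, List[GenomicInterval]]] = None

    def _build_anchor_index(self) -> Dict[str, Tuple[np.ndarray, np.ndarray, List[str]]]:
        if self._anchor_index is None:
            by_chrom: Dict[str, List[Tuple[int, int, str]]] = {}
            for aid, iv in self.anchors.items():
                by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, aid))
            index = {}
            for chrom, rows in by_chrom.items():
                rows.sort()
                starts = np.array([r[0] for r in rows], dtype=np.int64)
                ends = np.array([r[1] for r in rows], dtype=np.int64)
                ids = [r[2] for r in rows]
                index[chrom] = (starts, ends, ids)
            self._anchor_index = index
        return self._anchor_index

    def anchors_containing(self, chrom: str, pos: int) -> List[str]:
        """IDs of anchors containing the 1-based position (possibly several)."""
        chrom = normalize_chrom(chrom)
        index = self._build_anchor_index()
        if chrom not in index:
            return []
        starts, ends, ids = index[chrom]
        p = pos - 1
        hit = (starts <= p) & (p < ends)
        return [ids[i] for i in np.nonzero(hit)[0]]

    def targets_of(self, anchor_id: str) -> List[GenomicInterval]:
        if self._targets_by_anchor is None:
            t: Dict[str, List[GenomicInterval]] = {}
            for aid, target in self.edges:
                t.setdefault(aid, []).append(target)
            self._targets_by_anchor = t
        return self._targets_by_anchor.get(anchor_id, [])

    def anchor_degrees(self) -> Dict[str, int]:
        deg: Dict[str, int] = {aid: 0 for aid in self.anchors}
        for aid, _ in self.edges:
            deg[aid] += 1
        return deg

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, ChromatinNet)
            and self.anchors == other.anchors
            and sorted(self.edges) == sorted(other.edges)
        )


VALID_RESOLUTIONS = (5000, 10000, 25000, 50000)


class ContactMatrix:
    """Sparse intra-chromosomal raw contact counts plus a normalization vector.

    ``entries`` maps bin pairs to raw counts; access is symmetric.  Bin
    indices are ``floor(pos / resolution)`` of 0-based positions.
    """

    def __init__(
        self,
        chrom: str,
        resolution: int,
        entries: Mapping[Tuple[int, int], float],
        normvec: Sequence[float],
    ) -> None:
        if resolution not in VALID_RESOLUTIONS:
            raise ValueError(
                f"resolution {resolution} not in {VALID_RESOLUTIONS}"
            )
        self.chrom = normalize_chrom(chrom)
        self.resolution = int(resolution)
        self.entries: Dict[Tuple[int, int], float] = {}
        for (i, j), v in entries.items():
            if i < 0 or j < 0:
                raise ValueError(f"negative bin index ({i},{j})")
            key = (i, j) if i <= j else (j, i)
            self.entries[key] = self.entries.get(key, 0.0) + float(v)
        self.normvec = np.asarray(normvec, dtype=float)

    def bin_of(self, pos: int) -> int:
        """Bin index of a 1-based genomic position."""
        if pos < 1:
            raise ValueError(f"pos must be >= 1, got {pos}")
        return (pos - 1) // self.resolution

    def raw(self, i: int, j: int) -> float:
        key = (i, j) if i <= j else (j, i)
        return self.entries.get(key, 0.0)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, ContactMatrix)
            and self.chrom == other.chrom
            and self.resolution == other.resolution
            and self.entries == other.entries
            and np.array_equal(self.normvec, other.normvec)
        )


class TFNetwork:
    """Undirected TF-TF interaction network; self-edges model homodimers."""

    def __init__(self, nodes: Iterable[str], edges: Iterable[Tuple[str, str]]) -> None:
        self.nodes = set(nodes)
        self.edges = set()
        for a, b in edges:
            if a not in self.nodes or b not in self.nodes:
                raise ValueError(f"edge ({a!r}, {b!r}) has endpoint outside node set")
            self.edges.add(self._key(a, b))

    @staticmethod
    def _key(a: str, b: str) -> Tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def has_edge(self, a: str, b: str) -> bool:
        return self._key(a, b) in self.edges

    def degrees(self) -> Dict[str, int]:
        deg = {n: 0 for n in self.nodes}
        for a, b in self.edges:
            deg[a] += 1
            if b != a:
                deg[b] += 1
        return deg

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, TFNetwork)
            and self.nodes == other.nodes
            and self.edges == other.edges
        )


class PWM:
    """Position probability matrix with background base frequencies."""

    def __init__(
        self,
        tf: str,
        matrix: Sequence[Sequence[float]],
        background: Optional[Sequence[float]] = None,
    ) -> None:
        self.tf = tf
        self.matrix = np.asarray(matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError(f"PWM {tf!r}: matrix must be (width, 4)")
        if np.any(self.matrix < 0):
            raise ValueError(f"PWM {tf!r}: negative probabilities")
        row_sums = self.matrix.sum(axis=1)
        if np.any(np.abs(row_sums - 1.0) > 1e-9):
            raise ValueError(f"PWM {tf!r}: rows must each sum to 1")
        if background is None:
            background = np.full(4, 0.25)
        self.background = np.asarray(background, dtype=float)
        if self.background.shape != (4,) or abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError(f"PWM {tf!r}: background must be 4 probabilities summing to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(self.tf, self.matrix[::-1, ::-1], self.background[::-1])

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, PWM)
            and self.tf == other.tf
            and np.allclose(self.matrix, other.matrix, atol=1e-12)
            and np.allclose(self.background, other.background, atol=1e-12)
        )


@dataclass(frozen=True)
class MotifHit:
    """A PWM match: TF, location, strand and log-likelihood-ratio score."""

    tf: str
    interval: GenomicInterval
    strand: str
    score: float

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def site_key(self) -> Tuple[str, str, int, int, str]:
        """Identity of the binding site (TF + exact location + strand)."""
        return (self.tf, self.interval.chrom, self.interval.start, self.interval.end, self.strand)


@dataclass(frozen=True)
class EnrichmentResult:
    """Point estimate with log-scale standard error, Z and two-sided p.

    ``se_log``, ``z`` and ``p`` are ``None`` when undefined (e.g. zero
    counts in the numerator).
    """

    estimate: float
    se_log: Optional[float]
    z: Optional[float]
    p: Optional[float]

    def __post_init__(self) -> None:
        if self.p is not None and not (0.0 < self.p <= 1.0):
            raise ValueError(f"p={self.p} outside (0, 1]")
        if self.se_log is not None and self.z is not None and self.se_log > 0:
            expect = math.log(self.estimate) / self.se_log
            if not math.isclose(expect, self.z, rel_tol=1e-9, abs_tol=1e-9):
                raise ValueError("z inconsistent with ln(estimate)/se_log")
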