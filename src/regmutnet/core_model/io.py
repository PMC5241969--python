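"""Readers and writers for the plain-text exchange formats.

All tabular formats are TSV.  Mutation tables and interface tables carry
a header line; BED files, TF-network edge lists, contact triples and
normalization vectors are headerless.  Positions in mutation files are
1-based; BED and edge intervals are 0-based half-open.
"""

from __future__ import annotations

import csv
import logging
import re
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .types import (
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
    normalize_chrom,
)

logger = logging.getLogger(__name__)

MUTATION_COLUMNS = [
    "id", "chrom", "pos", "ref", "alt", "mclass", "protein", "residue", "diseases",
]

_CHROM_RE = re.compile(r"^chr[A-Za-z0-9_.]+$")


def _valid_chrom(name: str) -> bool:
    return bool(_CHROM_RE.match(normalize_chrom(name)))


# ---------------------------------------------------------------------------
# mutations
# ---------------------------------------------------------------------------

def read_mutations(path, dialect: str = "tsv") -> List[Mutation]:
    """Read mutations from TSV or minimal VCF.

    Rows with unrecognisable chromosome names are skipped with a logged
    count; any other malformed row raises ``ValueError`` naming the line.
    Duplicate mutation IDs are rejected.
    """
    if dialect == "tsv":
        muts = _read_mutations_tsv(path)
    elif dialect == "vcf_minimal":
        muts = _read_mutations_vcf(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; use 'tsv' or 'vcf_minimal'")
    seen = set()
    for m in muts:
        if m.id in seen:
            raise ValueError(f"{path}: duplicate mutation ID {m.id!r}")
        seen.add(m.id)
    return muts


def _read_mutations_tsv(path) -> List[Mutation]:
    muts: List[Mutation] = []
    skipped = 0
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file; header required") from None
        if header != MUTATION_COLUMNS:
            raise ValueError(
                f"{path}: bad header {header}; expected {MUTATION_COLUMNS}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(MUTATION_COLUMNS):
                raise ValueError(f"{path}:{lineno}: expected {len(MUTATION_COLUMNS)} columns, got {len(row)}")
            rec = dict(zip(MUTATION_COLUMNS, row))
            if not _valid_chrom(rec["chrom"]):
                skipped += 1
                continue
            try:
                muts.append(
                    Mutation(
                        id=rec["id"],
                        chrom=rec["chrom"],
                        pos=int(rec["pos"]),
                        mclass=MutationClass(rec["mclass"]),
                        ref=rec["ref"] or None,
                        alt=rec["alt"] or None,
                        protein=rec["protein"] or None,
                        residue=int(rec["residue"]) if rec["residue"] else None,
                        diseases=frozenset(d for d in rec["diseases"].split(";") if d),
                    )
                )
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    if skipped:
        logger.warning("%s: skipped %d rows with unknown chromosome names", path, skipped)
    return muts


def _read_mutations_vcf(path) -> List[Mutation]:
    muts: List[Mutation] = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise ValueError(f"{path}:{lineno}: expected >= 8 VCF columns, got {len(fields)}")
            chrom, pos, vid, ref, alt = fields[0], fields[1], fields[2], fields[3], fields[4]
            info = fields[7]
            if not _valid_chrom(chrom):
                skipped += 1
                continue
            kv: Dict[str, str] = {}
            for item in info.split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    kv[k] = v
            try:
                muts.append(
                    Mutation(
                        id=vid,
                        chrom=chrom,
                        pos=int(pos),
                        mclass=MutationClass(kv.get("MCLASS", "non_coding")),
                        ref=None if ref in (".", "") else ref,
                        alt=None if alt in (".", "") else alt,
                        protein=kv.get("PROT") or None,
                        residue=int(kv["RES"]) if kv.get("RES") else None,
                        diseases=frozenset(d for d in kv.get("DIS", "").split(",") if d),
                    )
                )
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    if skipped:
        logger.warning("%s: skipped %d VCF records with unknown chromosome names", path, skipped)
    return muts


def write_mutations(muts: Iterable[Mutation], path, dialect: str = "tsv") -> None:
    if dialect == "tsv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(MUTATION_COLUMNS)
            for m in muts:
                w.writerow([
                    m.id, m.chrom, m.pos, m.ref or "", m.alt or "", m.mclass.value,
                    m.protein or "", m.residue if m.residue is not None else "",
                    ";".join(sorted(m.diseases)),
                ])
    elif dialect == "vcf_minimal":
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for m in muts:
                info = [f"MCLASS={m.mclass.value}"]
                if m.protein:
                    info.append(f"PROT={m.protein}")
                if m.residue is not None:
                    info.append(f"RES={m.residue}")
                if m.diseases:
                    info.append("DIS=" + ",".join(sorted(m.diseases)))
                fh.write(
                    f"{m.chrom}\t{m.pos}\t{m.id}\t{m.ref or '.'}\t{m.alt or '.'}"
                    f"\t.\t.\t{';'.join(info)}\n"
                )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# interface maps
# ---------------------------------------------------------------------------

def read_interface_maps(path) -> Dict[str, InterfaceMap]:
    """Read per-protein interface annotations.

    Columns: protein, length, start, end, class (1-based inclusive
    residue intervals).
    """
    rows: Dict[str, Tuple[int, List[Tuple[int, int, InterfaceClass]]]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != ["protein", "length", "start", "end", "class"]:
            raise ValueError(f"{path}: bad header {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                protein, length, start, end, cls = row
                length, start, end = int(length), int(start), int(end)
                cls = InterfaceClass(cls)
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            if protein in rows and rows[protein][0] != length:
                raise ValueError(f"{path}:{lineno}: inconsistent length for {protein!r}")
            rows.setdefault(protein, (length, []))[1].append((start, end, cls))
    return {
        protein: InterfaceMap(protein, length, intervals)
        for protein, (length, intervals) in rows.items()
    }


def write_interface_maps(imaps: Mapping[str, InterfaceMap], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["protein", "length", "start", "end", "class"])
        for protein in sorted(imaps):
            im = imaps[protein]
            for start, end, cls in im.intervals:
                w.writerow([protein, im.length, start, end, cls.value])


# ---------------------------------------------------------------------------
# chromatin interaction network
# ---------------------------------------------------------------------------

def read_chromatin_net(anchors_bed, edges_tsv) -> ChromatinNet:
    """Read anchors (BED with name column) plus anchor->target edges."""
    anchors: Dict[str, GenomicInterval] = {}
    with open(anchors_bed) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{anchors_bed}:{lineno}: BED needs chrom,start,end,name")
            chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            if name in anchors:
                raise ValueError(f"{anchors_bed}:{lineno}: duplicate anchor ID {name!r}")
            anchors[name] = GenomicInterval(chrom, start, end)
    edges: List[Tuple[str, GenomicInterval]] = []
    with open(edges_tsv, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != ["anchor_id", "chrom", "start", "end"]:
            raise ValueError(f"{edges_tsv}: bad header {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            aid, chrom, start, end = row[0], row[1], int(row[2]), int(row[3])
            edges.append((aid, GenomicInterval(chrom, start, end)))
    return ChromatinNet(anchors, edges)


def write_chromatin_net(net: ChromatinNet, anchors_bed, edges_tsv) -> None:
    with open(anchors_bed, "w") as fh:
        for name in sorted(net.anchors):
            iv = net.anchors[name]
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")
    with open(edges_tsv, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["anchor_id", "chrom", "start", "end"])
        for aid, t in net.edges:
            w.writerow([aid, t.chrom, t.start, t.end])


# ---------------------------------------------------------------------------
# contact matrices
# ---------------------------------------------------------------------------

def read_contact_matrix(triples_path, normvec_path, chrom: str, resolution: int) -> ContactMatrix:
    """Read a sparse raw matrix (bp triples) and a one-column norm vector.

    Triple rows are ``bin_i_start_bp  bin_j_start_bp  raw_count`` with
    starts that must be multiples of the resolution.
    """
    entries: Dict[Tuple[int, int], float] = {}
    data = np.loadtxt(triples_path, dtype=float, ndmin=2)
    if data.size:
        if data.shape[1] != 3:
            raise ValueError(f"{triples_path}: expected 3 columns")
        for bi_bp, bj_bp, count in data:
            if bi_bp % resolution or bj_bp % resolution:
                raise ValueError(
                    f"{triples_path}: bin start {bi_bp:.0f}/{bj_bp:.0f} not a multiple of {resolution}"
                )
            i, j = int(bi_bp) // resolution, int(bj_bp) // resolution
            key = (i, j) if i <= j else (j, i)
            entries[key] = entries.get(key, 0.0) + float(count)
    normvec = np.loadtxt(normvec_path, dtype=float, ndmin=1)
    return ContactMatrix(chrom, resolution, entries, normvec)


def write_contact_matrix(cm: ContactMatrix, triples_path, normvec_path) -> None:
    with open(triples_path, "w") as fh:
        for (i, j) in sorted(cm.entries):
            fh.write(f"{i * cm.resolution}\t{j * cm.resolution}\t{cm.entries[(i, j)]:g}\n")
    with open(normvec_path, "w") as fh:
        for v in cm.normvec:
            fh.write(f"{v:.10g}\n")


# ---------------------------------------------------------------------------
# TF network
# ---------------------------------------------------------------------------

def read_tf_network(path) -> TFNetwork:
    """Read a headerless 2-column TSV edge list; nodes are edge endpoints."""
    edges: List[Tuple[str, str]] = []
    nodes = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            a, b = fields
            nodes.update((a, b))
            edges.append((a, b))
    return TFNetwork(nodes, edges)


def write_tf_network(net: TFNetwork, path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(net.edges):
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# PWMs
# ---------------------------------------------------------------------------

def read_pfm(path, pseudocount: float = 0.0) -> List[PWM]:
    """Read simple PFM records: ``>name`` then 4 rows A/C/G/T.

    Rows may hold counts or probabilities; columns are normalized to
    probabilities (with ``pseudocount`` added per cell first).
    """
    pwms: List[PWM] = []
    name: Optional[str] = None
    rows: Dict[str, List[float]] = {}

    def _flush() -> None:
        if name is None:
            return
        if set(rows) != set(BASES):
            raise ValueError(f"{path}: record {name!r} missing base rows")
        mat = np.array([rows[b] for b in BASES], dtype=float).T + pseudocount
        sums = mat.sum(axis=1, keepdims=True)
        if np.any(sums <= 0):
            raise ValueError(f"{path}: record {name!r} has a zero column")
        pwms.append(PWM(name, mat / sums))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                name = line[1:].strip()
                rows = {}
            else:
                fields = line.replace(":", " ").split()
                base = fields[0].upper()
                if base not in BASE_SET:
                    raise ValueError(f"{path}: unexpected PFM row {line!r}")
                rows[base] = [float(x) for x in fields[1:]]
    _flush()
    return pwms


BASE_SET = set(BASES)


def write_pfm(pwms: Sequence[PWM], path) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.tf}\n")
            for bi, base in enumerate(BASES):
                vals = " ".join(f"{v:.6f}" for v in pwm.matrix[:, bi])
                fh.write(f"{base} {vals}\n")


def read_meme(path) -> List[PWM]:
    """Read MEME minimal-format motifs (letter-probability matrices)."""
    pwms: List[PWM] = []
    background = np.full(4, 0.25)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            i += 1
            fields = lines[i].split()
            freq = {fields[k]: float(fields[k + 1]) for k in range(0, len(fields), 2)}
            background = np.array([freq.get(b, 0.25) for b in BASES])
        elif line.startswith("MOTIF"):
            name = line.split()[1]
            i += 1
            while i < len(lines) and not lines[i].strip().startswith("letter-probability matrix"):
                i += 1
            if i >= len(lines):
                raise ValueError(f"{path}: motif {name!r} has no probability matrix")
            m = re.search(r"w=\s*(\d+)", lines[i])
            if m is None:
                raise ValueError(f"{path}: motif {name!r}: cannot parse matrix width")
            width = int(m.group(1))
            mat = []
            for _ in range(width):
                i += 1
                mat.append([float(x) for x in lines[i].split()])
            pwms.append(PWM(name, np.array(mat), background))
        i += 1
    return pwms


def write_meme(pwms: Sequence[PWM], path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        if pwms:
            bg = pwms[0].background
            fh.write("Background letter frequencies\n")
            fh.write(" ".join(f"{b} {v:.6f}" for b, v in zip(BASES, bg)) + "\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.tf}\n")
            fh.write(
                f"letter-probability matrix: alphabet= ACGT w= {pwm.width} nsites= 20 E= 0\n"
            )
            for row in pwm.matrix:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(seqs: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> Dict[str, str]:
    """In-memory FASTA reader (sequences used here are small)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
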