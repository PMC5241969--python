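from __future__ import annotations

import pytest

from regmutnet.core_model.types import (
    ChromatinNet,
    GenomicInterval,
    InterfaceClass,
    InterfaceMap,
    Mutation,
    MutationClass,
    TFNetwork,
)


@pytest.fixture
def toy_tfnet() -> TFNetwork:
    return TFNetwork({"A", "B", "C"}, [("A", "B")])


@pytest.fixture
def toy_chromnet() -> ChromatinNet:
    anchors = {
        "a1": GenomicInterval("chr1", 1000, 5000),
        "a2": GenomicInterval("chr1", 0, 1000),
    }
    edges = [
        ("a2", GenomicInterval("chr1", 29_000, 31_000)),
        ("a1", GenomicInterval("chr1", 200_000, 210_000)),
    ]
    return ChromatinNet(anchors, edges)


def make_mut(
    mid: str,
    chrom: str = "chr1",
    pos: int = 1,
    mclass: str = "non_coding",
    protein: str | None = None,
    residue: int | None = None,
    diseases=(),
) -> Mutation:
    return Mutation(
        id=mid,
        chrom=chrom,
        pos=pos,
        mclass=MutationClass(mclass),
        protein=protein,
        residue=residue,
        diseases=frozenset(diseases),
    )
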