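import random

import numpy as np
import pytest

from hsrcnv.core import DEFAULT_SCHEME, ReadRecord


def random_dna(rng, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


@pytest.fixture
def rng():
    return random.Random(20240901)


@pytest.fixture
def np_rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def scheme():
    return DEFAULT_SCHEME


def make_read(
    name="r1",
    chrom="chr1",
    pos=1000,
    cigar=((("M", 150)),),
    seq=None,
    **kwargs,
):
    cigar = [tuple(c) for c in cigar]
    if seq is None:
        qlen = sum(n for op, n in cigar if op in "MIS=X")
        seq = "A" * qlen
    return ReadRecord(name=name, chrom=chrom, pos=pos, cigar=cigar, seq=seq, **kwargs)


def biopython_local_score(query: str, target: str) -> int:
    """Independent affine-gap local alignment oracle (N never matches)."""
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    m = substitution_matrices.Array("ACGTN", dims=2)
    for a in "ACGTN":
        for b in "ACGTN":
            m[a, b] = 1.0 if (a == b and a != "N") else -4.0
    aligner.substitution_matrix = m
    aligner.open_gap_score = -7  # first gap base: open + extend
    aligner.extend_gap_score = -1
    return int(aligner.score(target, query))
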