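"""Shared domain types, library-statistics estimation and difference counting.

Coordinates are 0-based half-open everywhere inside the package; conversion
to 1-based happens only at the VCF boundary.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np

# CIGAR operations that consume the query / the reference.
_QUERY_OPS = set("MIS=X")
_REF_OPS = set("MDN=X")

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class LibraryStatsError(ValueError):
    """Raised when the insert-size distribution cannot be estimated."""


@dataclass(frozen=True)
class GenomeInterval:
    """A 0-based half-open interval on a chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomeInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class AlignmentScheme:
    """Affine-gap scoring. The first base of a gap costs gap_open + gap_extend."""

    match: int = 1
    mismatch: int = -4
    gap_open: int = -6
    gap_extend: int = -1

    def __post_init__(self) -> None:
        if self.match <= 0 or self.mismatch >= 0 or self.gap_extend >= 0:
            raise ValueError("need match > 0, mismatch < 0, gap_extend < 0")
        if self.gap_open > 0:
            raise ValueError("gap_open must be <= 0")


#: one scheme is used for every alignment in the package so that HSR scores,
#: junction scores and expected-support comparisons stay on a common scale
DEFAULT_SCHEME = AlignmentScheme(1, -4, -6, -1)


@dataclass(frozen=True)
class LibraryStats:
    """Insert-size distribution of the sequencing library.

    max_is = mu + 3 sigma is the discordance threshold for deletion-type
    pairs.
    """

    read_len: int
    mu: float
    sigma: float
    n_sampled: int

    @property
    def max_is(self) -> float:
        return self.mu + 3.0 * self.sigma


@dataclass
class ReadRecord:
    """A minimal aligned-read record decoupled from the BAM layer.

    ``cigar`` is a list of (op, length) with op in M=XIDSH. ``insert_size``
    follows the SAM TLEN sign convention.
    """

    name: str
    chrom: str
    pos: int
    cigar: list[tuple[str, int]]
    seq: str
    mapq: int = 60
    is_reverse: bool = False
    is_paired: bool = True
    is_proper: bool = True
    mate_chrom: str | None = None
    mate_pos: int | None = None
    mate_is_reverse: bool | None = None
    insert_size: int = 0
    is_secondary: bool = False
    is_supplementary: bool = False
    is_duplicate: bool = False
    nm: int | None = None

    def __post_init__(self) -> None:
        qlen = sum(n for op, n in self.cigar if op in _QUERY_OPS and op != "H")
        if self.seq and qlen != len(self.seq):
            raise ValueError(
                f"{self.name}: cigar consumes {qlen} query bases, seq has {len(self.seq)}"
            )

    @property
    def reference_end(self) -> int:
        return self.pos + sum(n for op, n in self.cigar if op in _REF_OPS)

    @property
    def left_clip(self) -> int:
        return self.cigar[0][1] if self.cigar and self.cigar[0][0] in "SH" else 0

    @property
    def right_clip(self) -> int:
        return self.cigar[-1][1] if self.cigar and self.cigar[-1][0] in "SH" else 0

    @classmethod
    def from_pysam(cls, seg) -> "ReadRecord":
        nm = seg.get_tag("NM") if seg.has_tag("NM") else None
        return cls(
            name=seg.query_name,
            chrom=seg.reference_name,
            pos=seg.reference_start,
            cigar=[("MIDNSHP=X"[op], ln) for op, ln in (seg.cigartuples or [])],
            seq=seg.query_sequence or "",
            mapq=seg.mapping_quality,
            is_reverse=seg.is_reverse,
            is_paired=seg.is_paired,
            is_proper=seg.is_proper_pair,
            mate_chrom=seg.next_reference_name if seg.is_paired and not seg.mate_is_unmapped else None,
            mate_pos=seg.next_reference_start if seg.is_paired and not seg.mate_is_unmapped else None,
            mate_is_reverse=seg.mate_is_reverse if seg.is_paired else None,
            insert_size=seg.template_length,
            is_secondary=seg.is_secondary,
            is_supplementary=seg.is_supplementary,
            is_duplicate=seg.is_duplicate,
            nm=nm,
        )


@dataclass(frozen=True)
class LocalAlignmentResult:
    """Span and score of a local alignment; empty alignments have score 0."""

    score: int
    query_start: int
    query_end: int
    ref_start: int
    ref_end: int
    cigar: tuple[tuple[str, int], ...] = ()


def _usable_for_stats(rec: ReadRecord) -> bool:
    if rec.is_secondary or rec.is_supplementary or rec.is_duplicate:
        return False
    if not rec.is_paired or rec.mate_chrom is None:
        return False
    if rec.mate_chrom != rec.chrom:
        return False
    # count each pair once via the leftmost (positive-TLEN) forward read
    return (not rec.is_reverse) and rec.insert_size > 0


def estimate_library_stats(
    records: Iterable[ReadRecord], sample_size: int = 100_000
) -> LibraryStats:
    """Estimate read length and insert-size mean/sd from concordant pairs.

    Uses the absolute template length of the first ``sample_size``
    forward-reverse same-chromosome pairs. Raises LibraryStatsError when
    fewer than 1000 usable pairs are available.
    """

    inserts: list[int] = []
    read_lens: Counter[int] = Counter()
    for rec in records:
        if rec.seq:
            read_lens[len(rec.seq)] += 1
        if _usable_for_stats(rec):
            inserts.append(abs(rec.insert_size))
            if len(inserts) >= sample_size:
                break
    if len(inserts) < 1000:
        raise LibraryStatsError(
            f"only {len(inserts)} usable pairs; need at least 1000 to estimate "
            "the insert-size distribution"
        )
    arr = np.asarray(sorted(inserts), dtype=float)  # sort: order invariance
    # pairs straddling large deletions inflate the tail; a generous cap at
    # twice the median removes them without touching the bulk
    arr = arr[arr <= 2.0 * np.median(arr)]
    mu = float(arr.mean())
    sigma = float(arr.std(ddof=0))
    read_len = read_lens.most_common(1)[0][0]
    return LibraryStats(read_len=read_len, mu=mu, sigma=sigma, n_sampled=len(arr))


def count_differences(rec: ReadRecord, ref_fetch: Callable[[str, int, int], str]) -> int:
    """Mismatched aligned bases plus the number of indel events.

    An indel of any length counts as a single difference. Soft/hard clipped
    bases are ignored.
    """

    ref = ref_fetch(rec.chrom, rec.pos, rec.reference_end).upper()
    qi = 0
    ri = 0
    diffs = 0
    for op, n in rec.cigar:
        if op in "M=X":
            if qi + n > len(rec.seq) or ri + n > len(ref):
                raise ValueError(f"{rec.name}: cigar inconsistent with reference window")
            for k in range(n):
                if rec.seq[qi + k].upper() != ref[ri + k]:
                    diffs += 1
            qi += n
            ri += n
        elif op == "I":
            diffs += 1
            qi += n
        elif op in "DN":
            diffs += 1
            ri += n
        elif op == "S":
            qi += n
        elif op == "H":
            pass
        else:
            raise ValueError(f"unsupported cigar op {op}")
    return diffs
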