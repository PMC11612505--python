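"""Read and pair classification: split reads, hidden split reads, discordant pairs.

A read is a *hidden split read* (HSR) if splitting it into two halves that
align independently would strictly increase its alignment score; the gain is
the HSR score. Candidate HSRs are unclipped reads with at least three
differences (mismatches plus indel events) from the reference. A pair is
deletion-discordant when its insert size exceeds mu + 3 sigma, and
duplication-discordant when the forward-facing read maps downstream of the
reverse-facing one (outward orientation).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .align import local_align, local_score, split_totals
from .core import (
    DEFAULT_SCHEME,
    AlignmentScheme,
    LibraryStats,
    ReadRecord,
    count_differences,
)

#: clips shorter than this are treated as adapter/quality noise, not evidence
MIN_CLIP = 5

#: minimum differences from the reference for a candidate ("strong") HSR
MIN_HSR_DIFFERENCES = 3

#: minimum HSR score for a split to be emitted; two avoided mismatches'
#: worth under the default scheme. Raw HSR realignment is mostly noise, so a
#: positive margin over the linear alignment is required.
MIN_HSR_SCORE = 8


class EvidenceClass(enum.Enum):
    SPLIT_LEFT_CLIP = "SPLIT_LEFT_CLIP"
    SPLIT_RIGHT_CLIP = "SPLIT_RIGHT_CLIP"
    HSR_CANDIDATE = "HSR_CANDIDATE"
    DISCORDANT_DEL = "DISCORDANT_DEL"
    DISCORDANT_DUP = "DISCORDANT_DUP"
    CONCORDANT = "CONCORDANT"
    NEUTRAL = "NEUTRAL"


class Side(enum.Enum):
    LEFT_CLIP = "LEFT_CLIP"
    RIGHT_CLIP = "RIGHT_CLIP"


@dataclass(frozen=True)
class HsrSplit:
    """A read's optimal free-split realignment."""

    read_name: str
    split_index: int
    virtual_side: Side
    virtual_breakpoint: int
    hsr_score: int


@dataclass(frozen=True)
class DiscordantPair:
    """A discordant pair reduced to its two clustering anchors.

    For deletion-type pairs ``left_anchor`` is the forward read's end and
    ``right_anchor`` the reverse read's start. For duplication-type (outward)
    pairs ``left_anchor`` is the upstream reverse read's start and
    ``right_anchor`` the downstream forward read's end, so that the event
    interval is bracketed by the anchors in both cases.
    """

    chrom: str
    kind: str  # "DEL" or "DUP"
    left_anchor: int
    right_anchor: int
    insert_size: int
    span: int = 0  # DUP only: fwd start - rev end (outward gap)


def clip_side(rec: ReadRecord) -> Side | None:
    """Side of the dominant soft/hard clip (>= MIN_CLIP bp), if any."""
    lc, rc = rec.left_clip, rec.right_clip
    if lc < MIN_CLIP and rc < MIN_CLIP:
        return None
    return Side.LEFT_CLIP if lc >= rc else Side.RIGHT_CLIP


def is_clipped(rec: ReadRecord) -> bool:
    return clip_side(rec) is not None


def classify_pair(r1: ReadRecord, r2: ReadRecord, stats: LibraryStats) -> set[EvidenceClass]:
    """Pair-level classification plus per-read clip classes."""
    classes: set[EvidenceClass] = set()
    for rec in (r1, r2):
        side = clip_side(rec)
        if side is Side.LEFT_CLIP:
            classes.add(EvidenceClass.SPLIT_LEFT_CLIP)
        elif side is Side.RIGHT_CLIP:
            classes.add(EvidenceClass.SPLIT_RIGHT_CLIP)
    if r1.chrom is None or r2.chrom is None or r1.chrom != r2.chrom:
        classes.add(EvidenceClass.NEUTRAL)
        return classes
    if r1.is_reverse == r2.is_reverse:
        classes.add(EvidenceClass.NEUTRAL)
        return classes
    fwd, rev = (r2, r1) if r1.is_reverse else (r1, r2)
    if fwd.pos > rev.pos:
        classes.add(EvidenceClass.DISCORDANT_DUP)
    elif abs(r1.insert_size) > stats.max_is:
        classes.add(EvidenceClass.DISCORDANT_DEL)
    else:
        classes.add(EvidenceClass.CONCORDANT)
    return classes


def pair_to_discordant(
    r1: ReadRecord, r2: ReadRecord, stats: LibraryStats
) -> DiscordantPair | None:
    """Build the clustering record for a discordant pair, if it is one."""
    classes = classify_pair(r1, r2, stats)
    fwd, rev = (r2, r1) if r1.is_reverse else (r1, r2)
    if EvidenceClass.DISCORDANT_DUP in classes:
        return DiscordantPair(
            chrom=r1.chrom,
            kind="DUP",
            left_anchor=rev.pos,
            right_anchor=fwd.reference_end,
            insert_size=abs(r1.insert_size),
            span=fwd.pos - rev.reference_end,
        )
    if EvidenceClass.DISCORDANT_DEL in classes:
        return DiscordantPair(
            chrom=r1.chrom,
            kind="DEL",
            left_anchor=fwd.reference_end,
            right_anchor=rev.pos,
            insert_size=abs(r1.insert_size),
        )
    return None


def is_candidate_hsr(rec: ReadRecord, ref_fetch: Callable[[str, int, int], str]) -> bool:
    """Unclipped and at least MIN_HSR_DIFFERENCES differences from the reference."""
    if is_clipped(rec):
        return False
    return count_differences(rec, ref_fetch) >= MIN_HSR_DIFFERENCES


def compute_hsr_split(
    rec: ReadRecord,
    window_seq: str,
    window_start: int,
    scheme: AlignmentScheme = DEFAULT_SCHEME,
    min_score: int = MIN_HSR_SCORE,
) -> HsrSplit | None:
    """Optimal free split of a candidate HSR against a reference window.

    The split index maximises score(r[:i]) + score(r[i:]) where each half is
    locally aligned to the window independently; the HSR score is that
    maximum minus the score of the unsplit read. Returns None when the gain
    is below ``min_score``. The virtual clip side is the side of the
    non-anchored half, and the virtual breakpoint mirrors a real clip
    position: the reference end of an anchored prefix (right clip) or the
    reference start of an anchored suffix (left clip).
    """
    n = len(rec.seq)
    if len(window_seq) < n:
        raise ValueError("reference window shorter than the read")
    totals = split_totals(rec.seq, window_seq, scheme)
    full = int(totals[0])  # T[0] = 0 + score(whole read)
    # splits at i in 1..n-1
    inner = totals[1:n]
    best_i = int(np.argmax(inner)) + 1
    hsr_score = int(inner[best_i - 1]) - full
    if hsr_score < min_score:
        return None
    left = local_align(rec.seq[:best_i], window_seq, scheme)
    right = local_align(rec.seq[best_i:], window_seq, scheme)
    if left.score <= 0 or right.score <= 0:
        return None
    # the anchored half is the one that stays nearest the original placement
    d_left = abs(window_start + left.ref_start - rec.pos)
    d_right = abs(window_start + right.ref_end - rec.reference_end)
    if d_left <= d_right:
        side = Side.RIGHT_CLIP
        breakpoint = window_start + left.ref_end
    else:
        side = Side.LEFT_CLIP
        breakpoint = window_start + right.ref_start
    return HsrSplit(
        read_name=rec.name,
        split_index=best_i,
        virtual_side=side,
        virtual_breakpoint=breakpoint,
        hsr_score=hsr_score,
    )


def full_read_score(rec: ReadRecord, window_seq: str, scheme: AlignmentScheme = DEFAULT_SCHEME) -> int:
    return local_score(rec.seq, window_seq, scheme)
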