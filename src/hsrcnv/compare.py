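"""Repeat-aware CNV comparison, duplication-vs-insertion matching, clustering.

Two same-type events match when their start and end coordinates are close,
the shorter overlaps the longer sufficiently, and their lengths are similar
(precise thresholds 100 bp / 0.8 / 100 bp; imprecise 500 bp / 0.5 / 500 bp).
Inside a shared tandem repeat the same physical event can be reported at any
copy, so only the length criterion applies there. A duplication matches an
insertion record when the inserted sequence aligns over at least 80% of its
length to the duplicated sequence concatenated ceil(i/d) times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from statistics import median_low
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .align import local_align
from .core import DEFAULT_SCHEME, AlignmentScheme, GenomeInterval


@dataclass(frozen=True)
class MatchParams:
    max_distance: int
    min_overlap: float
    max_len_diff: int


PRECISE = MatchParams(100, 0.8, 100)
IMPRECISE = MatchParams(500, 0.5, 500)

#: tolerance, in repeat copies, for calling a CNV a whole-unit multiple
INTEGER_COPY_TOL = 0.05

#: fraction of a CNV that must lie in one repeat interval to count as contained
REPEAT_CONTAINMENT = 0.9


@dataclass(frozen=True)
class RepeatInterval:
    chrom: str
    start: int
    end: int
    unit_length: int

    def __post_init__(self) -> None:
        if self.unit_length < 1:
            raise ValueError("unit_length must be >= 1")


class RepeatTrack:
    """Tandem-repeat annotation: intervals with a repeat unit length."""

    def __init__(self, intervals: Iterable[RepeatInterval] = ()):
        self._trees: dict[str, IntervalTree] = {}
        self.intervals: list[RepeatInterval] = []
        for iv in intervals:
            self.add(iv)

    def add(self, iv: RepeatInterval) -> None:
        self.intervals.append(iv)
        self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)

    def overlapping(self, chrom: str, start: int, end: int) -> list[RepeatInterval]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted(
            (hit.data for hit in tree.overlap(start, end)),
            key=lambda r: (r.start, r.end, r.unit_length),
        )

    @classmethod
    def from_bed(cls, path: str) -> "RepeatTrack":
        """Read a BED-like file: chrom, start, end, unit_length."""
        track = cls()
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track")):
                    continue
                fields = line.split("\t")
                track.add(
                    RepeatInterval(fields[0], int(fields[1]), int(fields[2]), int(fields[3]))
                )
        return track

    def to_bed(self, path: str) -> None:
        with open(path, "w") as fh:
            for iv in sorted(self.intervals, key=lambda r: (r.chrom, r.start, r.end)):
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.unit_length}\n")


@dataclass(frozen=True)
class InsertionRecord:
    chrom: str
    site: int
    inserted_seq: str

    def __post_init__(self) -> None:
        if len(self.inserted_seq) < 1:
            raise ValueError("inserted sequence must be non-empty")


def _coords(cnv) -> tuple[str, int, int, str, bool]:
    return cnv.interval.chrom, cnv.interval.start, cnv.interval.end, cnv.svtype, cnv.precise


def pick_params(a, b, params: MatchParams | None) -> MatchParams:
    if params is not None:
        return params
    return PRECISE if (a.precise and b.precise) else IMPRECISE


def cnv_match(a, b, params: MatchParams | None = None) -> bool:
    """Positional match of two same-type CNVs under a parameter set.

    With no explicit parameters, the imprecise set is used when either call
    is imprecise.
    """
    ca, sa, ea, ta, _ = _coords(a)
    cb, sb, eb, tb, _ = _coords(b)
    if ta != tb or ca != cb:
        return False
    p = pick_params(a, b, params)
    if abs(sa - sb) > p.max_distance or abs(ea - eb) > p.max_distance:
        return False
    la, lb = ea - sa, eb - sb
    if abs(la - lb) > p.max_len_diff:
        return False
    shorter = min(la, lb)
    if shorter <= 0:
        return False
    overlap = max(0, min(ea, eb) - max(sa, sb))
    return overlap / shorter >= p.min_overlap


def containing_repeat(cnv, repeats: RepeatTrack) -> RepeatInterval | None:
    """The repeat interval covering >= 90% of the CNV; shortest unit on ties."""
    iv = cnv.interval
    best: RepeatInterval | None = None
    for rep in repeats.overlapping(iv.chrom, iv.start, iv.end):
        cov = min(iv.end, rep.end) - max(iv.start, rep.start)
        if iv.length > 0 and cov / iv.length >= REPEAT_CONTAINMENT:
            if best is None or rep.unit_length < best.unit_length:
                best = rep
    return best


def in_tandem_repeat(cnv, repeats: RepeatTrack) -> bool:
    return containing_repeat(cnv, repeats) is not None


def cnv_match_repeat_aware(
    a, b, params: MatchParams | None = None, repeats: RepeatTrack | None = None
) -> bool:
    """As cnv_match, but inside one shared tandem repeat only lengths count."""
    if repeats is not None and a.svtype == b.svtype and a.interval.chrom == b.interval.chrom:
        ra = containing_repeat(a, repeats)
        rb = containing_repeat(b, repeats)
        if ra is not None and ra == rb:
            p = pick_params(a, b, params)
            return abs(a.interval.length - b.interval.length) <= p.max_len_diff
    return cnv_match(a, b, params)


def dup_ins_match(
    dup,
    ins: InsertionRecord,
    params: MatchParams | None = None,
    scheme: AlignmentScheme = DEFAULT_SCHEME,
    dup_seq: str | None = None,
    ref_fetch=None,
) -> bool:
    """Match a called tandem duplication against an insertion-style record.

    The insertion site must be within max_distance of either duplication
    boundary, and the inserted sequence I must locally align to D' (the
    duplicated sequence concatenated ceil(|I|/|D|) times) covering >= 80% of I.
    """
    if dup.svtype != "DUP" or ins.chrom != dup.interval.chrom:
        return False
    p = params if params is not None else (PRECISE if dup.precise else IMPRECISE)
    if (
        abs(ins.site - dup.interval.start) > p.max_distance
        and abs(ins.site - dup.interval.end) > p.max_distance
    ):
        return False
    if dup_seq is None:
        if ref_fetch is None:
            raise ValueError("need dup_seq or ref_fetch to compare sequences")
        dup_seq = ref_fetch(dup.interval.chrom, dup.interval.start, dup.interval.end)
    i = len(ins.inserted_seq)
    d = len(dup_seq)
    if d == 0:
        return False
    n = math.ceil(i / d)
    dprime = dup_seq * n
    res = local_align(ins.inserted_seq, dprime, scheme)
    covered = res.query_end - res.query_start
    return covered >= 0.8 * i


def repeat_units(cnv, repeat_interval: RepeatInterval) -> float:
    """Event length divided by the repeat unit length."""
    if repeat_interval.unit_length <= 0:
        raise ValueError("unit_length must be positive")
    return cnv.interval.length / repeat_interval.unit_length


def is_integer_multiple(units: float, tol: float = INTEGER_COPY_TOL) -> bool:
    return abs(units - round(units)) <= tol


@dataclass
class CNVCluster:
    members: list
    representative: GenomeInterval
    svtype: str


def cluster_catalogue(cnvs: Sequence, params: MatchParams | None = None) -> list[CNVCluster]:
    """Greedy clique cover of the compatibility graph.

    Events are sorted by coordinate; each event joins the current clique only
    if compatible with every member, so every cluster is a clique by
    construction. The representative takes member-wise median coordinates.
    """
    out: list[CNVCluster] = []
    ordered = sorted(
        cnvs, key=lambda c: (c.svtype, c.interval.chrom, c.interval.start, c.interval.end)
    )
    open_cliques: list[list] = []
    for c in ordered:
        placed = False
        for clique in open_cliques:
            if (
                clique[0].svtype == c.svtype
                and clique[0].interval.chrom == c.interval.chrom
                and all(cnv_match(c, m, params) for m in clique)
            ):
                clique.append(c)
                placed = True
                break
        if not placed:
            open_cliques.append([c])
    for clique in open_cliques:
        rep = GenomeInterval(
            clique[0].interval.chrom,
            int(median_low([m.interval.start for m in clique])),
            int(median_low([m.interval.end for m in clique])),
        )
        out.append(CNVCluster(clique, rep, clique[0].svtype))
    return out


def evaluate(
    calls: Sequence,
    truth: Sequence,
    params: MatchParams | None = None,
    repeats: RepeatTrack | None = None,
    ref_fetch=None,
) -> tuple[float | None, float | None]:
    """Sensitivity and precision of ``calls`` against ``truth``.

    Matching is repeat-aware; truth duplications given as InsertionRecord
    entries are matched against called duplications via dup_ins_match.
    Sensitivity is None when the truth set is empty; precision is None when
    there are no calls.
    """

    def matches(call, t) -> bool:
        if isinstance(t, InsertionRecord):
            return dup_ins_match(call, t, params, ref_fetch=ref_fetch)
        return cnv_match_repeat_aware(call, t, params, repeats)

    matched_truth = sum(1 for t in truth if any(matches(c, t) for c in calls))
    matched_calls = sum(1 for c in calls if any(matches(c, t) for t in truth))
    sens = matched_truth / len(truth) if truth else None
    prec = matched_calls / len(calls) if calls else None
    return sens, prec
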