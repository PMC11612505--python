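"""Consensus piling, consensus pairing, junction assembly and realignment.

Clipped reads and hidden split reads (via their virtual clips) are piled
into per-side consensus sequences. A right-clipped and a left-clipped
consensus that lie within each other's opposite breakpoint range are paired
and merged into a junction sequence; unpaired consensuses are extended with
nearby reads by a greedy overlap-layout-consensus step. Realigning the two
sides of a junction to the reference yields a precise deletion (gap on the
reference) or tandem duplication (overlap on the reference).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median_low
from typing import Iterable, Sequence

import numpy as np

from .align import local_align, split_totals
from .core import DEFAULT_SCHEME, AlignmentScheme, GenomeInterval, LibraryStats
from .evidence import Side

#: (virtual) clip positions within this distance pile into one cluster
CLUSTER_TOL = 5

#: minimum reads on one side to emit a consensus
MIN_CONSENSUS_SUPPORT = 3

#: suffix-prefix overlap acceptance thresholds for junction assembly / OLC
MIN_OVERLAP = 20
MIN_OVERLAP_IDENTITY = 0.9

#: default minimum CNV size; 30 enables the small-indel mode
DEFAULT_MIN_SIZE = 50

#: fraction of a junction half that must align for the half to count as anchored
MIN_ANCHOR_FRACTION = 0.9

#: minimum length of a junction half considered for realignment
MIN_HALF_LEN = 20


@dataclass
class ClipEvidence:
    """One read's contribution to a breakpoint pile.

    ``anchor_seq`` are the read bases on the aligned side of the (virtual)
    clip, laid out so that they end (right clip) or start (left clip) at
    ``clip_pos``; ``tail_seq`` are the bases beyond the breakpoint.
    """

    name: str
    side: Side
    clip_pos: int
    anchor_seq: str
    tail_seq: str
    mapq: int
    mate_start: int | None  # same-chromosome mate coordinates, if any
    is_hsr: bool = False


@dataclass
class Consensus:
    side: Side
    breakpoint: int
    sequence: str
    clip_offset: int  # index in sequence where the tail begins (right) / anchor begins (left)
    support: int
    hsr_support: int
    mean_mapq: float
    members: list[ClipEvidence] = field(default_factory=list)
    opposite_range: GenomeInterval | None = None
    range_degraded: bool = False

    @property
    def sr_support(self) -> int:
        return self.support - self.hsr_support


@dataclass
class JunctionSequence:
    sequence: str
    junction_offset: int
    provenance: str  # "PAIRED" or "EXTENDED"
    sources: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not (0 < self.junction_offset < len(self.sequence)):
            raise ValueError("junction offset must be interior to the sequence")


@dataclass
class CandidateCNV:
    svtype: str  # "DEL" or "DUP"
    interval: GenomeInterval
    precise: bool
    source: str  # "SPLIT" or "DISCORDANT"
    junction: JunctionSequence | None = None
    support_sr: int = 0
    support_hsr: int = 0
    support_disc: int = 0
    junction_score: int = 0
    mean_mapq: float = 60.0
    ci: int = 0  # half-width of the breakpoint confidence interval (imprecise)

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def junction_score_ratio(self) -> float:
        if self.junction is None or not len(self.junction.sequence):
            return 0.0
        return self.junction_score / len(self.junction.sequence)


def _plurality(column: list[str]) -> str:
    # deterministic: highest count, ties to the lexicographically smallest base
    counts: dict[str, int] = {}
    for b in column:
        counts[b] = counts.get(b, 0) + 1
    return min(counts, key=lambda b: (-counts[b], b))


def _cluster_1d(evs: list[ClipEvidence], tol: int) -> list[list[ClipEvidence]]:
    evs = sorted(evs, key=lambda e: (e.clip_pos, e.name))
    clusters: list[list[ClipEvidence]] = []
    for ev in evs:
        if clusters and ev.clip_pos - clusters[-1][-1].clip_pos <= tol:
            clusters[-1].append(ev)
        else:
            clusters.append([ev])
    return clusters


def canonicalize_clip(ev_: ClipEvidence, ref_str: str) -> ClipEvidence:
    """Shift a (virtual) clip to its anchor-maximal equivalent position.

    In a tandem repeat the same junction can be represented with the clip at
    any equivalent copy boundary; extending the anchor while the tail still
    matches the reference makes the representation unique, so reads from the
    same junction pile at one breakpoint.
    """
    bp, anchor, tail = ev_.clip_pos, ev_.anchor_seq, ev_.tail_seq
    if ev_.side is Side.RIGHT_CLIP:
        while len(tail) > 1 and bp < len(ref_str) and tail[0] == ref_str[bp]:
            anchor += tail[0]
            tail = tail[1:]
            bp += 1
    else:
        while len(tail) > 1 and bp > 0 and tail[-1] == ref_str[bp - 1]:
            anchor = tail[-1] + anchor
            tail = tail[:-1]
            bp -= 1
    if bp == ev_.clip_pos:
        return ev_
    return ClipEvidence(
        ev_.name, ev_.side, bp, anchor, tail, ev_.mapq, ev_.mate_start, ev_.is_hsr
    )


def pile_consensuses(
    evidences: Iterable[ClipEvidence],
    side: Side,
    min_support: int = MIN_CONSENSUS_SUPPORT,
    min_length: int = 0,
    cluster_tol: int = CLUSTER_TOL,
) -> list[Consensus]:
    """Cluster same-side (virtual) clips and build per-column plurality consensuses.

    Columns are indexed relative to each read's own clip position, so small
    jitter between members does not smear the junction. Clusters need
    ``min_support`` members and at least one mapq > 0 seed.
    """
    evs = [e for e in evidences if e.side is side]
    out: list[Consensus] = []
    for cluster in _cluster_1d(evs, cluster_tol):
        if len(cluster) < min_support:
            continue
        if not any(e.mapq > 0 for e in cluster):
            continue
        bp = int(median_low([e.clip_pos for e in cluster]))
        cols: dict[int, list[str]] = {}
        for e in cluster:
            # reads clipped at equivalent positions (junction microhomology)
            # carry tails shifted by the clip-position difference; align all
            # columns to the cluster breakpoint
            d = e.clip_pos - bp
            if side is Side.RIGHT_CLIP:
                for k, b in enumerate(e.anchor_seq):
                    cols.setdefault(d + k - len(e.anchor_seq), []).append(b)
                for k, b in enumerate(e.tail_seq):
                    cols.setdefault(d + k, []).append(b)
            else:
                for k, b in enumerate(e.tail_seq):
                    cols.setdefault(d + k - len(e.tail_seq), []).append(b)
                for k, b in enumerate(e.anchor_seq):
                    cols.setdefault(d + k, []).append(b)
        offsets = sorted(cols)
        lo = min(offsets)
        hi = max(offsets) + 1
        seq = "".join(_plurality(cols[c]) for c in range(lo, hi) if c in cols)
        clip_offset = -lo
        cons = Consensus(
            side=side,
            breakpoint=bp,
            sequence=seq,
            clip_offset=clip_offset,
            support=len(cluster),
            hsr_support=sum(1 for e in cluster if e.is_hsr),
            mean_mapq=float(np.mean([e.mapq for e in cluster])),
            members=cluster,
        )
        if min_length and len(seq) < min_length:
            continue
        out.append(cons)
    return out


def opposite_breakpoint_range(
    consensus: Consensus,
    stats: LibraryStats,
    chrom: str,
    chrom_len: int,
) -> GenomeInterval:
    """Range, inferred from member mates, where the partner breakpoint must lie.

    Right-clipped: [min mate start, max mate end + max_IS]; mirrored for
    left-clipped. Falls back to a max_IS-wide window beyond the breakpoint
    when no mate is mapped (flagged degraded).
    """
    max_is = int(round(stats.max_is))
    mate_starts = [e.mate_start for e in consensus.members if e.mate_start is not None]
    if not mate_starts:
        consensus.range_degraded = True
        if consensus.side is Side.RIGHT_CLIP:
            lo, hi = consensus.breakpoint, consensus.breakpoint + max_is
        else:
            lo, hi = consensus.breakpoint - max_is, consensus.breakpoint
    else:
        mate_ends = [s + stats.read_len for s in mate_starts]
        if consensus.side is Side.RIGHT_CLIP:
            lo, hi = min(mate_starts), max(mate_ends) + max_is
        else:
            lo, hi = min(mate_starts) - max_is, max(mate_ends)
    lo = max(0, lo)
    hi = max(lo, min(hi, chrom_len))
    rng = GenomeInterval(chrom, lo, hi)
    consensus.opposite_range = rng
    return rng


def pair_consensuses(
    lefts: Sequence[Consensus],
    rights: Sequence[Consensus],
    slack: int = 0,
) -> tuple[list[tuple[Consensus, Consensus]], list[Consensus]]:
    """Greedy mutual-range pairing; each consensus used at most once.

    A pair is (right-clipped c1, left-clipped c2) with c2's breakpoint inside
    c1's opposite range and vice versa. Valid pairs are taken by descending
    combined support (deterministic tie-break on coordinates). ``slack``
    inflates the ranges: for a tandem duplication longer than the insert
    size, junction-read mates map inside the duplicated span, so the
    opposite breakpoint sits up to roughly an insert size outside the
    mate-derived range.
    """
    valid: list[tuple[int, int, int, int, Consensus, Consensus]] = []
    for li, c2 in enumerate(lefts):
        for ri, c1 in enumerate(rights):
            if c1.opposite_range is None or c2.opposite_range is None:
                continue
            if (
                c1.opposite_range.start - slack <= c2.breakpoint <= c1.opposite_range.end + slack
                and c2.opposite_range.start - slack <= c1.breakpoint <= c2.opposite_range.end + slack
            ):
                valid.append(
                    (-(c1.support + c2.support), c1.breakpoint, c2.breakpoint, li, c1, c2)
                )
    valid.sort(key=lambda v: v[:4])
    used: set[int] = set()
    pairs: list[tuple[Consensus, Consensus]] = []
    for _, _, _, _, c1, c2 in valid:
        if id(c1) in used or id(c2) in used:
            continue
        used.add(id(c1))
        used.add(id(c2))
        pairs.append((c1, c2))
    unpaired = [c for c in list(lefts) + list(rights) if id(c) not in used]
    return pairs, unpaired


def best_suffix_prefix_overlap(
    s1: str,
    s2: str,
    min_len: int = MIN_OVERLAP,
    min_identity: float = MIN_OVERLAP_IDENTITY,
) -> tuple[int, int] | None:
    """Best gapless overlap of a suffix of s1 with a prefix of s2.

    Returns (overlap_length, matches) maximising the match count among
    overlaps passing the length and identity floors, or None.
    """
    a = np.frombuffer(s1.encode("ascii"), dtype=np.uint8)
    b = np.frombuffer(s2.encode("ascii"), dtype=np.uint8)
    best: tuple[int, int] | None = None
    for o in range(min(len(s1), len(s2)), min_len - 1, -1):
        matches = int((a[len(a) - o :] == b[:o]).sum())
        if matches / o >= min_identity and (best is None or matches > best[1]):
            best = (o, matches)
    return best


def assemble_junction_from_pair(
    pair: tuple[Consensus, Consensus], scheme: AlignmentScheme = DEFAULT_SCHEME
) -> JunctionSequence | None:
    """Merge a (right-clipped, left-clipped) consensus pair across their overlap.

    Both consensuses describe the same junction, with their clip offsets
    marking the breakpoint column, so the merge offset is implied rather
    than searched — in a tandem repeat a free suffix-prefix search can lock
    in one repeat unit out of phase and fabricate a chimeric junction. The
    implied overlap must still be long enough and of sufficient identity.
    Each side keeps its well-covered anchor bases across the overlap.
    """
    c1, c2 = pair
    tail1 = len(c1.sequence) - c1.clip_offset  # c1 columns at/after the junction
    o = tail1 + c2.clip_offset  # implied overlap length
    if o < MIN_OVERLAP or o > min(len(c1.sequence), len(c2.sequence)):
        return None
    a = c1.sequence[-o:]
    b = c2.sequence[:o]
    matches = sum(1 for x, y in zip(a, b) if x == y)
    if matches / o < MIN_OVERLAP_IDENTITY:
        return None
    # junction-relative columns: [-co1, 0) from c1's anchor, [0, ...) from c2's
    merged = c1.sequence[: c1.clip_offset] + c2.sequence[c2.clip_offset :]
    offset = c1.clip_offset
    if not (0 < offset < len(merged)):
        return None
    return JunctionSequence(merged, offset, "PAIRED", (id(c1), id(c2)))


def extend_unpaired(
    consensus: Consensus,
    local_reads: Sequence[str],
    read_len: int,
) -> JunctionSequence | None:
    """Greedy OLC extension of an unpaired consensus into a junction sequence.

    Repeatedly appends the read with the best suffix-prefix overlap past the
    clip, up to 2 * read_len of novel sequence; requires the final junction
    to reach 1.5 * read_len.
    """
    seq = consensus.sequence
    if consensus.side is Side.LEFT_CLIP:
        # work in reversed space so extension is always rightwards
        seq = seq[::-1]
        reads = [r[::-1] for r in local_reads]
    else:
        reads = list(local_reads)
    novel_cap = 2 * read_len
    base_len = len(seq)
    seed_k = 12
    while len(seq) - base_len < novel_cap:
        best = None
        seed = seq[-seed_k:]
        for r in reads:
            if seed not in r:  # cheap anchor filter before scoring overlaps
                continue
            ov = best_suffix_prefix_overlap(seq, r)
            if ov is None:
                continue
            o, matches = ov
            ext = len(r) - o
            if ext <= 0:
                continue
            key = (matches, ext, r)
            if best is None or key > best[0]:
                best = (key, r, o)
        if best is None:
            break
        _, r, o = best
        take = min(len(r) - o, novel_cap - (len(seq) - base_len))
        seq = seq + r[o : o + take]
    if len(seq) < 1.5 * read_len:
        return None
    grown = len(seq) - len(consensus.sequence)
    if consensus.side is Side.LEFT_CLIP:
        seq = seq[::-1]
        # novel bases grew on the left, pushing the clip point rightwards
        offset = consensus.clip_offset + grown
    else:
        offset = consensus.clip_offset
    if not (0 < offset < len(seq)):
        return None
    return JunctionSequence(seq, offset, "EXTENDED", (id(consensus),))


def _anchor_offset(jseq: str, read: str, k: int = 16) -> int | None:
    """Gapless placement of a read on a junction via exact seed k-mers."""
    votes: dict[int, int] = {}
    for sp in range(0, len(read) - k + 1, k):
        idx = jseq.find(read[sp : sp + k])
        if idx >= 0:
            off = idx - sp
            votes[off] = votes.get(off, 0) + 1
    if not votes:
        return None
    off, cnt = max(votes.items(), key=lambda kv: (kv[1], -abs(kv[0]), -kv[0]))
    return off if cnt >= 2 else None


def polish_junction(
    junction: JunctionSequence,
    local_reads: Sequence[str],
    min_votes: int = 2,
    min_identity: float = 0.9,
) -> JunctionSequence:
    """Correct assembly errors by per-column plurality over re-anchored reads.

    Reads are placed gaplessly by exact seed k-mers and vote only when they
    agree with the junction at ``min_identity`` over the placed span, which
    keeps reference-allele reads (heterozygous events) from overwriting the
    breakpoint-crossing content.
    """
    jseq = junction.sequence
    cols: dict[int, list[str]] = {}
    for read in local_reads:
        off = _anchor_offset(jseq, read)
        if off is None:
            continue
        lo = max(0, -off)
        hi = min(len(read), len(jseq) - off)
        if hi - lo < MIN_OVERLAP:
            continue
        matches = sum(1 for kk in range(lo, hi) if read[kk] == jseq[off + kk])
        if matches / (hi - lo) < min_identity:
            continue
        for kk in range(lo, hi):
            cols.setdefault(off + kk, []).append(read[kk])
    polished = list(jseq)
    for p, col in cols.items():
        if len(col) >= min_votes:
            polished[p] = _plurality(col)
    return JunctionSequence(
        "".join(polished), junction.junction_offset, junction.provenance, junction.sources
    )


def realign_junction(
    junction: JunctionSequence,
    window_seq: str,
    window_start: int,
    scheme: AlignmentScheme = DEFAULT_SCHEME,
    min_size: int = DEFAULT_MIN_SIZE,
    top_k: int = 8,
) -> CandidateCNV | None:
    """Split-realign a junction sequence onto the reference window.

    Scans all split points with the two-pass prefix/suffix DP, then verifies
    the best-scoring candidates (plus the assembly's own junction offset)
    with full half alignments, requiring each half to anchor with at least
    90% of its length aligned. A reference gap between the halves is a
    deletion; a reference overlap is a tandem duplication.
    """
    jseq = junction.sequence
    n = len(jseq)
    if n < 2 * MIN_HALF_LEN:
        return None
    totals = split_totals(jseq, window_seq, scheme)
    candidates = list(range(MIN_HALF_LEN, n - MIN_HALF_LEN + 1))
    candidates.sort(key=lambda i: (-int(totals[i]), abs(i - junction.junction_offset)))
    candidates = candidates[:top_k]
    if MIN_HALF_LEN <= junction.junction_offset <= n - MIN_HALF_LEN:
        if junction.junction_offset not in candidates:
            candidates.append(junction.junction_offset)
    best: tuple[int, CandidateCNV] | None = None
    for i in candidates:
        left = local_align(jseq[:i], window_seq, scheme)
        right = local_align(jseq[i:], window_seq, scheme)
        if (left.query_end - left.query_start) < MIN_ANCHOR_FRACTION * i:
            continue
        if (right.query_end - right.query_start) < MIN_ANCHOR_FRACTION * (n - i):
            continue
        e_l = window_start + left.ref_end
        s_r = window_start + right.ref_start
        if s_r > e_l:
            svtype, start, end = "DEL", e_l, s_r
        elif s_r < e_l:
            svtype, start, end = "DUP", s_r, e_l
        else:
            continue
        if end - start < min_size:
            continue
        score = left.score + right.score
        if best is None or score > best[0]:
            cand = CandidateCNV(
                svtype=svtype,
                interval=GenomeInterval("", start, end),
                precise=True,
                source="SPLIT",
                junction=junction,
                junction_score=score,
            )
            best = (score, cand)
    return best[1] if best else None


def write_consensus_fasta(consensuses: Sequence[Consensus], path: str) -> None:
    """Debug dump: consensus sequences with side/breakpoint/support headers."""
    with open(path, "w") as fh:
        for i, c in enumerate(consensuses):
            fh.write(
                f">consensus_{i} side={c.side.value} breakpoint={c.breakpoint} "
                f"support={c.support} hsr={c.hsr_support}\n{c.sequence}\n"
            )


def left_align_interval(
    seq_fetch, chrom: str, start: int, end: int, max_shift: int = 10_000
) -> tuple[int, int]:
    """Shift an event to its leftmost equivalent position within a repeat.

    While the base before the start equals the base before the end, the
    event can shift one base left without changing the alternate sequence.
    """
    lo = max(0, start - max_shift)
    buf = seq_fetch(chrom, lo, end).upper()
    s = start - lo
    e = end - lo
    while s > 0 and buf[s - 1] == buf[e - 1]:
        s -= 1
        e -= 1
    return lo + s, lo + e
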