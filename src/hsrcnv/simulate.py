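"""Synthetic references, planted CNVs and paired-end read simulation.

The generator emulates the data regimes the caller targets: tandem repeats
with configurable unit length, copy number and inter-copy divergence;
planted deletions and tandem duplications (including exact full-unit
events); paired reads with Normal(mu, sigma) insert sizes and substitution
errors; and an aligner that prefers a full alignment with mismatches over a
clipped one unless clipping wins by a margin — the behaviour that turns
junction reads in repeats into hidden split reads instead of split reads.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np

from .align import glocal_align, local_align
from .core import ReadRecord
from .compare import RepeatInterval, RepeatTrack

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class RepeatSpec:
    """A tandem repeat to embed: ``copies`` units of ``unit_length`` bp.

    ``divergence`` is the per-base substitution rate applied independently
    to every copy after the first, relative to the first copy.
    """

    unit_length: int
    copies: int
    divergence: float = 0.0
    position: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.divergence <= 1.0):
            raise ValueError("divergence must be in [0, 1]")
        if self.unit_length < 1 or self.copies < 2:
            raise ValueError("need unit_length >= 1 and copies >= 2")

    @property
    def span(self) -> int:
        return self.unit_length * self.copies


@dataclass(frozen=True)
class TruthEvent:
    svtype: str  # "DEL" or "DUP"
    start: int
    end: int
    zygosity: str = "HOM"  # "HOM" or "HET"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SimConfig:
    seed: int = 0
    contig_name: str = "sim1"
    contig_length: int = 1_000_000
    repeat_specs: list[RepeatSpec] = field(default_factory=list)
    coverage: float = 30.0
    read_len: int = 150
    mu: float = 400.0
    sigma: float = 50.0
    subst_error: float = 0.002
    #: a read is emitted clipped only when the best clipped placement beats
    #: the best full placement by more than this score margin (kept equal to
    #: the caller's minimum HSR score so the two sides of the model agree)
    clip_margin: int = 8

    def __post_init__(self) -> None:
        if self.mu <= self.read_len:
            raise ValueError("mean insert size must exceed the read length")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _mutate(rng: np.random.Generator, arr: np.ndarray, rate: float) -> np.ndarray:
    out = arr.copy()
    if rate <= 0:
        return out
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        choices = _BASES[_BASES != out[i]]
        out[i] = choices[rng.integers(0, len(choices))]
    return out


def make_reference(config: SimConfig) -> tuple[str, RepeatTrack]:
    """Random background with embedded tandem repeats and their annotation."""
    rng = np.random.default_rng(config.seed)
    seq = _random_seq(rng, config.contig_length)
    placed: list[tuple[int, int]] = []
    track = RepeatTrack()
    margin = 3000
    specs = list(config.repeat_specs)
    for spec in specs:
        span = spec.span
        if span + 2 * margin > config.contig_length:
            raise ValueError("repeat does not fit in the contig")
        if spec.position is not None:
            pos = spec.position
            if pos < 0 or pos + span > config.contig_length:
                raise ValueError("repeat overflows the contig")
        else:
            for _ in range(1000):
                pos = int(rng.integers(margin, config.contig_length - span - margin))
                if all(pos + span + margin <= s or pos >= e + margin for s, e in placed):
                    break
            else:
                raise ValueError("could not place repeat without overlap")
        unit = _random_seq(rng, spec.unit_length)
        copies = [unit]
        for _ in range(spec.copies - 1):
            copies.append(_mutate(rng, unit, spec.divergence))
        seq[pos : pos + span] = np.concatenate(copies)
        placed.append((pos, pos + span))
        track.add(RepeatInterval(config.contig_name, pos, pos + span, spec.unit_length))
    return seq.tobytes().decode("ascii"), track


def random_unique_events(
    rng: np.random.Generator,
    contig_length: int,
    n_del: int,
    n_dup: int,
    size_range: tuple[int, int] = (60, 2000),
    min_gap: int = 5000,
    margin: int = 5000,
    zygosity: str = "HOM",
    avoid: list[tuple[int, int]] | None = None,
) -> list[TruthEvent]:
    """Plant non-overlapping events with unique (non-repetitive) junctions."""
    events: list[TruthEvent] = []
    taken = list(avoid or [])
    kinds = ["DEL"] * n_del + ["DUP"] * n_dup
    for k, kind in enumerate(kinds):
        for _ in range(10_000):
            size = int(rng.integers(size_range[0], size_range[1] + 1))
            start = int(rng.integers(margin, contig_length - margin - size))
            end = start + size
            if all(end + min_gap <= s or start >= e + min_gap for s, e in taken):
                taken.append((start, end))
                zyg = zygosity if zygosity != "MIX" else ("HOM" if k % 2 == 0 else "HET")
                events.append(TruthEvent(kind, start, end, zyg))
                break
        else:
            raise ValueError("could not place all events")
    return sorted(events, key=lambda e: e.start)


def full_unit_repeat_events(
    track: RepeatTrack,
    kinds: list[str],
    zygosity: str = "HOM",
    unit_index: int = 1,
) -> list[TruthEvent]:
    """One full-unit event per repeat: delete or duplicate a single copy."""
    reps = sorted(track.intervals, key=lambda r: (r.chrom, r.start))
    if len(kinds) > len(reps):
        raise ValueError("more events requested than repeats available")
    events = []
    for rep, kind in zip(reps, kinds):
        s = rep.start + unit_index * rep.unit_length
        e = s + rep.unit_length
        if e > rep.end:
            raise ValueError("unit_index outside the repeat")
        events.append(TruthEvent(kind, s, e, zygosity))
    return sorted(events, key=lambda ev: ev.start)


@dataclass
class Haplotype:
    """A donor sequence with its colinear mapping back to the reference."""

    seq: str
    #: colinear blocks (donor_start, ref_start, length), sorted by donor_start
    blocks: list[tuple[int, int, int]]
    #: junctions (donor_pos, ref_left_end, ref_right_start, svtype)
    junctions: list[tuple[int, int, int, str]]

    def donor_to_ref(self, pos: int) -> int:
        ds, rs, _ = self.block_of(pos)
        return rs + (pos - ds)

    def _starts(self) -> list[int]:
        if not hasattr(self, "_starts_cache"):
            self._starts_cache = [b[0] for b in self.blocks]
        return self._starts_cache

    def _jpos(self) -> list[int]:
        if not hasattr(self, "_jpos_cache"):
            self._jpos_cache = [j[0] for j in self.junctions]
        return self._jpos_cache

    def block_of(self, pos: int) -> tuple[int, int, int]:
        return self.blocks[bisect.bisect_right(self._starts(), pos) - 1]

    def junctions_in(self, a: int, b: int) -> list[tuple[int, int, int, str]]:
        jp = self._jpos()
        lo = bisect.bisect_right(jp, a)
        hi = bisect.bisect_left(jp, b)
        return self.junctions[lo:hi]


def plant_cnvs(ref_seq: str, truth: list[TruthEvent]) -> tuple[Haplotype, Haplotype]:
    """Apply events to donor haplotypes: HET to the first only, HOM to both."""
    ordered = sorted(truth, key=lambda e: e.start)
    for a, b in zip(ordered, ordered[1:]):
        if b.start < a.end:
            raise ValueError("planted events must not overlap")
    for e in ordered:
        if e.start < 0 or e.end > len(ref_seq):
            raise ValueError("event outside the contig")

    def build(events: list[TruthEvent]) -> Haplotype:
        parts: list[str] = []
        blocks: list[tuple[int, int, int]] = []
        junctions: list[tuple[int, int, int, str]] = []
        donor = 0
        cur = 0
        for e in events:
            if e.svtype == "DEL":
                ln = e.start - cur
                if ln > 0:
                    parts.append(ref_seq[cur : e.start])
                    blocks.append((donor, cur, ln))
                    donor += ln
                junctions.append((donor, e.start, e.end, "DEL"))
                cur = e.end
            else:  # DUP: the copy [start, end) appears twice
                ln = e.end - cur
                parts.append(ref_seq[cur : e.end])
                blocks.append((donor, cur, ln))
                donor += ln
                junctions.append((donor, e.end, e.start, "DUP"))
                parts.append(ref_seq[e.start : e.end])
                blocks.append((donor, e.start, e.end - e.start))
                donor += e.end - e.start
                cur = e.end
        parts.append(ref_seq[cur:])
        blocks.append((donor, cur, len(ref_seq) - cur))
        return Haplotype("".join(parts), blocks, junctions)

    hap1 = build(ordered)
    hap2 = build([e for e in ordered if e.zygosity == "HOM"])
    return hap1, hap2


def _cigar_nm(cigar, seq: str, pos: int, ref_seq: str) -> int:
    """SAM NM: mismatched bases plus total gap bases."""
    qi = ri = 0
    nm = 0
    for op, n in cigar:
        if op in "M=X":
            for k in range(n):
                if seq[qi + k] != ref_seq[pos + ri + k]:
                    nm += 1
            qi += n
            ri += n
        elif op == "I":
            nm += n
            qi += n
        elif op == "D":
            nm += n
            ri += n
        elif op in "SH":
            qi += n if op == "S" else 0
    return nm


def _normalise_cigar(cigar: list[tuple[str, int]]) -> list[tuple[str, int]]:
    """Merge runs and convert terminal insertions to soft clips."""
    out: list[tuple[str, int]] = []
    for op, n in cigar:
        if n <= 0:
            continue
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + n)
        else:
            out.append((op, n))
    if out and out[0][0] == "I":
        out[0] = ("S", out[0][1])
    if out and out[-1][0] == "I":
        out[-1] = ("S", out[-1][1])
    # a leading/trailing D does not consume query; drop it
    if out and out[0][0] == "D":
        out.pop(0)
    if out and out[-1][0] == "D":
        out.pop()
    return out


def _place_read(
    seq: str,
    a: int,
    hap: Haplotype,
    ref_seq: str,
    config: SimConfig,
) -> tuple[int, list[tuple[str, int]]]:
    """Reference placement of a donor read, emulating aligner preference.

    Reads not crossing a junction are placed directly via the coordinate
    map. Junction-crossing reads are aligned to a local reference window
    both fully (query-global) and freely (local); the clipped placement is
    used only when it beats the full one by more than ``clip_margin``.
    """
    b = a + len(seq)
    juncs = hap.junctions_in(a, b)
    if not juncs:
        ds, rs, ln = hap.block_of(a)
        return rs + (a - ds), [("M", len(seq))]
    # window: union of the mapped spans of the donor segments between junctions
    bounds = [a] + [j[0] for j in juncs] + [b]
    ref_points: list[int] = []
    for lo, hi in zip(bounds, bounds[1:]):
        ds, rs, ln = hap.block_of(lo)
        ref_points.append(rs + (lo - ds))
        ref_points.append(rs + min(hi - ds, ln))
    for j in juncs:
        ref_points.extend([j[1], j[2]])
    pad = len(seq) + 50
    lo = max(0, min(ref_points) - pad)
    hi = min(len(ref_seq), max(ref_points) + pad)
    window = ref_seq[lo:hi]
    full = glocal_align(seq, window)
    free = local_align(seq, window)
    covered = free.query_end - free.query_start
    if free.score - full.score > config.clip_margin and covered < len(seq):
        cigar = (
            [("S", free.query_start)]
            + list(free.cigar)
            + [("S", len(seq) - free.query_end)]
        )
        return lo + free.ref_start, _normalise_cigar(cigar)
    return lo + full.ref_start, _normalise_cigar(list(full.cigar))


def simulate_alignments(
    ref_seq: str,
    haplotypes: tuple[Haplotype, Haplotype],
    config: SimConfig,
    out_path: str,
) -> str:
    """Simulate a coordinate-sorted paired-end alignment file (SAM or BAM)."""
    import pysam

    rng = np.random.default_rng(config.seed + 1_000_003)
    rl = config.read_len
    records: list[ReadRecord] = []
    n_haps = len(haplotypes)
    pairs_per_hap = int(round(config.coverage * config.contig_length / (2 * rl) / n_haps))
    frag_floor = rl + 10

    for h, hap in enumerate(haplotypes):
        hap_len = len(hap.seq)
        sizes = np.maximum(
            frag_floor, np.rint(rng.normal(config.mu, config.sigma, pairs_per_hap)).astype(int)
        )
        starts = rng.integers(0, np.maximum(1, hap_len - sizes))
        n_errs = rng.binomial(rl, config.subst_error, size=(pairs_per_hap, 2))
        for k in range(pairs_per_hap):
            f = int(starts[k])
            size = int(sizes[k])
            reads = [hap.seq[f : f + rl], hap.seq[f + size - rl : f + size]]
            for ridx in range(2):
                ne = int(n_errs[k, ridx])
                if ne:
                    sq = list(reads[ridx])
                    pos_err = rng.choice(rl, size=ne, replace=False)
                    subs = rng.integers(0, 3, size=ne)
                    for p, s in zip(pos_err, subs):
                        sq[p] = "ACGT".replace(sq[p], "")[s]
                    reads[ridx] = "".join(sq)
            left_s, right_s = reads
            pos_l, cig_l = _place_read(left_s, f, hap, ref_seq, config)
            pos_r, cig_r = _place_read(right_s, f + size - rl, hap, ref_seq, config)
            name = f"sim{h}_{k}"
            rec_l = ReadRecord(
                name=name, chrom=config.contig_name, pos=pos_l, cigar=cig_l,
                seq=left_s, mapq=60, is_reverse=False,
                mate_chrom=config.contig_name, mate_pos=pos_r, mate_is_reverse=True,
            )
            rec_r = ReadRecord(
                name=name, chrom=config.contig_name, pos=pos_r, cigar=cig_r,
                seq=right_s, mapq=60, is_reverse=True,
                mate_chrom=config.contig_name, mate_pos=pos_l, mate_is_reverse=False,
            )
            outer_lo = min(rec_l.pos, rec_r.pos)
            outer_hi = max(rec_l.reference_end, rec_r.reference_end)
            tlen = outer_hi - outer_lo
            rec_l.insert_size = tlen if rec_l.pos <= rec_r.pos else -tlen
            rec_r.insert_size = -rec_l.insert_size
            inward = rec_l.pos <= rec_r.pos
            rec_l.is_proper = rec_r.is_proper = bool(
                inward and tlen <= config.mu + 4 * config.sigma
            )
            rec_l.nm = _cigar_nm(cig_l, left_s, pos_l, ref_seq)
            rec_r.nm = _cigar_nm(cig_r, right_s, pos_r, ref_seq)
            rec_l.is_paired = rec_r.is_paired = True
            records.extend([rec_l, rec_r])

    records.sort(key=lambda r: (r.pos, r.name, r.is_reverse))
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": config.contig_name, "LN": config.contig_length}],
    }
    mode = "wb" if out_path.endswith(".bam") else "w"
    with pysam.AlignmentFile(out_path, mode, header=header) as out:
        for idx, rec in enumerate(records):
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = rec.name
            seg.query_sequence = rec.seq
            seg.flag = (
                0x1  # paired
                | 0x2 * int(rec.is_proper)
                | 0x10 * int(rec.is_reverse)
                | 0x20 * int(not rec.is_reverse)
                | (0x40 if not rec.is_reverse else 0x80)
            )
            seg.reference_id = 0
            seg.reference_start = rec.pos
            seg.mapping_quality = rec.mapq
            seg.cigartuples = [("MIDNSHP=X".index(op), ln) for op, ln in rec.cigar]
            seg.next_reference_id = 0
            seg.next_reference_start = rec.mate_pos
            seg.template_length = rec.insert_size
            seg.query_qualities = pysam.qualitystring_to_array("I" * len(rec.seq))
            seg.set_tag("NM", rec.nm)
            out.write(seg)
    if out_path.endswith(".bam"):
        pysam.index(out_path)
    return out_path


def write_fasta(seq: str, name: str, path: str) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    SeqIO.write([SeqRecord(Seq(seq), id=name, description="")], path, "fasta")


def write_truth_tsv(truth: list[TruthEvent], chrom: str, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tsvtype\tzygosity\n")
        for e in sorted(truth, key=lambda e: e.start):
            fh.write(f"{chrom}\t{e.start}\t{e.end}\t{e.svtype}\t{e.zygosity}\n")


def read_truth_tsv(path: str) -> tuple[str, list[TruthEvent]]:
    chrom = ""
    events: list[TruthEvent] = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            chrom, start, end, svtype, zyg = line.rstrip("\n").split("\t")
            events.append(TruthEvent(svtype, int(start), int(end), zyg))
    return chrom, events


def truth_to_candidates(truth: list[TruthEvent], chrom: str):
    """Truth events as precise candidate records, for matching/evaluation."""
    from .core import GenomeInterval
    from .split_caller import CandidateCNV

    return [
        CandidateCNV(
            svtype=e.svtype,
            interval=GenomeInterval(chrom, e.start, e.end),
            precise=True,
            source="SPLIT",
        )
        for e in sorted(truth, key=lambda e: e.start)
    ]
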