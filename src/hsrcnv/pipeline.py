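"""End-to-end CNV calling: evidence -> candidates -> features -> filter -> VCF."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import discordant as disc_mod
from . import evidence as ev
from . import features as ft
from . import split_caller as sc
from .compare import PRECISE, cnv_match
from .core import (
    GenomeInterval,
    LibraryStats,
    ReadRecord,
    count_differences,
    estimate_library_stats,
)

log = logging.getLogger("hsrcnv")


class InputError(RuntimeError):
    """Unusable inputs (missing files, contig mismatches...)."""


@dataclass
class RunConfig:
    bam: str
    ref: str
    out_vcf: str
    repeats: str | None = None
    model: str | None = None
    features_out: str | None = None
    min_size: int = sc.DEFAULT_MIN_SIZE
    min_support: int = sc.MIN_CONSENSUS_SUPPORT
    hsr_min_score: int = ev.MIN_HSR_SCORE
    alpha: float = ft.ALPHA
    hsr_enabled: bool = True
    sample_size: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_size < 30:
            raise ValueError("min_size must be at least 30")
        if self.min_support < 3:
            raise ValueError("min_support must be at least 3")


def _collect_records(bam_path: str, contigs: dict[str, int]) -> dict[str, list[ReadRecord]]:
    import pysam

    by_chrom: dict[str, list[ReadRecord]] = {}
    with pysam.AlignmentFile(bam_path, check_sq=False) as bam:
        bad = [c for c in bam.references if c not in contigs]
        if bad:
            raise InputError(
                f"alignment contigs {bad} are absent from the reference "
                f"(reference has {sorted(contigs)})"
            )
        for seg in bam.fetch(until_eof=True):
            if seg.is_unmapped or seg.is_secondary or seg.is_supplementary or seg.is_duplicate:
                continue
            rec = ReadRecord.from_pysam(seg)
            by_chrom.setdefault(rec.chrom, []).append(rec)
    return by_chrom


def _pair_tables(records: list[ReadRecord]):
    """Per-chromosome pair summaries for discordance and insert-size tests."""
    by_name: dict[str, list[ReadRecord]] = {}
    for rec in records:
        by_name.setdefault(rec.name, []).append(rec)
    fr_pairs: list[tuple[int, int, int]] = []
    outward: list[tuple[int, int, int]] = []
    mates: list[tuple[ReadRecord, ReadRecord]] = []
    for name, recs in by_name.items():
        if len(recs) != 2:
            continue
        r1, r2 = recs
        if r1.is_reverse == r2.is_reverse:
            continue
        fwd, rev = (r2, r1) if r1.is_reverse else (r1, r2)
        mates.append((fwd, rev))
        if fwd.pos <= rev.pos:
            fr_pairs.append(
                (fwd.reference_end, rev.pos, max(rev.reference_end - fwd.pos, 0))
            )
        else:
            outward.append((rev.pos, fwd.reference_end, fwd.pos - rev.reference_end))
    fr_pairs.sort()
    outward.sort()
    return fr_pairs, outward, mates


def _clip_evidence_from_read(rec: ReadRecord) -> sc.ClipEvidence | None:
    side = ev.clip_side(rec)
    if side is None:
        return None
    lc, rc = rec.left_clip, rec.right_clip
    core = rec.seq[lc : len(rec.seq) - rc] if rc else rec.seq[lc:]
    mate = rec.mate_pos if rec.mate_chrom == rec.chrom else None
    if side is ev.Side.RIGHT_CLIP:
        return sc.ClipEvidence(
            rec.name, side, rec.reference_end, core, rec.seq[len(rec.seq) - rc :],
            rec.mapq, mate,
        )
    return sc.ClipEvidence(rec.name, side, rec.pos, core, rec.seq[:lc], rec.mapq, mate)


#: a CIGAR indel at least this long is treated as junction evidence
MIN_CIGAR_INDEL = 20


def _indel_evidence(rec: ReadRecord) -> list[sc.ClipEvidence]:
    """Junction evidence from large CIGAR indels.

    Aligners represent short deletions/duplications as D/I operations inside
    a full-length alignment rather than as clips; each such read observes
    both breakpoints, so it contributes one virtual clip per side.
    """
    out: list[sc.ClipEvidence] = []
    mate = rec.mate_pos if rec.mate_chrom == rec.chrom else None
    qi = 0
    p = rec.pos
    for op, n in rec.cigar:
        if op in "M=X":
            qi += n
            p += n
        elif op == "S":
            qi += n
        elif op == "I":
            if n >= MIN_CIGAR_INDEL:
                out.append(sc.ClipEvidence(
                    rec.name, ev.Side.RIGHT_CLIP, p, rec.seq[:qi], rec.seq[qi:],
                    rec.mapq, mate))
                out.append(sc.ClipEvidence(
                    rec.name, ev.Side.LEFT_CLIP, p, rec.seq[qi + n :], rec.seq[: qi + n],
                    rec.mapq, mate))
            qi += n
        elif op in "DN":
            if n >= MIN_CIGAR_INDEL:
                out.append(sc.ClipEvidence(
                    rec.name, ev.Side.RIGHT_CLIP, p, rec.seq[:qi], rec.seq[qi:],
                    rec.mapq, mate))
                out.append(sc.ClipEvidence(
                    rec.name, ev.Side.LEFT_CLIP, p + n, rec.seq[qi:], rec.seq[:qi],
                    rec.mapq, mate))
            p += n
    return out


def _clip_evidence_from_hsr(rec: ReadRecord, split: ev.HsrSplit) -> sc.ClipEvidence:
    i = split.split_index
    mate = rec.mate_pos if rec.mate_chrom == rec.chrom else None
    if split.virtual_side is ev.Side.RIGHT_CLIP:
        return sc.ClipEvidence(
            rec.name, split.virtual_side, split.virtual_breakpoint,
            rec.seq[:i], rec.seq[i:], rec.mapq, mate, is_hsr=True,
        )
    return sc.ClipEvidence(
        rec.name, split.virtual_side, split.virtual_breakpoint,
        rec.seq[i:], rec.seq[:i], rec.mapq, mate, is_hsr=True,
    )


def _attach_supports(cand: sc.CandidateCNV, c1: sc.Consensus, c2: sc.Consensus | None) -> None:
    cand.support_sr = c1.sr_support + (c2.sr_support if c2 else 0)
    cand.support_hsr = c1.hsr_support + (c2.hsr_support if c2 else 0)
    mapqs = [c1.mean_mapq] + ([c2.mean_mapq] if c2 else [])
    cand.mean_mapq = float(np.mean(mapqs))


def _dedupe_precise(calls: list[sc.CandidateCNV]) -> list[sc.CandidateCNV]:
    """Keep the best-supported representative among near-identical calls."""
    ordered = sorted(
        calls,
        key=lambda c: (-(c.support_sr + c.support_hsr), -c.junction_score, c.interval.start),
    )
    kept: list[sc.CandidateCNV] = []
    for c in ordered:
        if any(cnv_match(c, k, PRECISE) for k in kept):
            continue
        kept.append(c)
    kept.sort(key=lambda c: (c.interval.start, c.interval.end))
    return kept


def _process_contig(
    chrom: str,
    ref_str: str,
    records: list[ReadRecord],
    stats: LibraryStats,
    config: RunConfig,
) -> list[ft.CallRecord]:
    max_is = int(round(stats.max_is))
    rl = stats.read_len

    def ref_fetch(c: str, s: int, e: int) -> str:
        return ref_str[max(0, s) : max(0, e)]

    fr_pairs, outward_pairs, mates = _pair_tables(records)

    coverage = np.zeros(len(ref_str), dtype=np.int32)
    for rec in records:
        if rec.mapq >= 20:
            coverage[rec.pos : rec.reference_end] += 1

    # ---- evidence
    clip_evs: list[sc.ClipEvidence] = []
    n_hsr_candidates = 0
    for rec in records:
        ce = _clip_evidence_from_read(rec)
        if ce is not None:
            clip_evs.append(sc.canonicalize_clip(ce, ref_str))
            continue
        indel_evs = _indel_evidence(rec)
        if indel_evs:
            clip_evs.extend(sc.canonicalize_clip(e, ref_str) for e in indel_evs)
            continue
        if not config.hsr_enabled:
            continue
        if rec.nm is not None and rec.nm < ev.MIN_HSR_DIFFERENCES:
            continue  # NM bounds the difference count from above
        if count_differences(rec, ref_fetch) < ev.MIN_HSR_DIFFERENCES:
            continue
        n_hsr_candidates += 1
        wlo = max(0, rec.pos - max_is)
        whi = min(len(ref_str), rec.reference_end + max_is)
        split = ev.compute_hsr_split(
            rec, ref_str[wlo:whi], wlo, min_score=config.hsr_min_score
        )
        if split is not None:
            clip_evs.append(sc.canonicalize_clip(_clip_evidence_from_hsr(rec, split), ref_str))

    disc_pairs = []
    for fwd, rev in mates:
        dp = ev.pair_to_discordant(fwd, rev, stats)
        if dp is not None:
            disc_pairs.append(dp)

    # ---- consensuses and junctions
    rights = sc.pile_consensuses(clip_evs, ev.Side.RIGHT_CLIP, config.min_support, rl // 2)
    lefts = sc.pile_consensuses(clip_evs, ev.Side.LEFT_CLIP, config.min_support, rl // 2)
    for cons in rights + lefts:
        sc.opposite_breakpoint_range(cons, stats, chrom, len(ref_str))
    pairs, unpaired = sc.pair_consensuses(lefts, rights, slack=max_is)

    split_calls: list[sc.CandidateCNV] = []

    def realign(junction: sc.JunctionSequence, anchors: list[int]):
        lo = max(0, min(anchors) - max_is)
        hi = min(len(ref_str), max(anchors) + max_is)
        return sc.realign_junction(
            junction, ref_str[lo:hi], lo, min_size=config.min_size
        )

    import bisect as _b

    pos_seq = sorted((r.pos, r.seq) for r in records)
    pos_index = [p for p, _ in pos_seq]

    def local_read_seqs(bp: int) -> list[str]:
        lo = _b.bisect_left(pos_index, bp - 2 * int(stats.mu))
        hi = _b.bisect_right(pos_index, bp + 2 * int(stats.mu))
        return [s for _, s in pos_seq[lo:hi]]

    for c1, c2 in pairs:
        junction = sc.assemble_junction_from_pair((c1, c2))
        if junction is None:
            unpaired.extend([c1, c2])
            continue
        anchors = [c1.breakpoint, c2.breakpoint]
        for cons in (c1, c2):
            if cons.opposite_range is not None:
                anchors.extend([cons.opposite_range.start, cons.opposite_range.end])
        cand = realign(junction, anchors)
        if cand is None:
            continue
        cand.interval = GenomeInterval(chrom, cand.interval.start, cand.interval.end)
        _attach_supports(cand, c1, c2)
        split_calls.append(cand)

    for cons in unpaired:
        anchors = [cons.breakpoint]
        if cons.opposite_range is not None:
            anchors.extend([cons.opposite_range.start, cons.opposite_range.end])
        candidates: list[sc.CandidateCNV] = []
        # the consensus itself spans the junction with plurality-corrected
        # content; realigning it directly avoids chimeric greedy extensions
        if 0 < cons.clip_offset < len(cons.sequence):
            direct = realign(
                sc.JunctionSequence(
                    cons.sequence, cons.clip_offset, "CONSENSUS", (id(cons),)
                ),
                anchors,
            )
            if direct is not None:
                candidates.append(direct)
        junction = sc.extend_unpaired(cons, local_read_seqs(cons.breakpoint), rl)
        if junction is not None:
            # extended junctions carry single-read errors; strict-identity
            # polish lets same-allele reads correct them without admitting
            # sibling-copy reads
            junction = sc.polish_junction(
                junction, local_read_seqs(cons.breakpoint), min_identity=0.98
            )
            extended = realign(junction, anchors)
            if extended is not None:
                candidates.append(extended)
        if not candidates:
            continue
        cand = max(candidates, key=lambda c: c.junction_score_ratio)
        cand.interval = GenomeInterval(chrom, cand.interval.start, cand.interval.end)
        _attach_supports(cand, cons, None)
        split_calls.append(cand)

    # ---- left-align, dedupe, merge with discordant clusters
    for cand in split_calls:
        s, e = sc.left_align_interval(ref_fetch, chrom, cand.interval.start, cand.interval.end)
        cand.interval = GenomeInterval(chrom, s, e)
    split_calls = _dedupe_precise(split_calls)
    disc_calls = disc_mod.cluster_discordant(disc_pairs, stats, config.min_support)
    disc_calls = [c for c in disc_calls if c.interval.length >= config.min_size]
    for cand in disc_calls:
        s, e = sc.left_align_interval(ref_fetch, chrom, cand.interval.start, cand.interval.end)
        cand.interval = GenomeInterval(chrom, s, e)
    merged = disc_mod.merge_candidates(split_calls, disc_calls)

    log.info(
        "%s: %d clip/HSR evidences (%d HSR candidates), %d/%d consensuses, "
        "%d split calls, %d discordant clusters, %d merged candidates",
        chrom, len(clip_evs), n_hsr_candidates, len(rights), len(lefts),
        len(split_calls), len(disc_calls), len(merged),
    )

    # ---- features and filtering
    out: list[ft.CallRecord] = []
    filter_config = ft.FilterConfig(min_support=config.min_support, alpha=config.alpha)
    model = ft.load_model(config.model) if config.model else None
    for cand in merged:
        sizes = ft.collect_spanning_insert_sizes(cand, fr_pairs, outward_pairs, stats)
        size_est = ft.insert_size_test(sizes, stats, cand.svtype)
        d_ev, d_lf, d_rf, degraded = ft.depth_features(cand, coverage, rl)
        concordant = sum(
            1
            for fwd_end, rev_start, ins in fr_pairs
            if fwd_end <= cand.interval.start and rev_start >= cand.interval.end
            and ins <= stats.max_is
        )
        feats = ft.CNVFeatures(
            support_sr=cand.support_sr,
            support_hsr=cand.support_hsr,
            support_disc=cand.support_disc,
            concordant_span=concordant,
            mean_mapq=cand.mean_mapq,
            junction_score=cand.junction_score,
            junction_score_ratio=min(1.0, cand.junction_score_ratio),
            depth_event=d_ev,
            depth_left_flank=d_lf,
            depth_right_flank=d_rf,
            flank_degraded=degraded,
            size_est=size_est,
        )
        if model is not None:
            prob = float(ft.rf_apply(model, feats.as_vector())[0])
            verdict = ("PASS",) if prob >= 0.5 else ("MODEL",)
        else:
            verdict = ft.hard_filter(feats, cand, filter_config)
        out.append(ft.CallRecord(cand, feats, verdict))
    return out


def run_call(config: RunConfig, stats: LibraryStats | None = None) -> list[ft.CallRecord]:
    """Run the full calling pipeline and write the VCF (and features TSV)."""
    import pyfaidx

    try:
        fasta = pyfaidx.Fasta(config.ref)
    except Exception as exc:  # pragma: no cover - passthrough diagnostics
        raise InputError(f"cannot open reference {config.ref}: {exc}") from exc
    contigs = {name: len(fasta[name]) for name in fasta.keys()}
    by_chrom = _collect_records(config.bam, contigs)

    if stats is None:
        def _all_records():
            for chrom in sorted(by_chrom):
                yield from by_chrom[chrom]

        stats = estimate_library_stats(_all_records(), config.sample_size)
    log.info(
        "library: read_len=%d mu=%.1f sigma=%.1f max_is=%.1f (n=%d)",
        stats.read_len, stats.mu, stats.sigma, stats.max_is, stats.n_sampled,
    )

    calls: list[ft.CallRecord] = []
    for chrom in sorted(by_chrom):
        ref_str = str(fasta[chrom][:]).upper()
        calls.extend(_process_contig(chrom, ref_str, by_chrom[chrom], stats, config))

    order = {name: i for i, name in enumerate(contigs)}
    calls.sort(key=lambda r: (order[r.candidate.interval.chrom], r.candidate.interval.start))

    def ref_base_fetch(c: str, s: int, e: int) -> str:
        return str(fasta[c][s:e])

    ft.write_vcf(calls, list(contigs.items()), config.out_vcf, ref_base_fetch)
    if config.features_out:
        ft.write_features_tsv(calls, config.features_out)
    n_pass = sum(1 for r in calls if r.passed)
    log.info("wrote %d calls (%d PASS) to %s", len(calls), n_pass, config.out_vcf)
    return calls
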