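"""Self-contained validation regimes on synthetic data.

These functions define the package's standard simulation studies: an
easy regime with unique junctions, a hidden-split regime with full-unit
events in diverged tandem repeats, a perfect-repeat negative control, and
statistical calibration checks for the insert-size test. They are used by
the test suite and by scripts that reproduce the headline numbers.
"""

from __future__ import annotations

import os
import tempfile

import numpy as np

from . import simulate as sim
from .compare import PRECISE, evaluate
from .core import LibraryStats
from .es import build_allele_pair, expected_support
from .features import insert_size_test
from .pipeline import RunConfig, run_call
from .split_caller import left_align_interval


def _run(ref_seq, track, truth, config, workdir, tag, hsr_enabled=True):
    ref_path = os.path.join(workdir, f"{tag}.fa")
    bam_path = os.path.join(workdir, f"{tag}.bam")
    vcf_path = os.path.join(workdir, f"{tag}.vcf")
    sim.write_fasta(ref_seq, config.contig_name, ref_path)
    haps = sim.plant_cnvs(ref_seq, truth)
    sim.simulate_alignments(ref_seq, haps, config, bam_path)
    calls = run_call(
        RunConfig(bam=bam_path, ref=ref_path, out_vcf=vcf_path, hsr_enabled=hsr_enabled)
    )
    return [c.candidate for c in calls if c.passed]


def easy_regime(
    seed: int,
    workdir: str | None = None,
    contig_length: int = 1_000_000,
    n_del: int = 30,
    n_dup: int = 30,
    coverage: float = 30.0,
) -> dict:
    """Unique-junction events (60-2000 bp) on a 1-Mb contig at 30x.

    Returns recall/precision under the precise comparison parameters, and
    the fraction of precise calls whose breakpoints equal the planted
    (left-aligned) ones exactly.
    """
    workdir = workdir or tempfile.mkdtemp(prefix="hsrcnv_easy_")
    config = sim.SimConfig(seed=seed, contig_length=contig_length, coverage=coverage)
    ref_seq, track = sim.make_reference(config)
    rng = np.random.default_rng(seed + 1)
    truth = sim.random_unique_events(
        rng, contig_length, n_del, n_dup, (60, 2000), zygosity="HOM"
    )
    passing = _run(ref_seq, track, truth, config, workdir, "easy")
    truth_c = sim.truth_to_candidates(truth, config.contig_name)
    recall, precision = evaluate(passing, truth_c, PRECISE)

    def fetch(c, s, e):
        return ref_seq[s:e]

    exact_truth = {
        (t.svtype,) + left_align_interval(fetch, config.contig_name, t.interval.start, t.interval.end)
        for t in truth_c
    }
    precise_calls = [c for c in passing if c.precise]
    n_exact = sum(
        1
        for c in precise_calls
        if (c.svtype, c.interval.start, c.interval.end) in exact_truth
    )
    return {
        "recall": recall,
        "precision": precision,
        "n_calls": len(passing),
        "n_precise": len(precise_calls),
        "n_exact": n_exact,
    }


def hidden_split_regime(
    seed: int,
    workdir: str | None = None,
    n_repeats: int = 20,
    contig_length: int = 600_000,
    coverage: float = 50.0,
) -> dict:
    """Full-unit events in tandem repeats with 2-5% inter-copy divergence.

    One full-unit deletion or duplication is planted per repeat (units
    60-180 bp, 3-6 copies). The caller runs twice: with the hidden-split
    module enabled and with split reads/discordant pairs only. Matching is
    repeat-aware.
    """
    workdir = workdir or tempfile.mkdtemp(prefix="hsrcnv_hsr_")
    rng = np.random.default_rng(seed)
    specs = [
        sim.RepeatSpec(
            unit_length=int(rng.integers(60, 181)),
            copies=int(rng.integers(3, 7)),
            divergence=float(rng.uniform(0.02, 0.05)),
        )
        for _ in range(n_repeats)
    ]
    config = sim.SimConfig(
        seed=seed, contig_length=contig_length, repeat_specs=specs, coverage=coverage
    )
    ref_seq, track = sim.make_reference(config)
    kinds = ["DEL", "DUP"] * (n_repeats // 2) + ["DEL"] * (n_repeats % 2)
    truth = sim.full_unit_repeat_events(track, kinds)
    truth_c = sim.truth_to_candidates(truth, config.contig_name)

    with_hsr = _run(ref_seq, track, truth, config, workdir, "hsr", hsr_enabled=True)
    without = _run(ref_seq, track, truth, config, workdir, "sronly", hsr_enabled=False)
    hsr_recall, hsr_precision = evaluate(with_hsr, truth_c, None, track)
    sr_recall, _ = evaluate(without, truth_c, None, track)
    return {
        "hsr_recall": hsr_recall,
        "hsr_precision": hsr_precision if hsr_precision is not None else 1.0,
        "sr_only_recall": sr_recall if sr_recall is not None else 0.0,
    }


def perfect_repeat_control(seed: int, workdir: str | None = None) -> dict:
    """Full-unit deletion in a 0%-divergence repeat: the analytic null case.

    The expected-support score is exactly zero and the simulation produces
    no pileable split evidence and no hidden-split candidates at the locus.
    """
    import pysam

    from .core import GenomeInterval, ReadRecord
    from .evidence import clip_side, compute_hsr_split, is_candidate_hsr
    from .split_caller import CandidateCNV

    workdir = workdir or tempfile.mkdtemp(prefix="hsrcnv_perf_")
    unit, copies, position = 80, 4, 30_000
    config = sim.SimConfig(
        seed=seed,
        contig_length=80_000,
        repeat_specs=[sim.RepeatSpec(unit, copies, 0.0, position=position)],
        coverage=30,
    )
    ref_seq, track = sim.make_reference(config)
    truth = sim.full_unit_repeat_events(track, ["DEL"])
    (event,) = truth

    cnv = CandidateCNV(
        "DEL", GenomeInterval(config.contig_name, event.start, event.end), True, "SPLIT"
    )
    allele = build_allele_pair(
        cnv, lambda c, s, e: ref_seq[s:e], len(ref_seq), flank=2000
    )
    es = expected_support(allele, config.read_len)

    bam_path = os.path.join(workdir, "perf.bam")
    haps = sim.plant_cnvs(ref_seq, truth)
    sim.simulate_alignments(ref_seq, haps, config, bam_path)

    lo, hi = position - 500, position + copies * unit + 500
    n_clipped = 0
    n_hsr_splits = 0
    fetch = lambda c, s, e: ref_seq[s:e]
    with pysam.AlignmentFile(bam_path) as bam:
        for seg in bam.fetch(config.contig_name, lo, hi):
            rec = ReadRecord.from_pysam(seg)
            if clip_side(rec) is not None:
                n_clipped += 1
                continue
            if (rec.nm or 0) >= 3 and is_candidate_hsr(rec, fetch):
                wlo = max(0, rec.pos - 600)
                whi = min(len(ref_seq), rec.reference_end + 600)
                if compute_hsr_split(rec, ref_seq[wlo:whi], wlo) is not None:
                    n_hsr_splits += 1
    return {
        "es": es.es,
        "n_breakpoint_reads": es.n_total,
        "n_clipped_at_locus": n_clipped,
        "n_hsr_splits_at_locus": n_hsr_splits,
    }


def insert_size_calibration(
    seed: int,
    n_null: int = 1000,
    n_ci: int = 500,
    n_pairs: int = 25,
    delta: float = 300.0,
) -> dict:
    """Type-I error of the insert-size test and coverage of the 95% size CI."""
    stats = LibraryStats(read_len=150, mu=400.0, sigma=50.0, n_sampled=100_000)
    rng = np.random.default_rng(seed + 7)
    hits = 0
    for _ in range(n_null):
        sizes = rng.normal(stats.mu, stats.sigma, n_pairs)
        if insert_size_test(list(sizes), stats, "DEL").p_value <= 0.05:
            hits += 1
    covered = 0
    for _ in range(n_ci):
        sizes = rng.normal(stats.mu + delta, stats.sigma, n_pairs)
        est = insert_size_test(list(sizes), stats, "DEL")
        if est.ci_lo <= delta <= est.ci_hi:
            covered += 1
    return {"type1_error": hits / n_null, "ci_coverage": covered / n_ci}
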