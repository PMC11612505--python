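"""Per-candidate features, insert-size statistics, filters and VCF I/O.

The insert-size test asks whether the read pairs bracketing a candidate are
drawn from the library's Normal(mu, sigma) insert-size distribution. For a
deletion the bracketing pairs' insert sizes shift up by the deleted length;
for a duplication, outward-oriented pairs appear whose reference gap plus mu
estimates the duplicated length. The one-sided z-test on the mean and the
normal-theory confidence interval are the concrete instantiation of that
idea used throughout this package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .core import GenomeInterval, LibraryStats
from .split_caller import CandidateCNV

ALPHA = 0.05


def f32(x: float) -> float:
    """Quantize so a value survives the VCF text round trip bit-exactly.

    htslib prints floats with six significant digits; quantizing through
    that text form (and float32) makes write -> read the identity.
    """
    return float(np.float32(float(f"{np.float32(x):.6g}")))


@dataclass(frozen=True)
class SizeEstimate:
    point: float
    ci_lo: float
    ci_hi: float
    p_value: float
    n_pairs: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value outside [0, 1]")


@dataclass
class CNVFeatures:
    support_sr: int = 0
    support_hsr: int = 0
    support_disc: int = 0
    concordant_span: int = 0
    mean_mapq: float = 60.0
    junction_score: int = 0
    junction_score_ratio: float = 0.0
    depth_event: float = 0.0
    depth_left_flank: float = 0.0
    depth_right_flank: float = 0.0
    flank_degraded: bool = False
    size_est: SizeEstimate = field(
        default_factory=lambda: SizeEstimate(0.0, 0.0, 0.0, 1.0, 0)
    )

    def as_vector(self) -> np.ndarray:
        flank = max(1e-9, (self.depth_left_flank + self.depth_right_flank) / 2)
        return np.array(
            [
                self.support_sr,
                self.support_hsr,
                self.support_disc,
                self.concordant_span,
                self.mean_mapq,
                self.junction_score,
                self.junction_score_ratio,
                self.depth_event,
                self.depth_left_flank,
                self.depth_right_flank,
                self.depth_event / flank,
                self.size_est.p_value,
                self.size_est.n_pairs,
            ],
            dtype=float,
        )


FEATURE_NAMES = [
    "support_sr",
    "support_hsr",
    "support_disc",
    "concordant_span",
    "mean_mapq",
    "junction_score",
    "junction_score_ratio",
    "depth_event",
    "depth_left_flank",
    "depth_right_flank",
    "depth_ratio",
    "pval",
    "n_pairs",
]


@dataclass
class CallRecord:
    candidate: CandidateCNV
    features: CNVFeatures
    filter: tuple[str, ...] = ("PASS",)
    genotype: str = "./."

    @property
    def passed(self) -> bool:
        return self.filter == ("PASS",)


def collect_spanning_insert_sizes(
    cnv: CandidateCNV,
    fr_pairs: Sequence[tuple[int, int, int]],
    outward_pairs: Sequence[tuple[int, int, int]],
    stats: LibraryStats,
) -> list[float]:
    """Insert-size observations for the pairs bracketing a candidate.

    ``fr_pairs`` are concordant-orientation pairs as (fwd_end, rev_start,
    abs_insert); ``outward_pairs`` are duplication-type pairs as (rev_start,
    fwd_end, span) where span is the reference gap between the inward-facing
    read ends. For deletions, returns insert sizes of pairs whose forward
    read ends at/before the start and whose reverse read starts at/after the
    end; for duplications, returns spans of outward pairs bracketing the
    interval (within max_IS).
    """
    iv = cnv.interval
    out: list[float] = []
    if cnv.svtype == "DEL":
        for fwd_end, rev_start, ins in fr_pairs:
            if fwd_end <= iv.start and rev_start >= iv.end:
                out.append(float(ins))
    else:
        max_is = stats.max_is
        for rev_start, fwd_end, span in outward_pairs:
            if rev_start >= iv.start - max_is and fwd_end <= iv.end + max_is:
                out.append(float(span))
    return out


def insert_size_test(
    sizes: Sequence[float], stats: LibraryStats, svtype: str = "DEL"
) -> SizeEstimate:
    """Point estimate, 95% CI and one-sided p-value for the event size.

    DEL: observations are insert sizes; the size estimate is mean - mu and
    the p-value is the upper-tail probability of the observed mean under
    sizes ~ Normal(mu, sigma) iid. DUP: observations are outward-pair spans;
    the size estimate is mean span + mu, tested one-sided against a true
    size of zero. Empty input yields p = 1 and an unbounded interval.
    """
    n = len(sizes)
    if n == 0:
        return SizeEstimate(0.0, -math.inf, math.inf, 1.0, 0)
    mean = float(np.mean(sizes))
    se = stats.sigma / math.sqrt(n)
    shift = (mean - stats.mu) if svtype == "DEL" else (mean + stats.mu)
    point = shift
    if se > 0:
        p = float(sps.norm.sf(shift / se))
        half = 1.959963984540054 * se
    else:
        p = 0.5 if shift == 0 else (0.0 if shift > 0 else 1.0)
        half = 0.0
    return SizeEstimate(point, point - half, point + half, min(max(p, 0.0), 1.0), n)


def depth_features(
    cnv: CandidateCNV,
    coverage: np.ndarray,
    read_len: int,
) -> tuple[float, float, float, bool]:
    """Mean per-base depth over the event and its two flank windows.

    Flanks are max(2 * read_len, 300) bp each side; a flank truncated by a
    contig edge flags the result as degraded.
    """
    iv = cnv.interval
    flank = max(2 * read_len, 300)
    ev = float(coverage[iv.start : iv.end].mean()) if iv.length else 0.0
    lf_lo = max(0, iv.start - flank)
    lf = coverage[lf_lo : iv.start]
    rf = coverage[iv.end : iv.end + flank]
    degraded = len(lf) < flank or len(rf) < flank
    left = float(lf.mean()) if len(lf) else 0.0
    right = float(rf.mean()) if len(rf) else 0.0
    return ev, left, right, degraded


@dataclass(frozen=True)
class FilterConfig:
    min_support: int = 3
    alpha: float = ALPHA
    min_junction_ratio: float = 0.9
    depth_min_len: int = 300
    del_depth_max: float = 0.75
    dup_depth_min: float = 1.25


def hard_filter(
    features: CNVFeatures, candidate: CandidateCNV, config: FilterConfig = FilterConfig()
) -> tuple[str, ...]:
    """Fixed filters applied when no trained model is available.

    PASS requires: enough one-sided split/HSR support or discordant support;
    a significant insert-size p-value or a precise call with a near-perfect
    junction realignment; and, for events of at least ``depth_min_len``,
    depth consistent with the event type.
    """
    reasons: list[str] = []
    split_support = features.support_sr + features.support_hsr
    if split_support < config.min_support and features.support_disc < config.min_support:
        reasons.append("SUPPORT")
    stat_ok = features.size_est.p_value <= config.alpha or (
        candidate.precise and features.junction_score_ratio >= config.min_junction_ratio
    )
    if not stat_ok:
        reasons.append("PVALUE")
    if candidate.interval.length >= config.depth_min_len and not features.flank_degraded:
        flank = (features.depth_left_flank + features.depth_right_flank) / 2
        if flank > 0:
            ratio = features.depth_event / flank
            if candidate.svtype == "DEL" and ratio > config.del_depth_max:
                reasons.append("DEPTH")
            if candidate.svtype == "DUP" and ratio < config.dup_depth_min:
                reasons.append("DEPTH")
    return ("PASS",) if not reasons else tuple(reasons)


def rf_train(feature_matrix: np.ndarray, labels: np.ndarray, seed: int = 0):
    """Train the random-forest filter (200 balanced trees, fixed seed)."""
    from sklearn.ensemble import RandomForestClassifier

    X = np.asarray(feature_matrix, dtype=float)
    y = np.asarray(labels)
    if len(X) != len(y):
        raise ValueError("feature matrix and labels differ in length")
    model = RandomForestClassifier(
        n_estimators=200, class_weight="balanced", random_state=seed, n_jobs=1
    )
    model.fit(X, y)
    return model


def rf_apply(model, features: np.ndarray) -> np.ndarray:
    """PASS probability per candidate; a candidate passes at >= 0.5."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if len(getattr(model, "classes_", [0, 1])) == 1:
        return np.full(len(X), float(model.classes_[0]))
    return model.predict_proba(X)[:, 1]


def save_model(model, path: str) -> None:
    import joblib

    joblib.dump(model, path)


def load_model(path: str):
    import joblib

    return joblib.load(path)


# --------------------------------------------------------------------------
# VCF I/O

_INFO_LINES = [
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">',
    '##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">',
    '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length of the variant; negative for deletions">',
    '##INFO=<ID=IMPRECISE,Number=0,Type=Flag,Description="Imprecise structural variant">',
    '##INFO=<ID=CIPOS,Number=2,Type=Integer,Description="Confidence interval around POS">',
    '##INFO=<ID=CIEND,Number=2,Type=Integer,Description="Confidence interval around END">',
    '##INFO=<ID=SUPPORT_SR,Number=1,Type=Integer,Description="Supporting split reads">',
    '##INFO=<ID=SUPPORT_HSR,Number=1,Type=Integer,Description="Supporting hidden split reads">',
    '##INFO=<ID=SUPPORT_DISC,Number=1,Type=Integer,Description="Supporting discordant pairs">',
    '##INFO=<ID=PVAL,Number=1,Type=Float,Description="Insert-size test p-value">',
    '##INFO=<ID=DEPTH_EV,Number=1,Type=Float,Description="Mean depth over the event">',
    '##INFO=<ID=DEPTH_LF,Number=1,Type=Float,Description="Mean depth over the left flank">',
    '##INFO=<ID=DEPTH_RF,Number=1,Type=Float,Description="Mean depth over the right flank">',
    '##INFO=<ID=JRATIO,Number=1,Type=Float,Description="Junction realignment score over junction length">',
]

_FILTER_LINES = [
    '##FILTER=<ID=SUPPORT,Description="Too few supporting reads">',
    '##FILTER=<ID=PVALUE,Description="Insert-size statistics not supportive">',
    '##FILTER=<ID=DEPTH,Description="Read depth inconsistent with the event type">',
    '##FILTER=<ID=MODEL,Description="Rejected by the trained classification model">',
]


def write_vcf(
    calls: Sequence[CallRecord],
    contigs: Sequence[tuple[str, int]],
    path: str,
    ref_fetch=None,
) -> None:
    """Write calls as VCF 4.2 with symbolic <DEL>/<DUP> alleles.

    POS is the 1-based base preceding the event; REF is that base (or N when
    no reference is supplied). Calls must be coordinate-sorted.
    """
    import pysam

    last: tuple[str, int] | None = None
    order = {name: i for i, (name, _) in enumerate(contigs)}
    for rec in calls:
        key = (order[rec.candidate.interval.chrom], rec.candidate.interval.start)
        if last is not None and key < last:
            raise ValueError("calls must be sorted by chromosome and position")
        last = key

    header = pysam.VariantHeader()
    header.add_line("##source=hsrcnv")
    for line in _INFO_LINES + _FILTER_LINES:
        header.add_line(line)
    for name, length in contigs:
        header.add_line(f"##contig=<ID={name},length={length}>")
    header.add_sample("SAMPLE")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')

    with pysam.VariantFile(path, "w", header=header) as vf:
        for i, rec in enumerate(calls):
            cnv = rec.candidate
            iv = cnv.interval
            pos0 = max(0, iv.start - 1)
            ref_base = "N"
            if ref_fetch is not None:
                ref_base = ref_fetch(iv.chrom, pos0, pos0 + 1).upper() or "N"
            r = vf.new_record(
                contig=iv.chrom,
                start=pos0,
                stop=iv.end,
                alleles=(ref_base, f"<{cnv.svtype}>"),
                id=f"HSRCNV_{cnv.svtype}_{i + 1}",
            )
            r.info["SVTYPE"] = cnv.svtype
            r.info["SVLEN"] = -iv.length if cnv.svtype == "DEL" else iv.length
            if not cnv.precise:
                r.info["IMPRECISE"] = True
                r.info["CIPOS"] = (-cnv.ci, cnv.ci)
                r.info["CIEND"] = (-cnv.ci, cnv.ci)
            f = rec.features
            r.info["SUPPORT_SR"] = f.support_sr
            r.info["SUPPORT_HSR"] = f.support_hsr
            r.info["SUPPORT_DISC"] = f.support_disc
            r.info["PVAL"] = f32(f.size_est.p_value)
            r.info["DEPTH_EV"] = f32(f.depth_event)
            r.info["DEPTH_LF"] = f32(f.depth_left_flank)
            r.info["DEPTH_RF"] = f32(f.depth_right_flank)
            r.info["JRATIO"] = f32(f.junction_score_ratio)
            for reason in rec.filter:
                r.filter.add(reason)
            r.samples["SAMPLE"]["GT"] = (None, None)
            vf.write(r)


def read_vcf(path: str) -> list[CallRecord]:
    """Read a VCF written by write_vcf back into CallRecords."""
    import pysam

    out: list[CallRecord] = []
    with pysam.VariantFile(path) as vf:
        for r in vf:
            svtype = r.info["SVTYPE"]
            start = r.start + 1  # POS is the base before the event
            end = r.stop
            precise = "IMPRECISE" not in r.info
            ci = 0
            if not precise and "CIPOS" in r.info:
                ci = abs(int(r.info["CIPOS"][0]))
            cand = CandidateCNV(
                svtype=svtype,
                interval=GenomeInterval(r.chrom, start, end),
                precise=precise,
                source="SPLIT" if precise else "DISCORDANT",
                support_sr=int(r.info.get("SUPPORT_SR", 0)),
                support_hsr=int(r.info.get("SUPPORT_HSR", 0)),
                support_disc=int(r.info.get("SUPPORT_DISC", 0)),
                ci=ci,
            )
            feats = CNVFeatures(
                support_sr=cand.support_sr,
                support_hsr=cand.support_hsr,
                support_disc=cand.support_disc,
                junction_score_ratio=float(r.info.get("JRATIO", 0.0)),
                depth_event=float(r.info.get("DEPTH_EV", 0.0)),
                depth_left_flank=float(r.info.get("DEPTH_LF", 0.0)),
                depth_right_flank=float(r.info.get("DEPTH_RF", 0.0)),
                size_est=SizeEstimate(
                    0.0, -math.inf, math.inf, float(r.info.get("PVAL", 1.0)), 0
                ),
            )
            filt = tuple(r.filter.keys()) or ("PASS",)
            out.append(CallRecord(cand, feats, filt))
    return out


def write_features_tsv(calls: Sequence[CallRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            "chrom\tstart\tend\tsvtype\tprecise\tfilter\t" + "\t".join(FEATURE_NAMES) + "\n"
        )
        for rec in calls:
            iv = rec.candidate.interval
            vec = "\t".join(f"{v:.6g}" for v in rec.features.as_vector())
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{rec.candidate.svtype}\t"
                f"{int(rec.candidate.precise)}\t{';'.join(rec.filter)}\t{vec}\n"
            )
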