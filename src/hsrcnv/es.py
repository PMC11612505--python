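"""Expected-support score and read-support classification for CNV alleles.

The ES score of a CNV is the fraction of all length-l reads from the CNV
allele that contain a breakpoint and align strictly better to the CNV
allele than to the reference window. It is a property of the two alleles:
a full-unit event in a perfect tandem repeat has ES = 0 (every junction
read aligns perfectly to the reference as well), while an event with a
fully novel junction has ES = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

from .align import local_score, local_align, split_totals
from .core import DEFAULT_SCHEME, AlignmentScheme, GenomeInterval
from .split_caller import CandidateCNV

DEFAULT_FLANK = 2000

#: unaligned bases at a read end for the alignment to count as clipped
CLIP_MIN = 5


@dataclass(frozen=True)
class AllelePair:
    """Reference and CNV-applied sequences around an event, with breakpoints.

    ``r_ref`` is the event span plus up to ``flank`` bases each side;
    ``r_cnv`` is the same window with the deletion removed or the extra
    tandem copy inserted. ``b1 <= b2`` are the breakpoint offsets on r_cnv
    (equal for deletions; the novel junction and the second copy's end for
    duplications).
    """

    r_ref: str
    r_cnv: str
    b1: int
    b2: int
    svtype: str
    flank_truncated: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.b1 <= self.b2 < len(self.r_cnv)):
            raise ValueError("breakpoints must be interior to the CNV allele")


@dataclass(frozen=True)
class ESResult:
    es: float
    n_total: int
    n_support: int


def build_allele_pair(cnv: CandidateCNV, ref_fetch, contig_len: int, flank: int = DEFAULT_FLANK) -> AllelePair:
    """Extract r_ref and construct r_cnv for an event, with flanks."""
    iv = cnv.interval
    if iv.start < 0 or iv.end > contig_len or iv.length <= 0:
        raise ValueError("CNV outside the contig")
    ws = max(0, iv.start - flank)
    we = min(contig_len, iv.end + flank)
    truncated = ws > iv.start - flank or we < iv.end + flank
    r_ref = ref_fetch(iv.chrom, ws, we).upper()
    left = iv.start - ws
    d = iv.length
    if cnv.svtype == "DEL":
        r_cnv = r_ref[:left] + r_ref[left + d :]
        b1 = b2 = left
    else:
        r_cnv = r_ref[: left + d] + r_ref[left : left + d] + r_ref[left + d :]
        b1 = left + d  # novel junction between the two copies
        b2 = left + 2 * d  # end of the second copy
    return AllelePair(r_ref, r_cnv, b1, b2, cnv.svtype, truncated)


def enumerate_breakpoint_reads(allele: AllelePair, read_len: int) -> list[tuple[int, str]]:
    """All positioned reads of length l from r_cnv strictly containing a breakpoint.

    Reads are (start, sequence); identical sequences at distinct offsets are
    distinct reads.
    """
    l = read_len
    if l >= len(allele.r_cnv):
        raise ValueError("read length must be shorter than the CNV allele")
    starts: set[int] = set()
    for b in (allele.b1, allele.b2):
        lo = max(0, b - l + 1)
        hi = min(b, len(allele.r_cnv) - l) + 1
        for i in range(lo, hi):
            if i < b < i + l:
                starts.add(i)
    return [(i, allele.r_cnv[i : i + l]) for i in sorted(starts)]


def expected_support(
    allele: AllelePair, read_len: int, scheme: AlignmentScheme = DEFAULT_SCHEME
) -> ESResult:
    """Fraction of breakpoint reads aligning strictly better to the CNV allele.

    Each read is an exact substring of r_cnv, so its score there is its
    length; ties go to the reference (a tie means the read does not support
    the event).
    """
    reads = enumerate_breakpoint_reads(allele, read_len)
    n_support = 0
    for _, seq in reads:
        s_cnv = len(seq) * scheme.match
        s_ref = local_score(seq, allele.r_ref, scheme)
        if s_cnv > s_ref:
            n_support += 1
    n = len(reads)
    return ESResult(es=n_support / n if n else 0.0, n_total=n, n_support=n_support)


def classify_read_support(
    seq: str, allele: AllelePair, scheme: AlignmentScheme = DEFAULT_SCHEME
) -> str:
    """SPLIT, HSR or NONE for a read drawn from the CNV allele.

    SPLIT: clipped (>= 5 unaligned terminal bases) against r_ref but not
    against r_cnv. HSR: unclipped against r_ref with a strictly better score
    on r_cnv. NONE otherwise.
    """
    ref_aln = local_align(seq, allele.r_ref, scheme)
    cnv_aln = local_align(seq, allele.r_cnv, scheme)

    def clipped(res) -> bool:
        return res.query_start >= CLIP_MIN or len(seq) - res.query_end >= CLIP_MIN

    if clipped(ref_aln) and not clipped(cnv_aln):
        return "SPLIT"
    if not clipped(ref_aln) and cnv_aln.score > ref_aln.score:
        return "HSR"
    return "NONE"


def hsr_scan_region(
    reads: list[str],
    region_seq: str,
    region_start: int = 0,
    chrom: str = "",
    scheme: AlignmentScheme = DEFAULT_SCHEME,
    min_size: int = 50,
) -> list[CandidateCNV]:
    """Naive single-read split scanner over a region.

    Every read that does not align perfectly is split at every position; the
    best-scoring pair of independently aligned halves implies a deletion
    (reference gap) or duplication (reference overlap). All events of at
    least ``min_size`` are returned; this is deliberately unfiltered and
    noisy.
    """
    out: list[CandidateCNV] = []
    for seq in reads:
        n = len(seq)
        if n < 2:
            continue
        if local_score(seq, region_seq, scheme) >= n * scheme.match:
            continue  # aligns perfectly; excluded from the scan
        totals = split_totals(seq, region_seq, scheme)
        best_i = int(max(range(1, n), key=lambda i: (totals[i], -i)))
        left = local_align(seq[:best_i], region_seq, scheme)
        right = local_align(seq[best_i:], region_seq, scheme)
        if left.score <= 0 or right.score <= 0:
            continue
        e_l = region_start + left.ref_end
        s_r = region_start + right.ref_start
        if s_r > e_l:
            svtype, start, end = "DEL", e_l, s_r
        elif s_r < e_l:
            svtype, start, end = "DUP", s_r, e_l
        else:
            continue
        if end - start < min_size:
            continue
        out.append(
            CandidateCNV(
                svtype=svtype,
                interval=GenomeInterval(chrom, start, end),
                precise=True,
                source="SPLIT",
            )
        )
    return out
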