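"""Consensus piling, pairing, junction assembly and realignment."""

import itertools

from hsrcnv.core import GenomeInterval, LibraryStats
from hsrcnv.evidence import Side
from hsrcnv.split_caller import (
    CandidateCNV,
    ClipEvidence,
    Consensus,
    JunctionSequence,
    assemble_junction_from_pair,
    best_suffix_prefix_overlap,
    canonicalize_clip,
    extend_unpaired,
    left_align_interval,
    opposite_breakpoint_range,
    pair_consensuses,
    pile_consensuses,
    realign_junction,
)

from .conftest import random_dna

STATS = LibraryStats(read_len=150, mu=400.0, sigma=50.0, n_sampled=10_000)


def _ev(name, side, pos, anchor, tail, mapq=60, mate=None, hsr=False):
    return ClipEvidence(name, side, pos, anchor, tail, mapq, mate, hsr)


class TestPiling:
    def test_unanimous_pile(self):
        evs = [_ev(f"r{i}", Side.RIGHT_CLIP, 500, "ACGTACGT", "TTGGCC") for i in range(5)]
        (cons,) = pile_consensuses(evs, Side.RIGHT_CLIP)
        assert cons.support == 5
        assert cons.breakpoint == 500
        assert cons.sequence == "ACGTACGTTTGGCC"
        assert cons.clip_offset == 8

    def test_two_reads_insufficient(self):
        evs = [_ev(f"r{i}", Side.RIGHT_CLIP, 500, "ACGT", "TTGG") for i in range(2)]
        assert pile_consensuses(evs, Side.RIGHT_CLIP) == []

    def test_plurality_wins_split_column(self):
        evs = [
            _ev("a", Side.RIGHT_CLIP, 500, "ACGT", "TTGG"),
            _ev("b", Side.RIGHT_CLIP, 500, "ACGT", "TTGG"),
            _ev("c", Side.RIGHT_CLIP, 500, "ACGT", "TAGG"),
        ]
        (cons,) = pile_consensuses(evs, Side.RIGHT_CLIP)
        assert cons.sequence == "ACGTTTGG"

    def test_mapq_zero_cannot_seed(self):
        evs = [_ev(f"r{i}", Side.RIGHT_CLIP, 500, "ACGT", "TTGG", mapq=0) for i in range(4)]
        assert pile_consensuses(evs, Side.RIGHT_CLIP) == []

    def test_distant_positions_form_separate_clusters(self):
        evs = [
            _ev(f"a{i}", Side.RIGHT_CLIP, 500, "ACGT", "TTGG") for i in range(3)
        ] + [_ev(f"b{i}", Side.RIGHT_CLIP, 900, "GGCC", "AATT") for i in range(3)]
        clusters = pile_consensuses(evs, Side.RIGHT_CLIP)
        assert [c.breakpoint for c in clusters] == [500, 900]

    def test_jittered_clips_align_by_offset(self):
        # clip at 501 with one extra anchor base is the same junction
        evs = [
            _ev("a", Side.RIGHT_CLIP, 500, "ACGT", "TTGGC"),
            _ev("b", Side.RIGHT_CLIP, 500, "ACGT", "TTGGC"),
            _ev("c", Side.RIGHT_CLIP, 501, "ACGTT", "TGGCA"),
        ]
        (cons,) = pile_consensuses(evs, Side.RIGHT_CLIP)
        assert cons.breakpoint == 500
        assert cons.sequence == "ACGTTTGGCA"


class TestOppositeRange:
    def _cons(self, side, bp, mates):
        members = [_ev(f"r{i}", side, bp, "ACGT", "TTGG", mate=m) for i, m in enumerate(mates)]
        return Consensus(side, bp, "ACGTTTGG", 4, len(members), 0, 60.0, members)

    def test_right_clip_range_from_mates(self):
        cons = self._cons(Side.RIGHT_CLIP, 11_500, [12_000, 12_150])
        rng = opposite_breakpoint_range(cons, STATS, "chr1", 10**6)
        assert (rng.start, rng.end) == (12_000, 12_150 + 150 + 550)

    def test_no_mates_falls_back_degraded(self):
        cons = self._cons(Side.RIGHT_CLIP, 11_500, [None])
        rng = opposite_breakpoint_range(cons, STATS, "chr1", 10**6)
        assert (rng.start, rng.end) == (11_500, 12_050)
        assert cons.range_degraded

    def test_left_clip_range_mirrored(self):
        cons = self._cons(Side.LEFT_CLIP, 12_000, [11_200, 11_400])
        rng = opposite_breakpoint_range(cons, STATS, "chr1", 10**6)
        assert (rng.start, rng.end) == (11_200 - 550, 11_400 + 150)

    def test_range_clipped_to_chromosome(self):
        cons = self._cons(Side.LEFT_CLIP, 300, [100])
        rng = opposite_breakpoint_range(cons, STATS, "chr1", 10**6)
        assert rng.start == 0


def _cons_at(side, bp, support, range_lo, range_hi):
    c = Consensus(side, bp, "A" * 40, 20, support, 0, 60.0, [])
    c.opposite_range = GenomeInterval("chr1", range_lo, range_hi)
    return c


class TestPairing:
    def test_mutual_ranges_pair(self):
        r = _cons_at(Side.RIGHT_CLIP, 1000, 5, 1200, 2000)
        l = _cons_at(Side.LEFT_CLIP, 1500, 5, 500, 1100)
        pairs, unpaired = pair_consensuses([l], [r])
        assert pairs == [(r, l)] and unpaired == []

    def test_disjoint_ranges_stay_unpaired(self):
        r = _cons_at(Side.RIGHT_CLIP, 1000, 5, 5000, 6000)
        l = _cons_at(Side.LEFT_CLIP, 1500, 5, 500, 1100)
        pairs, unpaired = pair_consensuses([l], [r])
        assert pairs == [] and set(map(id, unpaired)) == {id(l), id(r)}

    def test_greedy_matches_exhaustive_on_small_instances(self):
        # two rights compete for one left: highest combined support wins,
        # verified against exhaustive matching over all one-to-one pairings
        r1 = _cons_at(Side.RIGHT_CLIP, 1000, 9, 1200, 2000)
        r2 = _cons_at(Side.RIGHT_CLIP, 1010, 4, 1200, 2000)
        l = _cons_at(Side.LEFT_CLIP, 1500, 5, 500, 1100)
        pairs, unpaired = pair_consensuses([l], [r1, r2])
        assert pairs == [(r1, l)]
        assert unpaired == [r2]

        def exhaustive_best(lefts, rights):
            best, best_support = None, -1
            for perm in itertools.permutations(range(len(rights)), len(lefts)):
                support = sum(lefts[i].support + rights[j].support for i, j in enumerate(perm))
                if support > best_support:
                    best_support, best = support, [(rights[j], lefts[i]) for i, j in enumerate(perm)]
            return best

        assert pairs == exhaustive_best([l], [r1, r2])

    def test_pairing_symmetric_in_input_order(self):
        r1 = _cons_at(Side.RIGHT_CLIP, 1000, 5, 1200, 2000)
        r2 = _cons_at(Side.RIGHT_CLIP, 3000, 5, 3200, 4000)
        l1 = _cons_at(Side.LEFT_CLIP, 1500, 5, 500, 1100)
        l2 = _cons_at(Side.LEFT_CLIP, 3500, 5, 2500, 3100)
        a, _ = pair_consensuses([l1, l2], [r1, r2])
        b, _ = pair_consensuses([l2, l1], [r2, r1])
        assert {(id(x), id(y)) for x, y in a} == {(id(x), id(y)) for x, y in b}


class TestJunctionAssembly:
    def _pair(self, rng, overlap, mismatches=0):
        # alt junction = X | Y; c1 carries X plus a Y prefix, c2 an X suffix plus Y
        x = random_dna(rng, 60)
        y = random_dna(rng, 60)
        tail1 = overlap // 2
        tail2 = overlap - tail1
        c1 = Consensus(Side.RIGHT_CLIP, 1000, x + y[:tail1], len(x), 5, 0, 60.0, [])
        c2seq = list(x[-tail2:] + y)
        for i in range(mismatches):
            c2seq[2 + i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[c2seq[2 + i]]
        c2 = Consensus(Side.LEFT_CLIP, 1300, "".join(c2seq), tail2, 5, 0, 60.0, [])
        return c1, c2, x, y

    def test_exact_overlap_merges(self, rng):
        c1, c2, x, y = self._pair(rng, 30)
        j = assemble_junction_from_pair((c1, c2))
        assert j is not None
        assert len(j.sequence) == len(c1.sequence) + len(c2.sequence) - 30
        assert j.junction_offset == c1.clip_offset
        assert j.sequence == x + y

    def test_small_overlap_rejected(self, rng):
        c1, c2, *_ = self._pair(rng, 10)
        assert assemble_junction_from_pair((c1, c2)) is None

    def test_overlap_with_one_mismatch_accepted(self, rng):
        c1, c2, *_ = self._pair(rng, 25, mismatches=1)  # 24/25 = 96% identity
        assert assemble_junction_from_pair((c1, c2)) is not None

    def test_low_identity_overlap_rejected(self, rng):
        c1, c2, *_ = self._pair(rng, 25, mismatches=5)  # 80% identity
        assert assemble_junction_from_pair((c1, c2)) is None


class TestSuffixPrefixOverlap:
    def test_exact(self):
        assert best_suffix_prefix_overlap("A" * 10 + "CGTACGTACGTACGTACGTA", "CGTACGTACGTACGTACGTA" + "T" * 10) == (20, 20)

    def test_below_floor(self):
        assert best_suffix_prefix_overlap("AAACGT", "ACGTTT") is None


class TestExtension:
    def test_planted_junction_recovered(self, rng):
        alt = random_dna(rng, 700)
        cons = Consensus(Side.RIGHT_CLIP, 1000, alt[100:280], 150, 5, 0, 60.0, [])
        reads = [alt[i : i + 150] for i in range(0, 550, 25)]
        j = extend_unpaired(cons, reads, 150)
        assert j is not None
        assert j.sequence in alt  # extension reproduces the planted sequence
        assert len(j.sequence) >= 1.5 * 150

    def test_no_overlapping_reads(self, rng):
        cons = Consensus(Side.RIGHT_CLIP, 1000, random_dna(rng, 180), 150, 5, 0, 60.0, [])
        assert extend_unpaired(cons, [random_dna(rng, 150) for _ in range(5)], 150) is None

    def test_tandem_repeat_extension_capped(self, rng):
        unit = random_dna(rng, 30)
        alt = unit * 40
        cons = Consensus(Side.RIGHT_CLIP, 1000, alt[:200], 150, 5, 0, 60.0, [])
        reads = [alt[i : i + 150] for i in range(0, 600, 10)]
        j = extend_unpaired(cons, reads, 150)
        assert j is not None
        assert len(j.sequence) <= 200 + 2 * 150  # novel growth capped at 2 read lengths

    def test_left_clip_extension_grows_leftwards(self, rng):
        alt = random_dna(rng, 700)
        # left-clipped consensus: tail (60) + anchor (120), clip at alt[400]
        cons = Consensus(Side.LEFT_CLIP, 2000, alt[340:520], 60, 5, 0, 60.0, [])
        reads = [alt[i : i + 150] for i in range(0, 550, 20)]
        j = extend_unpaired(cons, reads, 150)
        assert j is not None
        assert j.sequence in alt
        # the junction point still maps to the original clip column
        assert j.sequence[j.junction_offset :].startswith(alt[400:420])


class TestRealignment:
    def test_planted_deletion_reconstructed(self, rng):
        left = random_dna(rng, 400)
        deleted = random_dna(rng, 200)
        right = random_dna(rng, 400)
        window = left + deleted + right
        junction = JunctionSequence(left[-120:] + right[:120], 120, "PAIRED")
        cand = realign_junction(junction, window, 0)
        assert cand is not None
        assert cand.svtype == "DEL"
        assert (cand.interval.start, cand.interval.end) == (400, 600)
        assert cand.precise

    def test_abbbc_duplication_spans_single_unit(self, rng):
        # reference A B C; sample A B B B C: realigning the junction of the
        # extra copies yields a duplication covering exactly B
        a = random_dna(rng, 300)
        b = random_dna(rng, 90)
        c = random_dna(rng, 300)
        window = a + b + c
        junction = JunctionSequence(b[-60:] + b[:60], 60, "PAIRED")
        cand = realign_junction(junction, window, 0)
        assert cand is not None
        assert cand.svtype == "DUP"
        assert (cand.interval.start, cand.interval.end) == (300, 390)

    def test_zero_length_event_yields_none(self, rng):
        seq = random_dna(rng, 500)
        junction = JunctionSequence(seq[200:440], 120, "PAIRED")  # contiguous reference
        assert realign_junction(junction, seq, 0) is None

    def test_event_below_min_size_rejected(self, rng):
        left = random_dna(rng, 300)
        deleted = random_dna(rng, 40)
        right = random_dna(rng, 300)
        window = left + deleted + right
        junction = JunctionSequence(left[-100:] + right[:100], 100, "PAIRED")
        assert realign_junction(junction, window, 0, min_size=50) is None
        small = realign_junction(junction, window, 0, min_size=30)
        assert small is not None and small.interval.length == 40

    def test_realignment_inverts_construction(self, rng):
        """For planted DEL/DUP with unique flanks the junction realignment
        must reproduce the planted interval exactly."""
        for trial in range(100):
            svtype = "DEL" if trial % 2 == 0 else "DUP"
            size = rng.randint(50, 2000)
            left = random_dna(rng, 300)
            mid = random_dna(rng, size)
            right = random_dna(rng, 300)
            window = left + mid + right
            if svtype == "DEL":
                jseq, offset = left[-130:] + right[:130], 130
            else:
                k = min(130, size)  # junction of the two tandem copies
                jseq, offset = mid[-k:] + mid[:k], k
            junction = JunctionSequence(jseq, offset, "PAIRED")
            cand = realign_junction(junction, window, 0)
            assert cand is not None, (svtype, size)
            assert cand.svtype == svtype
            assert (cand.interval.start, cand.interval.end) == (300, 300 + size)


class TestLeftAlignAndCanonical:
    def test_left_align_shifts_through_repeat(self):
        seq = "T" * 100 + "ACAC" * 10 + "G" * 100  # AC repeat at [100, 140)

        def fetch(chrom, s, e):
            return seq[s:e]

        # deleting [120, 124) is equivalent to deleting [100, 104)
        assert left_align_interval(fetch, "c", 120, 124) == (100, 104)

    def test_left_align_unique_context_no_shift(self, rng):
        seq = random_dna(rng, 500)

        def fetch(chrom, s, e):
            return seq[s:e]

        s, e = left_align_interval(fetch, "c", 200, 260)
        shifted = s != 200
        # at most a short microhomology shift in random sequence
        assert e - s == 60 and 200 - s <= 12

    def test_canonicalize_right_clip_extends_anchor(self):
        ref = "AAAACCCCGGGGTTTT" * 10
        ev = ClipEvidence("r", Side.RIGHT_CLIP, 4, "AAAA", "CCCCTAAA", 60, None)
        canon = canonicalize_clip(ev, ref)
        assert canon.clip_pos == 8  # CCCC matches the reference and joins the anchor
        assert canon.anchor_seq.endswith("CCCC")
        assert canon.tail_seq == "TAAA"
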