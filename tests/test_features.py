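"""Insert-size statistics, depth features, filters, RF and VCF round trips."""

import math

import numpy as np
import pytest
from hsrcnv.core import GenomeInterval, LibraryStats
from hsrcnv.features import (
    CallRecord,
    CNVFeatures,
    FilterConfig,
    SizeEstimate,
    collect_spanning_insert_sizes,
    depth_features,
    f32,
    hard_filter,
    insert_size_test,
    read_vcf,
    rf_apply,
    rf_train,
    write_vcf,
)
from hsrcnv.split_caller import CandidateCNV

STATS = LibraryStats(read_len=150, mu=400.0, sigma=50.0, n_sampled=10_000)


def _cnv(start=10_000, end=10_300, svtype="DEL", precise=True):
    return CandidateCNV(svtype, GenomeInterval("chr1", start, end), precise,
                        "SPLIT" if precise else "DISCORDANT")


class TestCollectSpanning:
    def test_no_pairs_spanning(self):
        assert collect_spanning_insert_sizes(_cnv(), [], [], STATS) == []

    def test_deletion_bracketing_condition(self):
        fr = [
            (9_900, 10_350, 700),   # brackets: fwd ends before start, rev after end
            (10_050, 10_400, 500),  # forward read inside the event: excluded
            (9_900, 10_200, 450),   # reverse read inside the event: excluded
        ]
        sizes = collect_spanning_insert_sizes(_cnv(), fr, [], STATS)
        assert sizes == [700.0]

    def test_duplication_uses_outward_spans(self):
        out = [(9_800, 10_500, -100), (5_000, 5_600, -50)]
        sizes = collect_spanning_insert_sizes(_cnv(svtype="DUP"), [], out, STATS)
        assert sizes == [-100.0]

    def test_shifted_mean_tracks_deletion_size(self, np_rng):
        # homozygous 300-bp deletion: spanning inserts centre on mu + 300
        sizes = list(np_rng.normal(700, 50, 64))
        est = insert_size_test(sizes, STATS, "DEL")
        assert abs(est.point - 300) < 3 * 50 / math.sqrt(64)


class TestInsertSizeTest:
    def test_null_centre_gives_half(self):
        est = insert_size_test([400.0] * 30, STATS, "DEL")
        assert est.p_value == pytest.approx(0.5)
        assert est.point == 0

    def test_alpha_boundary_closed_form(self):
        n = 25
        mean = 400 + 1.6448536269514722 * 50 / math.sqrt(n)
        est = insert_size_test([mean] * n, STATS, "DEL")
        assert est.p_value == pytest.approx(0.05, abs=1e-6)

    def test_empty_input_degenerate(self):
        est = insert_size_test([], STATS, "DEL")
        assert est.p_value == 1.0 and est.n_pairs == 0
        assert est.ci_lo == -math.inf and est.ci_hi == math.inf

    def test_null_pvalues_uniform(self, np_rng):
        # under no CNV the one-sided p-value must be uniform: type-I error
        # at alpha=0.05 within Monte-Carlo noise
        hits = 0
        reps = 1000
        for _ in range(reps):
            sizes = np_rng.normal(STATS.mu, STATS.sigma, 30)
            if insert_size_test(list(sizes), STATS, "DEL").p_value <= 0.05:
                hits += 1
        assert abs(hits / reps - 0.05) < 0.02

    def test_ci_covers_true_size(self, np_rng):
        covered = 0
        reps = 500
        delta = 300
        for _ in range(reps):
            sizes = np_rng.normal(STATS.mu + delta, STATS.sigma, 25)
            est = insert_size_test(list(sizes), STATS, "DEL")
            if est.ci_lo <= delta <= est.ci_hi:
                covered += 1
        assert abs(covered / reps - 0.95) < 0.03

    def test_dup_size_estimate_from_spans(self):
        # spans of outward pairs around a duplication of length d centre on d - mu
        est = insert_size_test([-300.0] * 25, STATS, "DUP")
        assert est.point == pytest.approx(100.0)  # d ~ mu + mean span
        assert est.p_value < 0.05


class TestDepth:
    def test_uniform_coverage(self):
        cov = np.full(20_000, 30, dtype=np.int32)
        ev, lf, rf, degraded = depth_features(_cnv(), cov, 150)
        assert (ev, lf, rf) == (30.0, 30.0, 30.0) and not degraded

    def test_homozygous_deletion_depth_drop(self):
        cov = np.full(20_000, 30, dtype=np.int32)
        cov[10_000:10_300] = 0
        ev, lf, rf, _ = depth_features(_cnv(), cov, 150)
        assert ev == 0.0 and lf == 30.0 and rf == 30.0

    def test_contig_edge_flags_degraded(self):
        cov = np.full(10_400, 30, dtype=np.int32)
        ev, lf, rf, degraded = depth_features(_cnv(), cov, 150)
        assert degraded  # right flank truncated at the contig end


class TestHardFilter:
    def _features(self, **kw):
        base = dict(
            support_sr=10, support_hsr=0, support_disc=0,
            junction_score_ratio=0.95,
            depth_event=12.0, depth_left_flank=30.0, depth_right_flank=30.0,
            size_est=SizeEstimate(300, 250, 350, 1e-6, 20),
        )
        base.update(kw)
        return CNVFeatures(**base)

    def test_well_supported_precise_deletion_passes(self):
        assert hard_filter(self._features(), _cnv()) == ("PASS",)

    def test_imprecise_with_weak_pvalue_fails(self):
        feats = self._features(
            support_sr=0, support_disc=3, junction_score_ratio=0.0,
            size_est=SizeEstimate(0, -50, 50, 0.3, 5),
            depth_event=30.0,
        )
        cand = _cnv(precise=False)
        verdict = hard_filter(feats, cand)
        assert "PVALUE" in verdict and "PASS" not in verdict

    def test_two_supporting_reads_fail_support(self):
        feats = self._features(support_sr=2)
        assert "SUPPORT" in hard_filter(feats, _cnv())

    def test_depth_checked_only_for_long_events(self):
        feats = self._features(depth_event=30.0)  # no depth drop
        long_del = _cnv(start=10_000, end=10_400)
        short_del = _cnv(start=10_000, end=10_200)
        assert "DEPTH" in hard_filter(feats, long_del)
        assert hard_filter(feats, short_del) == ("PASS",)

    def test_duplication_requires_depth_gain(self):
        feats = self._features(depth_event=30.0, size_est=SizeEstimate(300, 250, 350, 1e-6, 20))
        dup = _cnv(svtype="DUP", start=10_000, end=10_400)
        assert "DEPTH" in hard_filter(feats, dup)
        feats = self._features(depth_event=45.0)
        assert hard_filter(feats, dup) == ("PASS",)


class TestRandomForest:
    def test_separable_features_high_accuracy(self, np_rng):
        n = 400
        X0 = np.column_stack([np_rng.normal(0, 1, n), np_rng.normal(0, 1, n)])
        X1 = np.column_stack([np_rng.normal(20, 1, n), np_rng.normal(0, 1, n)])
        X = np.vstack([X0, X1])
        y = np.array([0] * n + [1] * n)
        idx = np_rng.permutation(2 * n)
        train, test = idx[: n], idx[n :]
        model = rf_train(X[train], y[train], seed=0)
        acc = np.mean((rf_apply(model, X[test]) >= 0.5).astype(int) == y[test])
        assert acc >= 0.95

    def test_degenerate_single_class(self):
        X = np.ones((50, 3))
        model = rf_train(X, np.ones(50, dtype=int), seed=0)
        assert np.all(rf_apply(model, X) >= 0.5)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            rf_train(np.ones((10, 2)), np.ones(9), seed=0)


def _random_calls(np_rng, n=50):
    calls = []
    pos = 1_000
    for i in range(n):
        svtype = "DEL" if np_rng.random() < 0.5 else "DUP"
        length = int(np_rng.integers(50, 2_000))
        precise = bool(np_rng.random() < 0.7)
        cand = CandidateCNV(
            svtype, GenomeInterval("chr1", pos, pos + length), precise,
            "SPLIT" if precise else "DISCORDANT",
            support_sr=int(np_rng.integers(0, 30)),
            support_hsr=int(np_rng.integers(0, 30)),
            support_disc=int(np_rng.integers(0, 30)),
            ci=0 if precise else 400,
        )
        feats = CNVFeatures(
            support_sr=cand.support_sr,
            support_hsr=cand.support_hsr,
            support_disc=cand.support_disc,
            junction_score_ratio=f32(np_rng.random()),
            depth_event=f32(np_rng.random() * 60),
            depth_left_flank=f32(np_rng.random() * 60),
            depth_right_flank=f32(np_rng.random() * 60),
            size_est=SizeEstimate(0, -math.inf, math.inf, f32(np_rng.random()), 0),
        )
        filt = ("PASS",) if np_rng.random() < 0.8 else ("SUPPORT", "PVALUE")
        calls.append(CallRecord(cand, feats, filt))
        pos += length + int(np_rng.integers(100, 2_000))
    return calls


class TestVcfRoundTrip:
    CONTIGS = [("chr1", 10_000_000)]

    def test_round_trip_is_lossless(self, np_rng, tmp_path):
        calls = _random_calls(np_rng)
        path = str(tmp_path / "calls.vcf")
        write_vcf(calls, self.CONTIGS, path)
        back = read_vcf(path)
        assert len(back) == len(calls)
        for a, b in zip(calls, back):
            ia, ib = a.candidate.interval, b.candidate.interval
            assert (ia.chrom, ia.start, ia.end) == (ib.chrom, ib.start, ib.end)
            assert a.candidate.svtype == b.candidate.svtype
            assert a.candidate.precise == b.candidate.precise
            assert a.candidate.ci == b.candidate.ci
            assert a.filter == b.filter
            fa, fb = a.features, b.features
            assert fa.size_est.p_value == fb.size_est.p_value
            assert (fa.support_sr, fa.support_hsr, fa.support_disc) == (
                fb.support_sr, fb.support_hsr, fb.support_disc)
            assert (fa.depth_event, fa.depth_left_flank, fa.depth_right_flank) == (
                fb.depth_event, fb.depth_left_flank, fb.depth_right_flank)
            assert fa.junction_score_ratio == fb.junction_score_ratio

    def test_empty_callset_valid_header_only(self, tmp_path):
        path = str(tmp_path / "empty.vcf")
        write_vcf([], self.CONTIGS, path)
        assert read_vcf(path) == []
        text = open(path).read()
        assert text.startswith("##fileformat=VCF")
        assert "#CHROM" in text

    def test_unsorted_calls_rejected(self, np_rng, tmp_path):
        calls = _random_calls(np_rng, 5)[::-1]
        with pytest.raises(ValueError):
            write_vcf(calls, self.CONTIGS, str(tmp_path / "x.vcf"))

    def test_svlen_sign_convention(self, np_rng, tmp_path):
        calls = _random_calls(np_rng, 20)
        path = str(tmp_path / "sign.vcf")
        write_vcf(calls, self.CONTIGS, path)
        import pysam

        with pysam.VariantFile(path) as vf:
            for rec, call in zip(vf, calls):
                svlen = rec.info["SVLEN"]
                expect = call.candidate.interval.length
                if call.candidate.svtype == "DEL":
                    assert svlen == -expect
                else:
                    assert svlen == expect
                assert rec.stop == call.candidate.interval.end
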