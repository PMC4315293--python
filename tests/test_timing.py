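import numpy as np
import pytest

import cnvhotspots as ch
from cnvhotspots.timing import (LateRule, _collect_weighted, read_timing_bedgraph,
                                weighted_median, write_timing_bedgraph)

from _oracles import nearest_probe_values, perbp_weighted_mean


def _chip_track(values, seg=100):
    n = len(values)
    return ch.TimingTrack("repli_chip_log2ratio", {
        "c": (np.arange(n) * seg, (np.arange(n) + 1) * seg, np.asarray(values, dtype=float))})


class TestProjectProbes:
    def test_midpoint_rule(self):
        track = ch.project_probes({"c": (np.array([100, 300]), np.array([1.0, -1.0]))},
                                  {"c": 400})
        s, e, v = track.segments("c")
        np.testing.assert_array_equal(s, [0, 200])
        np.testing.assert_array_equal(e, [200, 400])
        np.testing.assert_array_equal(v, [1.0, -1.0])

    def test_single_probe_errors(self):
        with pytest.raises(ValueError, match=">= 2 probes"):
            ch.project_probes({"c": (np.array([100]), np.array([1.0]))}, {"c": 400})

    def test_duplicate_positions_error(self):
        with pytest.raises(ValueError, match="duplicate"):
            ch.project_probes({"c": (np.array([5, 5]), np.array([1.0, 2.0]))}, {"c": 400})

    def test_matches_nearest_probe_brute_force(self, rng):
        size = 5000
        pos = np.sort(rng.choice(np.arange(10, size - 10), size=50, replace=False))
        ratio = rng.normal(size=50)
        track = ch.project_probes({"c": (pos, ratio)}, {"c": size})
        want = nearest_probe_values(pos, ratio, size)
        got = np.array([track.point_value("c", bp) for bp in range(size)])
        # the midpoint-boundary bp itself may tie either way; allow both
        mismatch = got != want
        for bp in np.flatnonzero(mismatch):
            d = np.abs(pos - bp)
            two_best = np.sort(d)[:2]
            assert two_best[0] == two_best[1] or abs(two_best[0] - two_best[1]) <= 1


class TestIntervalTiming:
    def test_uniform_identity(self):
        track = _chip_track([70.0] * 10)
        assert ch.interval_timing(ch.GenomicInterval("c", 0, 1000), track) == 70.0

    def test_half_and_half(self):
        track = _chip_track([20.0, 80.0], seg=500)
        assert ch.interval_timing(ch.GenomicInterval("c", 0, 1000), track) == 50.0

    def test_no_coverage_gives_nan(self):
        track = _chip_track([1.0])
        assert np.isnan(ch.interval_timing(ch.GenomicInterval("d", 0, 10), track))
        assert np.isnan(ch.interval_timing(ch.GenomicInterval("c", 5000, 6000), track))

    def test_fuzz_vs_perbp_oracle(self, rng):
        n = 40
        starts = np.cumsum(rng.integers(0, 50, n)) + np.arange(n) * 100
        ends = starts + rng.integers(1, 100, n)
        vals = rng.normal(size=n)
        track = ch.TimingTrack("repli_seq_score", {"c": (starts, ends, vals)})
        hi = int(ends[-1])
        for _ in range(200):
            s = int(rng.integers(0, hi - 1))
            e = int(rng.integers(s + 1, hi + 1))
            want = perbp_weighted_mean(starts, ends, vals, (s, e))
            got = ch.interval_timing(ch.GenomicInterval("c", s, e), track)
            if np.isnan(want):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-9)

    def test_union_mean_is_weighted_mean_of_parts(self):
        track = _chip_track([1.0, 2.0, 3.0, 4.0], seg=250)
        a = ch.GenomicInterval("c", 0, 250)
        b = ch.GenomicInterval("c", 250, 1000)
        whole = ch.interval_timing(ch.GenomicInterval("c", 0, 1000), track)
        parts = (ch.interval_timing(a, track) * 250 + ch.interval_timing(b, track) * 750) / 1000
        assert whole == pytest.approx(parts)


class TestLateSegments:
    def test_strict_below_not_merged_across_intervening(self):
        track = _chip_track([-1.0, -0.5, -0.9])
        late = ch.late_segments(track, LateRule("repli_chip_below", -0.8))
        assert [(iv.start, iv.end) for iv in late.segments] == [(0, 100), (200, 300)]

    def test_boundary_is_strict(self):
        track = _chip_track([-0.8])
        late = ch.late_segments(track, LateRule("repli_chip_below", -0.8))
        assert late.segments == []

    def test_all_above_threshold_empty(self):
        track = _chip_track([0.5, 1.0])
        assert ch.late_segments(track, LateRule("repli_chip_below", -0.8)).segments == []

    def test_adjacent_late_segments_merge(self):
        track = _chip_track([-1.0, -0.9, 0.0])
        late = ch.late_segments(track, LateRule("repli_chip_below", -0.8))
        assert [(iv.start, iv.end) for iv in late.segments] == [(0, 200)]

    def test_incompatible_rule_rejected(self):
        track = ch.TimingTrack("repli_seq_score", {"c": (np.array([0]), np.array([10]),
                                                         np.array([50.0]))})
        with pytest.raises(ValueError, match="incompatible"):
            ch.late_segments(track, LateRule("repli_chip_below", -0.8))

    def test_matches_scan_oracle(self, rng):
        vals = rng.normal(-0.8, 0.3, size=100)
        track = _chip_track(vals)
        late = ch.late_segments(track, LateRule("repli_chip_below", -0.8))
        bm = np.repeat(vals < -0.8, 100)
        got = np.zeros(10_000, dtype=bool)
        for iv in late.segments:
            got[iv.start:iv.end] = True
        np.testing.assert_array_equal(got, bm)

    def test_permissive_threshold_is_superset(self, rng):
        vals = rng.normal(-0.8, 0.3, size=200)
        track = _chip_track(vals)
        tight = ch.late_segments(track, LateRule("repli_chip_below", -0.9))
        loose = ch.late_segments(track, LateRule("repli_chip_below", -0.5))
        bm_t = np.zeros(20_000, dtype=bool)
        bm_l = np.zeros(20_000, dtype=bool)
        for iv in tight.segments:
            bm_t[iv.start:iv.end] = True
        for iv in loose.segments:
            bm_l[iv.start:iv.end] = True
        assert np.all(bm_l[bm_t])


class TestStratifyByTranscription:
    def test_no_tus_genome_equals_untranscribed(self, default_dataset):
        ds = default_dataset
        out = ch.stratify_timing_by_transcription(ds.genome, [], ds.timing)
        h = out["histograms"]
        g = h[h.stratum == "genome"]["percent"].to_numpy()
        u = h[h.stratum == "untranscribed"]["percent"].to_numpy()
        t = h[h.stratum == "transcribed"]["percent"].to_numpy()
        np.testing.assert_allclose(g, u)
        assert t.sum() == 0

    def test_traces_sum_to_100(self, default_dataset):
        ds = default_dataset
        out = ch.stratify_timing_by_transcription(ds.genome, ds.tus, ds.timing)
        for name, sub in out["histograms"].groupby("stratum"):
            assert sub["percent"].sum() == pytest.approx(100.0, abs=1e-6)

    def test_bp_conservation(self, default_dataset):
        ds = default_dataset
        out = ch.stratify_timing_by_transcription(ds.genome, ds.tus, ds.timing)
        s = out["summary"].set_index("stratum")["bp"]
        assert s["transcribed"] + s["untranscribed"] == s["genome"] == ds.genome.mappable_bp

    def test_transcribed_earlier_than_untranscribed(self, default_dataset):
        # generator builds transcribed bp on an early baseline
        ds = default_dataset
        out = ch.stratify_timing_by_transcription(ds.genome, ds.tus, ds.timing)
        s = out["summary"].set_index("stratum")["mean_timing"]
        assert s["transcribed"] > s["untranscribed"]  # higher score = earlier


class TestTimingByTuLength:
    def test_flat_profile_when_timing_constant(self):
        track = _chip_track([42.0] * 100, seg=10_000)
        tus = [ch.TranscriptionUnit(ch.GenomicInterval("c", i * 100_000, i * 100_000 + L), "+", 1.0)
               for i, L in enumerate([50_000, 90_000, 70_000])]
        df, _ = ch.timing_by_tu_length(tus, track)
        assert (df["median_timing"] == 42.0).all()

    def test_empty_bins_omitted(self):
        track = _chip_track([1.0] * 100, seg=10_000)
        tus = [ch.TranscriptionUnit(ch.GenomicInterval("c", 0, 50_000), "+", 1.0),
               ch.TranscriptionUnit(ch.GenomicInterval("c", 100_000, 900_000), "+", 1.0)]
        df, _ = ch.timing_by_tu_length(tus, track)
        assert len(df) == 2  # no zero-filled bins between

    def test_genome_median_reference(self, default_dataset):
        ds = default_dataset
        _, ref = ch.timing_by_tu_length(ds.tus, ds.timing, genome=ds.genome)
        values, weights = _collect_weighted(ds.timing, ds.genome.mappable_intervals())
        assert ref == weighted_median(values, weights)


class TestTimingByExpression:
    def test_single_stratum_reproduces_transcribed_trace(self, default_dataset):
        ds = default_dataset
        vals = ds.timing.values()
        edges = np.linspace(vals.min(), vals.max() + 1e-9, 41)
        one = ch.timing_by_expression(ds.tus, ds.timing, quantile_edges=(), bin_edges=edges)
        strat = ch.stratify_timing_by_transcription(ds.genome, ds.tus, ds.timing,
                                                    bin_edges=edges)
        t = strat["histograms"]
        txn = t[t.stratum == "transcribed"]["percent"].to_numpy()
        got = one["percent"].to_numpy()
        # single stratum covers all TU bp; differs from the transcribed trace
        # only by the mappability clip, which the generator keeps TU-free
        np.testing.assert_allclose(got, txn, atol=1e-9)

    def test_each_stratum_sums_to_100(self, default_dataset):
        ds = default_dataset
        df = ch.timing_by_expression(ds.tus, ds.timing)
        for _, sub in df.groupby("stratum"):
            assert sub["percent"].sum() == pytest.approx(100.0, abs=1e-6)

    def test_high_rpkm_stratum_is_earliest(self, default_dataset):
        # RPKM-length anticorrelation: intense TUs are short, hence early
        ds = default_dataset
        df = ch.timing_by_expression(ds.tus, ds.timing, quantile_edges=(0.5,))
        means = {}
        for name, sub in df.groupby("stratum"):
            mid = (sub["bin_left"] + sub["bin_right"]) / 2
            means[name] = float(np.average(mid, weights=sub["percent"]))
        low, high = sorted(means)  # 'rpkm_q0-0.5' < 'rpkm_q0.5-1'
        assert means[high] > means[low]


class TestTimingIO:
    def test_bedgraph_roundtrip(self, tmp_path, rng):
        vals = rng.normal(size=20)
        track = _chip_track(vals)
        p = tmp_path / "t.bedgraph"
        write_timing_bedgraph(track, p)
        back = read_timing_bedgraph(p, "repli_chip_log2ratio")
        s0, e0, v0 = track.segments("c")
        s1, e1, v1 = back.segments("c")
        np.testing.assert_array_equal(s0, s1)
        np.testing.assert_array_equal(v0, v1)
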