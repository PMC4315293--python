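import numpy as np
import pytest
import scipy.stats as st

import cnvhotspots as ch
from cnvhotspots.genome import FeatureSet
from cnvhotspots.regions import CNVCall

from _oracles import bitmap_fraction_overlap


def _call(chrom, s, e, t="deletion"):
    return CNVCall(interval=ch.GenomicInterval(chrom, s, e), cnv_type=t)


@pytest.fixture(scope="module")
def open_genome():
    return ch.MappableGenome({"chr1": 10_000_000})


class TestPermuteRegions:
    def test_uniform_start_distribution(self, open_genome):
        region = [ch.GenomicInterval("chr1", 0, 1_000_000)]
        starts = [placed[0].start
                  for placed in ch.permute_regions(region, open_genome, 1000, seed=7)]
        ks = st.kstest(np.asarray(starts) / 9_000_000, "uniform")
        assert ks.pvalue > 0.01

    def test_zero_iterations_rejected(self, open_genome):
        with pytest.raises(ValueError):
            list(ch.permute_regions([ch.GenomicInterval("chr1", 0, 10)], open_genome, 0, 1))

    def test_seed_reproducibility(self, open_genome):
        regions = [ch.GenomicInterval("chr1", 0, 1000), ch.GenomicInterval("chr1", 5000, 9000)]
        a = [tuple((iv.chrom, iv.start) for iv in it)
             for it in ch.permute_regions(regions, open_genome, 50, seed=3)]
        b = [tuple((iv.chrom, iv.start) for iv in it)
             for it in ch.permute_regions(regions, open_genome, 50, seed=3)]
        assert a == b

    def test_placements_stay_mappable(self, toy_genome):
        for placed in ch.permute_regions([ch.GenomicInterval("chrT", 0, 50_000)],
                                         toy_genome, 200, seed=9):
            iv = placed[0]
            pieces = toy_genome.subtract_excluded(iv)
            assert len(pieces) == 1 and pieces[0] == iv

    def test_oversized_region_errors(self, toy_genome):
        with pytest.raises(ValueError, match="mappable stretch"):
            list(ch.permute_regions([ch.GenomicInterval("chrT", 0, 900_000)],
                                    toy_genome, 1, seed=1))

    def test_no_overlap_mode(self, open_genome):
        regions = [ch.GenomicInterval("chr1", 0, 1_000_000)] * 3
        for placed in ch.permute_regions(regions, open_genome, 20, seed=5,
                                         allow_overlap=False):
            spans = sorted((iv.start, iv.end) for iv in placed)
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2


class TestScoreOverlap:
    def test_fraction_example(self):
        region = [ch.GenomicInterval("c", 0, 1_000_000)]
        feats = FeatureSet("f", [ch.GenomicInterval("c", 100_000, 300_000),
                                 ch.GenomicInterval("c", 500_000, 700_000)])
        assert ch.score_overlap(region, feats, "fraction_of_span")[0] == pytest.approx(0.4)

    def test_no_overlap_scores(self):
        region = [ch.GenomicInterval("c", 0, 1000)]
        feats = FeatureSet("f", [ch.GenomicInterval("c", 5000, 6000)])
        assert ch.score_overlap(region, feats, "boolean")[0] == 0
        assert ch.score_overlap(region, feats, "fraction_of_span")[0] == 0
        assert ch.score_overlap(region, feats, "longest_feature_bp")[0] == 0

    def test_longest_feature(self):
        region = [ch.GenomicInterval("c", 900, 1100)]
        feats = FeatureSet("f", [ch.GenomicInterval("c", 0, 1000),
                                 ch.GenomicInterval("c", 1050, 5050),
                                 ch.GenomicInterval("c", 2000, 9000)])  # no overlap
        assert ch.score_overlap(region, feats, "longest_feature_bp")[0] == 4000

    def test_length_weighted_mean_two_bins(self):
        track = ch.TimingTrack("repli_seq_score", {
            "c": (np.array([0, 500]), np.array([500, 1000]), np.array([10.0, 20.0]))})
        region = [ch.GenomicInterval("c", 0, 1000)]
        got = ch.score_overlap(region, FeatureSet("f", []), "length_weighted_mean",
                               signal=track)
        assert got[0] == pytest.approx(15.0)

    def test_signal_required(self):
        with pytest.raises(ValueError, match="signal"):
            ch.score_overlap([ch.GenomicInterval("c", 0, 10)], FeatureSet("f", []),
                             "length_weighted_mean")

    def test_fraction_fuzz_vs_bitmap(self, rng):
        size = 100_000
        feats = []
        for _ in range(20):
            s = int(rng.integers(0, size - 10))
            feats.append((s, min(size, s + int(rng.integers(1, 5000)))))
        fs = FeatureSet("f", [ch.GenomicInterval("c", s, e) for s, e in feats])
        for _ in range(100):
            s = int(rng.integers(0, size - 1))
            e = int(rng.integers(s + 1, size + 1))
            got = ch.score_overlap([ch.GenomicInterval("c", s, e)], fs, "fraction_of_span")[0]
            assert got == pytest.approx(bitmap_fraction_overlap((s, e), feats, size))


class TestEnrichmentTest:
    def test_add_one_rule_floor(self, open_genome):
        # actual overlaps fully, features tiny: actual should beat all iterations
        feats = FeatureSet("f", [ch.GenomicInterval("chr1", 0, 1000)])
        region = ch.merge_to_regions([_call("chr1", 0, 1000)])[0]
        res = ch.enrichment_test({"g": [region]}, feats, "fraction_of_span",
                                 open_genome, n_iter=999, seed=0)["g"]
        assert res.actual == 1.0
        assert res.p_emp == pytest.approx(1 / 1000)
        assert res.direction == "enriched"

    def test_saturated_features_give_p_one(self, open_genome):
        feats = FeatureSet("f", [ch.GenomicInterval("chr1", 0, 10_000_000)])
        region = ch.merge_to_regions([_call("chr1", 5, 1005)])[0]
        res = ch.enrichment_test({"g": [region]}, feats, "fraction_of_span",
                                 open_genome, n_iter=99, seed=0)["g"]
        assert res.actual == 1.0
        assert np.all(res.iterations == 1.0)
        assert res.p_emp == 1.0

    def test_planted_signal_power(self):
        """CNVs planted in TUs at >=10x background rate reach p < 0.01."""
        model = ch.SyntheticModel(
            cnvs=ch.CNVSpec(n_deletions=40, n_duplications=20,
                            baseline_rate_per_bp=3e-8),
            seed=11)
        ds = ch.generate(model)
        kept, _ = ch.filter_large_cnvs(ds.cnvs)
        regions = ch.merge_to_regions(kept)
        feats = FeatureSet("tus", [t.span for t in ds.tus])
        res = ch.enrichment_test({"all": regions}, feats, "fraction_of_span",
                                 ds.genome, n_iter=1000, seed=2)["all"]
        assert res.direction == "enriched" and res.p_emp < 0.01

    def test_seed_gives_bit_identical_result(self, open_genome):
        feats = FeatureSet("f", [ch.GenomicInterval("chr1", 0, 500_000)])
        region = ch.merge_to_regions([_call("chr1", 100, 2000)])[0]
        r1 = ch.enrichment_test({"g": [region]}, feats, "fraction_of_span",
                                open_genome, n_iter=200, seed=42)["g"]
        r2 = ch.enrichment_test({"g": [region]}, feats, "fraction_of_span",
                                open_genome, n_iter=200, seed=42)["g"]
        assert np.array_equal(r1.iterations, r2.iterations) and r1.p_emp == r2.p_emp


class TestClusteringSignificance:
    def test_two_interval_analytic_overlap(self, open_genome):
        """P(two uniform 1-Mb intervals merge at gap 0) == 1 - ((G-2l)/(G-l))^2."""
        cnvs = [_call("chr1", 0, 1_000_000), _call("chr1", 2_000_000, 3_000_000)]
        p = ch.clustering_significance(cnvs, open_genome, max_gap=0, k=2,
                                       n_iter=4000, seed=13)
        analytic = 1 - ((10e6 - 2e6) / (10e6 - 1e6)) ** 2
        assert p == pytest.approx(analytic, abs=0.025)

    def test_k_exceeding_cnv_count_hits_floor(self, open_genome):
        cnvs = [_call("chr1", 0, 1000), _call("chr1", 5000, 6000)]
        p = ch.clustering_significance(cnvs, open_genome, max_gap=0, k=5,
                                       n_iter=199, seed=1)
        assert p == pytest.approx(1 / 200)

    def test_k_below_two_rejected(self, open_genome):
        with pytest.raises(ValueError):
            ch.clustering_significance([_call("chr1", 0, 10)], open_genome, 0, 1, 10, 0)

    def test_span_pvalue_detects_planted_clustering(self, default_dataset):
        kept, _ = ch.filter_large_cnvs(default_dataset.cnvs)
        res = ch.clustering_pvalue(kept, default_dataset.genome, 750_000,
                                   n_iter=499, seed=3)
        assert res.direction == "depleted" and res.p_emp < 0.01


class TestPermuteTus:
    def test_all_tus_hit(self, open_genome):
        tus = [ch.TranscriptionUnit(ch.GenomicInterval("chr1", i * 100_000, i * 100_000 + 50_000),
                                    "+", 1.0) for i in range(5)]
        cnvs = [_call("chr1", 0, 9_999_999)]
        df = ch.permute_tus(tus, open_genome, cnvs, n_iter=20, seed=0,
                            length_bins=[10_000, 100_000])
        assert (df["actual_pct"] == 100.0).all()

    def test_no_cnvs(self, open_genome):
        tus = [ch.TranscriptionUnit(ch.GenomicInterval("chr1", 0, 50_000), "+", 1.0)]
        df = ch.permute_tus(tus, open_genome, [], n_iter=10, seed=0,
                            length_bins=[10_000, 100_000])
        assert (df["actual_pct"] == 0.0).all() and (df["perm_mean_pct"] == 0.0).all()

    def test_length_dependent_risk_shows_in_top_bin(self, default_dataset):
        ds = default_dataset
        kept, _ = ch.filter_large_cnvs(ds.cnvs)
        df = ch.permute_tus(ds.tus, ds.genome, kept, n_iter=200, seed=5,
                            length_bins=[0, 100_000, 500_000, 1_000_000, 3_000_000])
        actual = df["actual_pct"].to_numpy()
        excess = (df["actual_pct"] - df["perm_mean_pct"]).to_numpy()
        # CNV risk grows with TU length: actual rises monotonically with the
        # length bin, every planted >=1-Mb TU is hit, and the actual exceeds
        # the permuted baseline in the large-TU bins
        assert np.all(np.diff(actual) >= 0)
        assert actual[-1] == 100.0
        assert np.all(excess[-2:] > 0)
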