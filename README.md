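# cnvhotspots

Analysis toolkit for the genomics of replication-stress-induced structural
instability: where do de novo copy number variants (CNVs) cluster, and why
do the hottest loci coincide with common fragile sites (CFSs)?

The package implements, as a tested pipeline over synthetic data, the chain
of analyses linking CNV hotspots to **large active transcription units
(TUs)**: CNV region merging and hotspot calling, randomized-placement
Monte-Carlo statistics for clustering and feature enrichment, TU calling
from strand-specific nascent-RNA (Bru-seq-style) coverage, replication
timing integration (Repli-seq scores / Repli-chip ratios), and metagene
profiling of CNV placement and timing in TU percent coordinates. It is
aimed at genomicists who want each of those steps as a reusable,
independently tested primitive.

## The model in brief

- **Regions and hotspots.** De novo CNVs larger than 2.5 Mb are omitted;
  the rest are chained into regions whenever they overlap or lie within
  750 kb of each other. Regions are stratified by member count:
  singletons (1), clusters (2–4), hotspots (≥ 5).
- **Permutation null.** Every Monte-Carlo statistic re-places intervals
  (regions, individual CNVs, or TUs) uniformly among all start positions at
  which the interval fits entirely in mappable sequence. Overlap is scored
  as Boolean, fraction-of-span, longest-overlapped-feature, or a
  length-weighted signal mean; empirical p-values use the add-one rule
  `p = (1 + #extreme) / (n_iter + 1)`.
- **TU calling.** A TU is a contiguous strand-specific span whose nascent
  RNA signal exceeds an RPKM threshold (two-component Gaussian mixture of
  the log signal by default), with sub-threshold dropouts ≤ 10 kb bridged
  and spans < 10 kb dropped.
- **Percent coordinates.** Positions are mapped to a TSS = 0% / TES = 100%
  axis (strand aware); CNV spans increment every grid point they cross, and
  replication timing is rescaled to [0, 1] by the min/max within each TU.
- **Synthetic study conditions.** The generator plants a 200-TU population
  (five ≥ 1 Mb) on a 3 × 60-Mb genome and places 300 CNVs with locus risk
  proportional to `(L / N_s)²` — the double-fork-failure scaling for a TU of
  length `L` and median fork travel `N_s` = 300 kb — with deletions centered
  mid-TU and duplications on the flanks.

## Worked example

```sh
python analysis/01_simulate_data.py --seed 1   # writes results/simdata/
python analysis/02_cnv_regions.py
python analysis/07_association_stats.py
```

prints (seed 1):

```
300 CNVs, median size 189 kb; 0 omitted as > 2.5 Mb
52 CNV regions: 27 singletons, 15 clusters (2-4), 10 hotspots (>= 5)
most clustered region: chr1:33928123-38154775 with 70 CNVs
Fisher's exact test, CNV counts in genes with a matching long transcript
in both lines (15 vs 1) against genes without (20 vs 65):
odds ratio 48.8, two-sided p = 1.4e-07
CNV count vs region length:      Spearman r = 0.84 (n = 52, permutation p = 0.0001)
```

The 10 hotspots recover all five planted ≥ 1-Mb TUs; the Fisher example is
the classic 2×2 check that CNVs track the presence of a long active
transcript across cell lines. The remaining drivers
(`03`–`06`) add the permutation enrichment tables, TU calling
(99.5% of planted TU bp recovered), the monotone TU-length → later-timing
relationship, and the deletion-mid / duplication-flank percent-coordinate
profiles, each written as TSV under `results/`.

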