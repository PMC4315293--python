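#!/usr/bin/env python
"""Monte-Carlo clustering significance and TU enrichment of CNV regions.

Asks (i) whether the observed CNV clustering exceeds uniform random
placement, and (ii) whether CNV regions, stratified by class, overlap the
TU annotation more than randomly placed regions of the same lengths.
Also runs the reciprocal test: the fraction of TUs hit by >= 1 CNV per
TU-length bin, actual vs randomly placed TUs.
"""

import argparse
from pathlib import Path

import cnvhotspots as ch
from cnvhotspots.genome import FeatureSet, read_bed, read_chrom_sizes
from cnvhotspots.permutation import write_permutation_results
from cnvhotspots.regions import read_cnv_table
from cnvhotspots.tucall import read_tus_bed


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/simdata"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--n-iter", type=int, default=1000)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    sizes = read_chrom_sizes(args.data / "genome.chrom.sizes")
    excluded = read_bed(args.data / "excluded.bed").features
    genome = ch.MappableGenome(sizes, excluded)
    cnvs = read_cnv_table(args.data / "cnvs.tsv")
    tus = read_tus_bed(args.data / "tus_truth.bed")

    kept, _ = ch.filter_large_cnvs(cnvs)
    regions = ch.classify_regions(ch.merge_to_regions(kept))

    p5 = ch.clustering_significance(kept, genome, 750_000, k=5,
                                    n_iter=args.n_iter, seed=args.seed)
    span = ch.clustering_pvalue(kept, genome, 750_000,
                                n_iter=args.n_iter, seed=args.seed + 1)
    print(f"P(any uniform-placement region holds >= 5 CNVs) = {p5:.3g} "
          f"(at this synthetic CNV density chance clusters are common)")
    print(f"total-region-span clustering p = {span.p_emp:.3g} ({span.direction}: "
          f"observed regions are more compact than uniform placement)")

    groups = {}
    for r in regions:
        groups.setdefault(r.region_class, []).append(r)
    feats = FeatureSet("tus", [t.span for t in tus])
    args.out.mkdir(parents=True, exist_ok=True)
    for kind in ("boolean", "fraction_of_span", "longest_feature_bp"):
        res = ch.enrichment_test(groups, feats, kind, genome,
                                 n_iter=args.n_iter, seed=args.seed + 2)
        write_permutation_results(res, kind, args.out / f"enrichment_{kind}.tsv")
        for gname, r in sorted(res.items()):
            print(f"  {kind:>18s} {gname:>9s}: actual {r.actual:10.3f} vs "
                  f"null mean {r.iterations.mean():10.3f}  p={r.p_emp:.3g} ({r.direction})")

    bins = [0, 100_000, 500_000, 1_000_000,
            max(t.length for t in tus) + 1]
    df = ch.permute_tus(tus, genome, kept, n_iter=args.n_iter,
                        seed=args.seed + 3, length_bins=bins)
    df.to_csv(args.out / "tu_permutation_by_length.tsv", sep="\t", index=False)
    print("fraction of TUs overlapping >= 1 CNV, by TU length bin:")
    print(df.to_string(index=False))


if __name__ == "__main__":
    main()
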