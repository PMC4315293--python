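#!/usr/bin/env python
"""Merge CNV calls into regions and classify singletons/clusters/hotspots.

Reads the CNV table written by 01_simulate_data.py, drops events > 2.5 Mb,
chains calls separated by <= 750 kb into regions, and stratifies them by
member count (1 / 2-4 / >= 5). Writes the per-region summary table.
"""

import argparse
from collections import Counter
from pathlib import Path

import cnvhotspots as ch
from cnvhotspots.regions import read_cnv_table, write_regions_bed


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/simdata"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    cnvs = read_cnv_table(args.data / "cnvs.tsv")
    kept, omitted = ch.filter_large_cnvs(cnvs)
    regions = ch.classify_regions(ch.merge_to_regions(kept))
    summary = ch.region_summary(regions)

    args.out.mkdir(parents=True, exist_ok=True)
    summary.to_csv(args.out / "cnv_regions.tsv", sep="\t", index=False)
    write_regions_bed(regions, args.out / "cnv_regions.bed")

    sizes = sorted(c.interval.length for c in cnvs)
    classes = Counter(r.region_class for r in regions)
    print(f"{len(cnvs)} CNVs, median size {sizes[(len(sizes)-1)//2]/1000:.0f} kb; "
          f"{len(omitted)} omitted as > 2.5 Mb")
    print(f"{len(regions)} CNV regions: "
          f"{classes['singleton']} singletons, {classes['cluster']} clusters (2-4), "
          f"{classes['hotspot']} hotspots (>= 5)")
    biggest = summary.sort_values("count", ascending=False).iloc[0]
    print(f"most clustered region: {biggest.chrom}:{biggest.start}-{biggest.end} "
          f"with {biggest['count']} CNVs")
    print(f"wrote {args.out}/cnv_regions.tsv and .bed")


if __name__ == "__main__":
    main()
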