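#!/usr/bin/env python
"""Generate the default synthetic study dataset and write its input files.

Emulates the study's inputs on a small 3 x 60-Mb genome: a 200-TU population
with five planted >= 1-Mb units, strand-specific nascent-RNA coverage,
a replication-timing field that delays the middle of large TUs, and 300
CNVs placed with locus risk proportional to (TU length / N_s)^2.
Downstream scripts (02-07) read the files written here.
"""

import argparse
from pathlib import Path

import cnvhotspots as ch


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/simdata"))
    args = ap.parse_args()

    ds = ch.generate(ch.SyntheticModel(seed=args.seed))
    ds.write(args.out)

    n_large = int(ds.tu_is_large.sum())
    print(f"genome: {len(ds.genome.chrom_sizes)} chromosomes, "
          f"{ds.genome.mappable_bp / 1e6:.1f} Mb mappable")
    print(f"TUs: {len(ds.tus)} total, {n_large} planted >= 1 Mb")
    print(f"CNVs: {len(ds.cnvs)} "
          f"({sum(c.cnv_type == 'deletion' for c in ds.cnvs)} deletions, "
          f"{sum(c.cnv_type == 'duplication' for c in ds.cnvs)} duplications)")
    print(f"wrote input files to {args.out}/")


if __name__ == "__main__":
    main()
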