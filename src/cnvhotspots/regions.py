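"""CNV region construction: size filtering, gap-merging, and class calls.

De novo CNV calls are merged into regions by single-linkage chaining:
two calls share a region iff they are connected by pairs that overlap or
are separated by at most ``max_gap`` bp (gap exactly equal to the limit
merges). Regions are then stratified by member count into singletons (1),
clusters (2-4), and hotspots (>= 5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .genome import GenomicInterval

DEFAULT_MAX_CNV_SIZE = 2_500_000   # larger events are dropped before merging
DEFAULT_MAX_GAP = 750_000
DEFAULT_HOTSPOT_MIN = 5
DEFAULT_CLUSTER_MIN = 2

CNV_TYPES = ("deletion", "duplication")


@dataclass(frozen=True)
class CNVCall:
    interval: GenomicInterval
    cnv_type: str
    sample_id: str = ""
    condition: str = ""
    genotype: str | None = None

    def __post_init__(self) -> None:
        if self.cnv_type not in CNV_TYPES:
            raise ValueError(f"cnv_type must be one of {CNV_TYPES}, got {self.cnv_type!r}")


@dataclass
class CNVRegion:
    span: GenomicInterval
    members: list[CNVCall]
    region_class: str | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("CNVRegion requires at least one member CNV")
        chroms = {m.interval.chrom for m in self.members}
        if chroms != {self.span.chrom}:
            raise ValueError("member CNVs on a different chromosome than the span")
        lo = min(m.interval.start for m in self.members)
        hi = max(m.interval.end for m in self.members)
        if (self.span.start, self.span.end) != (lo, hi):
            raise ValueError("span is not the minimal cover of the members")

    @property
    def count(self) -> int:
        return len(self.members)


def filter_large_cnvs(
    cnvs: list[CNVCall], max_size: int = DEFAULT_MAX_CNV_SIZE
) -> tuple[list[CNVCall], list[CNVCall]]:
    """Split calls into (kept, omitted) with omitted strictly larger than ``max_size``."""
    if max_size <= 0:
        raise ValueError("max_size must be positive")
    kept = [c for c in cnvs if c.interval.length <= max_size]
    omitted = [c for c in cnvs if c.interval.length > max_size]
    return kept, omitted


def merge_to_regions(cnvs: list[CNVCall], max_gap: int = DEFAULT_MAX_GAP) -> list[CNVRegion]:
    """Single-linkage chain CNVs into regions; gap <= max_gap merges.

    Merging deliberately ignores cnv_type and condition — regions mix
    deletions/duplications and treatments; the members keep their labels for
    downstream stratification.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    ordered = sorted(cnvs, key=lambda c: (c.interval.chrom, c.interval.start, c.interval.end))
    regions: list[CNVRegion] = []
    bucket: list[CNVCall] = []
    cur_end = -1
    for call in ordered:
        iv = call.interval
        if bucket and iv.chrom == bucket[0].interval.chrom and iv.start - cur_end <= max_gap:
            bucket.append(call)
            cur_end = max(cur_end, iv.end)
        else:
            if bucket:
                regions.append(_close(bucket))
            bucket = [call]
            cur_end = iv.end
    if bucket:
        regions.append(_close(bucket))
    return regions


def _close(members: list[CNVCall]) -> CNVRegion:
    chrom = members[0].interval.chrom
    span = GenomicInterval(chrom,
                           min(m.interval.start for m in members),
                           max(m.interval.end for m in members))
    return CNVRegion(span=span, members=list(members))


def classify_regions(
    regions: list[CNVRegion],
    hotspot_min: int = DEFAULT_HOTSPOT_MIN,
    cluster_min: int = DEFAULT_CLUSTER_MIN,
) -> list[CNVRegion]:
    """Assign singleton/cluster/hotspot by member count (in place; returns list)."""
    if not hotspot_min > cluster_min >= 2:
        raise ValueError("require hotspot_min > cluster_min >= 2")
    for r in regions:
        if r.count >= hotspot_min:
            r.region_class = "hotspot"
        elif r.count >= cluster_min:
            r.region_class = "cluster"
        else:
            r.region_class = "singleton"
    return regions


def _median_lower(values: list[int]) -> int:
    # lower midpoint for even counts: deterministic, always an observed value
    v = sorted(values)
    return v[(len(v) - 1) // 2]


def region_summary(regions: list[CNVRegion]) -> pd.DataFrame:
    rows = []
    for r in regions:
        sizes = [m.interval.length for m in r.members]
        rows.append({
            "chrom": r.span.chrom,
            "start": r.span.start,
            "end": r.span.end,
            "span_bp": r.span.length,
            "count": r.count,
            "region_class": r.region_class,
            "median_cnv_bp": _median_lower(sizes),
            "n_deletions": sum(m.cnv_type == "deletion" for m in r.members),
            "n_duplications": sum(m.cnv_type == "duplication" for m in r.members),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O: CNV call table (header required) and region BED6+


def read_cnv_table(path: str | Path) -> list[CNVCall]:
    """TSV with header: chrom, start, end, type, sample, condition[, genotype]."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "type", "sample", "condition"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    calls = []
    for row in df.itertuples(index=False):
        calls.append(CNVCall(
            interval=GenomicInterval(str(row.chrom), int(row.start), int(row.end)),
            cnv_type=str(row.type),
            sample_id=str(row.sample),
            condition=str(row.condition),
            genotype=str(row.genotype) if "genotype" in df.columns else None,
        ))
    return calls


def write_cnv_table(cnvs: list[CNVCall], path: str | Path) -> None:
    rows = [{
        "chrom": c.interval.chrom, "start": c.interval.start, "end": c.interval.end,
        "type": c.cnv_type, "sample": c.sample_id, "condition": c.condition,
    } for c in cnvs]
    pd.DataFrame(rows, columns=["chrom", "start", "end", "type", "sample", "condition"]) \
        .to_csv(path, sep="\t", index=False)


def write_regions_bed(regions: list[CNVRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            fh.write(f"{r.span.chrom}\t{r.span.start}\t{r.span.end}\t"
                     f"region_{i}\t{r.count}\t.\t{r.region_class}\n")
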