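"""Percent-coordinate (metagene-style) profiles relative to TUs.

Positions are expressed as percent distance along a TU: 0 at the TSS, 100
at the TES, negative upstream and >100 downstream, strand-aware (on the
minus strand genomic decrease means percent increase). Profiles align many
TUs on this axis: CNV crossing counts per type, and replication timing
min-max rescaled within each TU.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import GenomicInterval, IntervalIndex
from .regions import CNVCall
from .timing import TimingTrack
from .tucall import TranscriptionUnit

# TU length strata used throughout (bp, inclusive bounds):
LARGE_TU = (500_001, None)     # "> 500 kb"
SMALL_TU = (50_000, 200_000)   # "50-200 kb"


def to_relative(pos: int, tu: TranscriptionUnit) -> float:
    """Percent coordinate of a bp position relative to a TU."""
    L = tu.length
    if tu.strand == "+":
        return 100.0 * (pos - tu.span.start) / L
    return 100.0 * (tu.span.end - pos) / L


def from_relative(percent: float, tu: TranscriptionUnit) -> float:
    """Inverse of :func:`to_relative` (bp, possibly fractional)."""
    L = tu.length
    if tu.strand == "+":
        return tu.span.start + percent / 100.0 * L
    return tu.span.end - percent / 100.0 * L


def _select_tus(tus, length_min, length_max) -> list[TranscriptionUnit]:
    hi = np.inf if length_max is None else length_max
    return [t for t in tus if length_min <= t.length <= hi]


def cnv_crossing_profile(
    cnvs: list[CNVCall],
    tus: list[TranscriptionUnit],
    length_min: int,
    length_max: int | None,
    flank_percent: float = 100.0,
    grid_step: float = 1.0,
    multi_tu: str = "per_tu",
) -> pd.DataFrame:
    """CNV crossing counts on the percent grid, separately per cnv_type.

    Every (CNV, TU) pair where the CNV intersects the TU span extended by
    ``flank_percent`` of the TU length on both sides contributes; the CNV
    span is mapped to percent space and increments every grid point it
    crosses. ``multi_tu="per_tu"`` counts a CNV once per overlapped TU
    (profiles are per-TU alignments, not a partition);
    ``multi_tu="best_tu"`` counts it only for the most-overlapped TU.
    """
    if multi_tu not in ("per_tu", "best_tu"):
        raise ValueError(f"unknown multi_tu policy {multi_tu!r}")
    eligible = _select_tus(tus, length_min, length_max)
    if not eligible:
        raise ValueError("length filters select no TUs")
    grid = np.round(np.arange(-flank_percent, 100.0 + flank_percent + grid_step / 2,
                              grid_step), 9)
    counts = {"deletion": np.zeros(len(grid), dtype=int),
              "duplication": np.zeros(len(grid), dtype=int)}
    for cnv in cnvs:
        iv = cnv.interval
        hits: list[tuple[int, TranscriptionUnit]] = []
        for tu in eligible:
            if tu.span.chrom != iv.chrom:
                continue
            ext = flank_percent / 100.0 * tu.length
            lo, hi = tu.span.start - ext, tu.span.end + ext
            ov = min(iv.end, hi) - max(iv.start, lo)
            if ov > 0:
                hits.append((int(ov), tu))
        if not hits:
            continue
        if multi_tu == "best_tu":
            hits = [max(hits, key=lambda h: h[0])]
        for _, tu in hits:
            p1 = to_relative(iv.start, tu)
            p2 = to_relative(iv.end, tu)
            lo, hi = min(p1, p2), max(p1, p2)
            counts[cnv.cnv_type][(grid >= lo) & (grid <= hi)] += 1
    df = pd.DataFrame({"percent": grid,
                       "deletions": counts["deletion"],
                       "duplications": counts["duplication"]})
    df.attrs["n_tus"] = len(eligible)
    return df


def relative_timing(
    tu: TranscriptionUnit,
    track: TimingTrack,
    grid_step: float = 1.0,
    flank_percent: float = 0.0,
) -> tuple[np.ndarray, np.ndarray] | None:
    """Timing along the TU's percent grid, rescaled to [0, 1] by the min
    and max within the TU span. Returns None (TU excluded) when the track
    yields fewer than two distinct values within the TU."""
    grid = np.round(np.arange(-flank_percent, 100.0 + flank_percent + grid_step / 2,
                              grid_step), 9)
    pos = np.asarray([from_relative(p, tu) for p in grid])
    # the exclusive end coordinate denotes the junction after the last bp;
    # sample that last bp rather than falling off the track
    bp = np.where(pos == tu.span.end, tu.span.end - 1, np.floor(pos)).astype(np.int64)
    raw = np.asarray([track.point_value(tu.span.chrom, int(b)) for b in bp])
    body = raw[(grid >= 0) & (grid <= 100)]
    body = body[~np.isnan(body)]
    if len(body) == 0:
        return None
    vmin, vmax = float(body.min()), float(body.max())
    if vmax == vmin:
        return None
    return grid, (raw - vmin) / (vmax - vmin)


def aggregate_relative_timing(
    tus: list[TranscriptionUnit],
    track: TimingTrack,
    length_min: int,
    length_max: int | None,
    grid_step: float = 1.0,
    flank_percent: float = 100.0,
) -> pd.DataFrame:
    """Mean and median relative timing per grid point over eligible TUs."""
    eligible = _select_tus(tus, length_min, length_max)
    if not eligible:
        raise ValueError("length filters select no TUs")
    traces, excluded = [], 0
    grid = None
    for tu in eligible:
        res = relative_timing(tu, track, grid_step=grid_step, flank_percent=flank_percent)
        if res is None:
            excluded += 1
            continue
        grid, vals = res
        traces.append(vals)
    if not traces:
        raise ValueError("no eligible TU has >= 2 distinct timing values")
    mat = np.vstack(traces)
    with np.errstate(invalid="ignore"):
        df = pd.DataFrame({
            "percent": grid,
            "mean": np.nanmean(mat, axis=0),
            "median": np.nanmedian(mat, axis=0),
            "n_tus": np.sum(~np.isnan(mat), axis=0),
        })
    df.attrs["n_excluded_degenerate"] = excluded
    return df


def endpoint_in_tu_fraction(cnvs: list[CNVCall], tus: list[TranscriptionUnit]) -> float:
    """Fraction of the given CNVs with >= 1 endpoint inside any TU span.

    Endpoints are the CNV's own first and last bp (start and end-1)."""
    if not cnvs:
        return float("nan")
    index = IntervalIndex([t.span for t in tus])
    n_in = 0
    for c in cnvs:
        iv = c.interval
        ends_in = (index.overlap_bp(iv.chrom, iv.start, iv.start + 1)[0] > 0
                   or index.overlap_bp(iv.chrom, iv.end - 1, iv.end)[0] > 0)
        n_in += bool(ends_in)
    return n_in / len(cnvs)
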