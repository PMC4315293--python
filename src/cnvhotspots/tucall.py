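"""Transcription-unit calling from strand-specific nascent-RNA coverage.

A transcription unit (TU) is operationally a contiguous genomic span whose
nascent-RNA signal, in RPKM, exceeds a calling threshold on one strand.
Sub-threshold dropouts up to ``max_internal_gap`` are bridged and short
spans are dropped, so a TU typically corresponds to the longest actively
transcribed isoform of a gene, introns included.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomicInterval, MappableGenome

DEFAULT_BIN_SIZE = 1000
DEFAULT_MAX_INTERNAL_GAP = 10_000
DEFAULT_MIN_LENGTH = 10_000


def rpkm(count: float, length_bp: float, total_reads: float) -> float:
    """Reads per kilobase per million mapped reads."""
    if length_bp <= 0:
        raise ValueError("length must be positive")
    if total_reads <= 0:
        raise ValueError("total mapped reads must be positive")
    return count / (length_bp / 1000.0) / (total_reads / 1e6)


@dataclass
class CoverageTrack:
    """Binned read counts for one strand, tiling each chromosome exactly."""

    strand: str
    bin_size: int
    counts: dict[str, np.ndarray]
    total_mapped_reads: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        for chrom, arr in self.counts.items():
            arr = np.asarray(arr)
            if np.any(arr < 0):
                raise ValueError(f"negative counts on {chrom}")
            self.counts[chrom] = arr

    def n_bins(self, chrom: str) -> int:
        return len(self.counts[chrom])

    def rpkm_bins(self, chrom: str) -> np.ndarray:
        return self.counts[chrom] / (self.bin_size / 1000.0) / (self.total_mapped_reads / 1e6)

    def all_rpkm(self) -> np.ndarray:
        return np.concatenate([self.rpkm_bins(c) for c in self.counts])


def merge_tracks(a: CoverageTrack, b: CoverageTrack) -> CoverageTrack:
    """Sum counts and totals of two same-strand tracks (condition merging)."""
    if a.strand != b.strand or a.bin_size != b.bin_size:
        raise ValueError("tracks differ in strand or bin size")
    if set(a.counts) != set(b.counts):
        raise ValueError("tracks cover different chromosomes")
    counts = {c: a.counts[c] + b.counts[c] for c in a.counts}
    return CoverageTrack(a.strand, a.bin_size, counts,
                         a.total_mapped_reads + b.total_mapped_reads)


@dataclass(frozen=True)
class TranscriptionUnit:
    span: GenomicInterval
    strand: str
    rpkm: float
    name: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")

    @property
    def tss(self) -> int:
        """Strand-aware 5' end."""
        return self.span.start if self.strand == "+" else self.span.end

    @property
    def tes(self) -> int:
        """Strand-aware 3' end."""
        return self.span.end if self.strand == "+" else self.span.start

    @property
    def length(self) -> int:
        return self.span.length


def determine_threshold(
    track: CoverageTrack,
    method: str = "mixture",
    quantile: float = 0.99,
    fixed: float | None = None,
    random_state: int = 0,
) -> float:
    """RPKM threshold separating active transcription from background.

    "mixture" fits a two-component Gaussian mixture to log10 RPKM of nonzero
    bins and returns the posterior-equality crossing between the component
    means; a degenerate (effectively unimodal) fit falls back to the
    quantile method with a warning. "quantile" returns the genome-wide RPKM
    quantile; "fixed" returns the user value.
    """
    if method == "fixed":
        if fixed is None:
            raise ValueError("fixed method requires a value")
        return float(fixed)
    values = track.all_rpkm()
    nonzero = values[values > 0]
    if len(nonzero) == 0:
        raise ValueError("coverage track is all zero")
    if method == "quantile":
        return float(np.quantile(values, quantile))
    if method != "mixture":
        raise ValueError(f"unknown threshold method {method!r}")
    from sklearn.mixture import GaussianMixture

    x = np.log10(nonzero).reshape(-1, 1)
    gm = GaussianMixture(n_components=2, random_state=random_state, n_init=3).fit(x)
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    lo, hi = np.argsort(means)
    if abs(means[hi] - means[lo]) < 0.5 * max(sds):  # effectively unimodal
        warnings.warn("mixture fit degenerate; falling back to quantile threshold")
        return float(np.quantile(values, quantile))
    grid = np.linspace(means[lo], means[hi], 2001)
    post = gm.predict_proba(grid.reshape(-1, 1))
    diff = post[:, hi] - post[:, lo]
    crossing = np.flatnonzero(np.diff(np.sign(diff)) != 0)
    xstar = grid[crossing[0]] if len(crossing) else 0.5 * (means[lo] + means[hi])
    return float(10 ** xstar)


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start_bin, end_bin) runs of True."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts, ends))


def call_tus(
    track: CoverageTrack,
    threshold: float,
    max_internal_gap: int = DEFAULT_MAX_INTERNAL_GAP,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> list[TranscriptionUnit]:
    """Chain supra-threshold bins into TUs on the track's strand.

    Sub-threshold runs of <= ``max_internal_gap`` bp between supra-threshold
    runs are bridged; spans shorter than ``min_length`` are dropped. TU RPKM
    is computed over the full called span.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    gap_bins = max_internal_gap // track.bin_size
    tus: list[TranscriptionUnit] = []
    for chrom in track.counts:
        r = track.rpkm_bins(chrom)
        runs = _runs_above(r >= threshold)
        merged: list[list[int]] = []
        for s, e in runs:
            if merged and s - merged[-1][1] <= gap_bins:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        for s, e in merged:
            start, end = s * track.bin_size, e * track.bin_size
            if end - start < min_length:
                continue
            span_count = float(track.counts[chrom][s:e].sum())
            tus.append(TranscriptionUnit(
                span=GenomicInterval(chrom, start, end),
                strand=track.strand,
                rpkm=rpkm(span_count, end - start, track.total_mapped_reads),
            ))
    return sorted(tus, key=lambda t: (t.span.chrom, t.span.start))


def tu_length_classes(
    tus: list[TranscriptionUnit],
    genome: MappableGenome,
    thresholds: tuple[int, ...] = (100_000, 500_000, 1_000_000),
) -> pd.DataFrame:
    """TU counts, aggregate bp, and mappable-genome fraction per length stratum."""
    rows = []
    mappable = genome.mappable_bp
    for t in thresholds:
        sel = [tu for tu in tus if tu.length > t]
        total = sum(tu.length for tu in sel)
        rows.append({
            "stratum": f">{t}",
            "min_length_bp": t,
            "n_tus": len(sel),
            "total_bp": total,
            "genome_fraction": total / mappable,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O: per-bin bedGraph (one line per nonzero bin) plus a totals file


def write_coverage_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, arr in track.counts.items():
            nz = np.flatnonzero(arr)
            for b in nz:
                s = int(b) * track.bin_size
                fh.write(f"{chrom}\t{s}\t{s + track.bin_size}\t{int(arr[b])}\n")


def read_coverage_bedgraph(
    path: str | Path,
    chrom_sizes: dict[str, int],
    bin_size: int,
    strand: str,
    total_mapped_reads: int,
) -> CoverageTrack:
    counts = {
        c: np.zeros(-(-size // bin_size), dtype=np.int64)
        for c, size in chrom_sizes.items()
    }
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            chrom, s, e, v = line.split("\t")
            s, e = int(s), int(e)
            if chrom not in counts:
                raise ValueError(f"{path}:{ln}: unknown chromosome {chrom}")
            if s % bin_size or (e - s) != bin_size:
                raise ValueError(f"{path}:{ln}: record not aligned to {bin_size}-bp bins")
            counts[chrom][s // bin_size] = int(v)
    return CoverageTrack(strand, bin_size, counts, total_mapped_reads)


def write_tus_bed(tus: list[TranscriptionUnit], path: str | Path) -> None:
    """BED6 + full-precision RPKM in column 7."""
    with open(path, "w") as fh:
        for i, tu in enumerate(tus):
            nm = tu.name or f"TU_{i}"
            score = min(1000, int(round(tu.rpkm)))
            fh.write(f"{tu.span.chrom}\t{tu.span.start}\t{tu.span.end}\t{nm}\t"
                     f"{score}\t{tu.strand}\t{tu.rpkm!r}\n")


def read_tus_bed(path: str | Path) -> list[TranscriptionUnit]:
    tus = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            chrom, s, e, name, _score, strand, rp = line.split("\t")[:7]
            tus.append(TranscriptionUnit(
                span=GenomicInterval(chrom, int(s), int(e)),
                strand=strand, rpkm=float(rp), name=name))
    return tus
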