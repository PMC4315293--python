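"""Genomic interval data model and plain-text readers/writers.

All coordinates are 0-based half-open (BED convention). Readers for 1-based
formats must convert at the boundary; nothing downstream ever sees 1-based
coordinates. Chromosome names are passed through verbatim (no "chr"
aliasing).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


def intersect_len(a: GenomicInterval, b: GenomicInterval) -> int:
    """Overlap in bp between two intervals; 0 on different chromosomes."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def merge_intervals(intervals: Iterable[GenomicInterval], gap: int = 0) -> list[GenomicInterval]:
    """Union of intervals, additionally bridging gaps <= ``gap`` bp."""
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    out: list[GenomicInterval] = []
    for iv in ivs:
        if out and out[-1].chrom == iv.chrom and iv.start - out[-1].end <= gap:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(iv)
    return out


class MappableGenome:
    """Chromosome sizes plus an exclusion mask (assembly gaps etc.).

    The mappable space — everything outside ``excluded`` — is the sampling
    domain for every permutation statistic in the pipeline.
    """

    def __init__(self, chrom_sizes: dict[str, int], excluded: Sequence[GenomicInterval] = ()):
        for chrom, size in chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"non-positive size for chromosome {chrom}")
        self.chrom_sizes = dict(chrom_sizes)
        excl = sorted(excluded, key=lambda iv: (iv.chrom, iv.start))
        prev: GenomicInterval | None = None
        for iv in excl:
            if iv.chrom not in self.chrom_sizes:
                raise ValueError(f"excluded interval on unknown chromosome {iv.chrom}")
            if iv.end > self.chrom_sizes[iv.chrom]:
                raise ValueError(f"excluded interval {iv} beyond chromosome end")
            if prev is not None and prev.chrom == iv.chrom and iv.start < prev.end:
                raise ValueError(f"excluded intervals overlap: {prev} / {iv}")
            prev = iv
        self.excluded = excl
        # maximal mappable runs per chromosome, as (starts, ends) arrays
        self._runs: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, size in self.chrom_sizes.items():
            gaps = [iv for iv in excl if iv.chrom == chrom]
            starts, ends, pos = [], [], 0
            for g in gaps:
                if g.start > pos:
                    starts.append(pos)
                    ends.append(g.start)
                pos = max(pos, g.end)
            if pos < size:
                starts.append(pos)
                ends.append(size)
            self._runs[chrom] = (np.asarray(starts, dtype=np.int64),
                                 np.asarray(ends, dtype=np.int64))

    @property
    def total_bp(self) -> int:
        return sum(self.chrom_sizes.values())

    @property
    def mappable_bp(self) -> int:
        return self.total_bp - sum(iv.length for iv in self.excluded)

    def mappable_runs(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(starts, ends) of the maximal mappable stretches of ``chrom``."""
        if chrom not in self._runs:
            raise KeyError(f"unknown chromosome {chrom}")
        return self._runs[chrom]

    def subtract_excluded(self, iv: GenomicInterval) -> list[GenomicInterval]:
        """Mappable sub-intervals of ``iv``, sorted and disjoint."""
        if iv.chrom not in self.chrom_sizes:
            raise KeyError(f"unknown chromosome {iv.chrom}")
        if iv.end > self.chrom_sizes[iv.chrom]:
            raise ValueError(f"{iv} extends beyond chromosome end")
        starts, ends = self._runs[iv.chrom]
        out = []
        for s, e in zip(starts, ends):
            lo, hi = max(iv.start, int(s)), min(iv.end, int(e))
            if lo < hi:
                out.append(GenomicInterval(iv.chrom, lo, hi))
        return out

    def mappable_intervals(self) -> list[GenomicInterval]:
        out = []
        for chrom in self.chrom_sizes:
            starts, ends = self._runs[chrom]
            out.extend(GenomicInterval(chrom, int(s), int(e)) for s, e in zip(starts, ends))
        return out


@dataclass
class FeatureSet:
    """Named list of intervals with optional strands and attributes.

    Features are kept sorted by (chrom, start, end); ``strands`` and every
    ``attrs`` column are permuted in lockstep with the sort.
    """

    name: str
    features: list[GenomicInterval]
    strands: list[str] | None = None
    attrs: dict[str, list] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.features)
        if self.strands is not None and len(self.strands) != n:
            raise ValueError("strands length mismatch")
        for key, col in self.attrs.items():
            if len(col) != n:
                raise ValueError(f"attribute {key!r} length mismatch")
        order = sorted(range(n), key=lambda i: (self.features[i].chrom,
                                                self.features[i].start,
                                                self.features[i].end))
        self.features = [self.features[i] for i in order]
        if self.strands is not None:
            self.strands = [self.strands[i] for i in order]
        self.attrs = {k: [v[i] for i in order] for k, v in self.attrs.items()}

    def __len__(self) -> int:
        return len(self.features)


class IntervalIndex:
    """Merged per-chromosome interval index for fast overlap queries.

    Built once from any interval collection; answers total-overlap-bp and
    any-overlap queries for vectorised query arrays via searchsorted on the
    merged representation.
    """

    def __init__(self, intervals: Iterable[GenomicInterval]):
        merged = merge_intervals(intervals)
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._prefix: dict[str, np.ndarray] = {}
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in merged:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in by_chrom.items():
            s = np.asarray([iv.start for iv in ivs], dtype=np.int64)
            e = np.asarray([iv.end for iv in ivs], dtype=np.int64)
            self._starts[chrom] = s
            self._ends[chrom] = e
            self._prefix[chrom] = np.concatenate([[0], np.cumsum(e - s)])

    def overlap_bp(self, chrom: str, qstart, qend) -> np.ndarray:
        """Total overlapped bp for each query [qstart[i], qend[i])."""
        qs = np.atleast_1d(np.asarray(qstart, dtype=np.int64))
        qe = np.atleast_1d(np.asarray(qend, dtype=np.int64))
        if chrom not in self._starts:
            return np.zeros(qs.shape, dtype=np.int64)
        s, e, pref = self._starts[chrom], self._ends[chrom], self._prefix[chrom]
        i = np.searchsorted(e, qs, side="right")
        j = np.searchsorted(s, qe, side="left")
        total = pref[j] - pref[i]
        has = j > i
        left = np.where(has, np.maximum(0, qs - s[np.minimum(i, len(s) - 1)]), 0)
        right = np.where(has, np.maximum(0, e[np.maximum(j - 1, 0)] - qe), 0)
        return np.where(has, total - left - right, 0)

    def overlaps(self, iv: GenomicInterval) -> bool:
        return bool(self.overlap_bp(iv.chrom, iv.start, iv.end)[0] > 0)


# ---------------------------------------------------------------------------
# plain-text I/O


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column TSV: chromosome name, length in bp."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{ln}: expected two tab-separated columns")
            sizes[parts[0]] = int(parts[1])
    return sizes


def read_bed(path: str | Path, dialect: str = "bed3", name: str | None = None) -> FeatureSet:
    """Read BED3 or BED6 into a FeatureSet (re-sorted by coordinate).

    BED6 keeps strand (column 6) and the name column as attribute ``name``.
    """
    if dialect not in ("bed3", "bed6"):
        raise ValueError(f"unknown BED dialect {dialect!r}")
    ivs: list[GenomicInterval] = []
    strands: list[str] = []
    names: list[str] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            need = 3 if dialect == "bed3" else 6
            if len(parts) < need:
                raise ValueError(f"{path}:{ln}: expected >= {need} columns")
            try:
                iv = GenomicInterval(parts[0], int(parts[1]), int(parts[2]))
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: {exc}") from exc
            ivs.append(iv)
            if dialect == "bed6":
                names.append(parts[3])
                strands.append(parts[5])
    if dialect == "bed6":
        return FeatureSet(name or str(path), ivs, strands=strands, attrs={"name": names})
    return FeatureSet(name or str(path), ivs)


def write_bed(features: FeatureSet | Sequence[GenomicInterval], path: str | Path) -> None:
    if isinstance(features, FeatureSet):
        ivs, strands = features.features, features.strands
        names = features.attrs.get("name")
    else:
        ivs, strands, names = list(features), None, None
    with open(path, "w") as fh:
        for i, iv in enumerate(ivs):
            if strands is not None:
                nm = names[i] if names else f"feature_{i}"
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{nm}\t0\t{strands[i]}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def write_chrom_sizes(sizes: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")
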