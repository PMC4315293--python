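"""Replication-timing tracks and transcription x timing stratification.

A timing track is a piecewise-constant signal over disjoint genomic
segments. Two source conventions are supported: Repli-seq timing scores
(higher = earlier replication) and Repli-chip log2 early/late ratios at
projected probe positions (higher = earlier; "late" is conventionally a
ratio below -0.8). Intervals with no timing coverage always propagate a
missing value, never a silent zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomicInterval, MappableGenome, merge_intervals

SOURCES = ("repli_seq_score", "repli_chip_log2ratio")


class TimingTrack:
    def __init__(self, source: str, segments: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        if source not in SOURCES:
            raise ValueError(f"source must be one of {SOURCES}")
        self.source = source
        self._seg: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (s, e, v) in segments.items():
            s = np.asarray(s, dtype=np.int64)
            e = np.asarray(e, dtype=np.int64)
            v = np.asarray(v, dtype=float)
            if not (len(s) == len(e) == len(v)):
                raise ValueError(f"segment array length mismatch on {chrom}")
            if np.any(e <= s):
                raise ValueError(f"empty segment on {chrom}")
            if np.any(s[1:] < e[:-1]):
                raise ValueError(f"overlapping segments on {chrom}")
            self._seg[chrom] = (s, e, v)
        # prefix sums for weighted queries
        self._pref: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (s, e, v) in self._seg.items():
            ln = (e - s).astype(float)
            self._pref[chrom] = (np.concatenate([[0.0], np.cumsum(ln)]),
                                 np.concatenate([[0.0], np.cumsum(ln * v)]))

    @property
    def chroms(self) -> list[str]:
        return list(self._seg)

    def segments(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self._seg[chrom]

    def values(self) -> np.ndarray:
        return np.concatenate([v for _, _, v in self._seg.values()])

    def point_value(self, chrom: str, pos: int) -> float:
        """Track value at a bp position; NaN outside coverage."""
        if chrom not in self._seg:
            return float("nan")
        s, e, v = self._seg[chrom]
        k = np.searchsorted(s, pos, side="right") - 1
        if k >= 0 and e[k] > pos:
            return float(v[k])
        return float("nan")

    def interval_mean_many(self, chrom: str, qstart, qend) -> np.ndarray:
        """Length-weighted mean value over each query; NaN where uncovered."""
        qs = np.atleast_1d(np.asarray(qstart, dtype=np.int64))
        qe = np.atleast_1d(np.asarray(qend, dtype=np.int64))
        if chrom not in self._seg:
            return np.full(qs.shape, np.nan)
        s, e, v = self._seg[chrom]
        pref_len, pref_wv = self._pref[chrom]
        i = np.searchsorted(e, qs, side="right")
        j = np.searchsorted(s, qe, side="left")
        has = j > i
        ii = np.minimum(i, len(s) - 1)
        jj = np.maximum(j - 1, 0)
        left = np.where(has, np.maximum(0, qs - s[ii]), 0).astype(float)
        right = np.where(has, np.maximum(0, e[jj] - qe), 0).astype(float)
        cov = np.where(has, pref_len[j] - pref_len[i] - left - right, 0.0)
        wsum = np.where(has, pref_wv[j] - pref_wv[i] - left * v[ii] - right * v[jj], 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(cov > 0, wsum / np.maximum(cov, 1e-300), np.nan)
        return out

    def interval_coverage_bp(self, chrom: str, qstart, qend) -> np.ndarray:
        qs = np.atleast_1d(np.asarray(qstart, dtype=np.int64))
        qe = np.atleast_1d(np.asarray(qend, dtype=np.int64))
        if chrom not in self._seg:
            return np.zeros(qs.shape)
        s, e, _ = self._seg[chrom]
        pref_len, _ = self._pref[chrom]
        i = np.searchsorted(e, qs, side="right")
        j = np.searchsorted(s, qe, side="left")
        has = j > i
        ii = np.minimum(i, len(s) - 1)
        jj = np.maximum(j - 1, 0)
        left = np.where(has, np.maximum(0, qs - s[ii]), 0).astype(float)
        right = np.where(has, np.maximum(0, e[jj] - qe), 0).astype(float)
        return np.where(has, pref_len[j] - pref_len[i] - left - right, 0.0)


def interval_timing(iv: GenomicInterval, track: TimingTrack) -> float:
    """bp-weighted mean timing over an interval; NaN if no coverage."""
    return float(track.interval_mean_many(iv.chrom, [iv.start], [iv.end])[0])


def project_probes(
    probes: dict[str, tuple[np.ndarray, np.ndarray]],
    chrom_sizes: dict[str, int],
    source: str = "repli_chip_log2ratio",
) -> TimingTrack:
    """Nearest-probe step function: each probe's ratio covers from the
    previous inter-probe midpoint to the next; terminal probes run to the
    chromosome ends."""
    segments = {}
    for chrom, (pos, ratio) in probes.items():
        pos = np.asarray(pos, dtype=np.int64)
        ratio = np.asarray(ratio, dtype=float)
        if len(pos) < 2:
            raise ValueError(f"need >= 2 probes on {chrom}")
        if np.any(np.diff(pos) == 0):
            raise ValueError(f"duplicate probe positions on {chrom}")
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"probe positions not increasing on {chrom}")
        size = chrom_sizes[chrom]
        mids = (pos[:-1] + pos[1:]) // 2
        starts = np.concatenate([[0], mids])
        ends = np.concatenate([mids, [size]])
        segments[chrom] = (starts, ends, ratio)
    return TimingTrack(source, segments)


def read_probe_tsv(path: str | Path) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """TSV with header: chrom, position, ratio."""
    df = pd.read_csv(path, sep="\t")
    out = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        out[str(chrom)] = (sub["position"].to_numpy(), sub["ratio"].to_numpy())
    return out


def read_timing_bedgraph(path: str | Path, source: str) -> TimingTrack:
    recs: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            chrom, s, e, v = line.split("\t")
            recs.setdefault(chrom, []).append((int(s), int(e), float(v)))
    segments = {}
    for chrom, rows in recs.items():
        rows.sort()
        segments[chrom] = (np.asarray([r[0] for r in rows]),
                           np.asarray([r[1] for r in rows]),
                           np.asarray([r[2] for r in rows]))
    return TimingTrack(source, segments)


def write_timing_bedgraph(track: TimingTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms:
            s, e, v = track.segments(chrom)
            for a, b, x in zip(s, e, v):
                fh.write(f"{chrom}\t{a}\t{b}\t{float(x)!r}\n")


# ---------------------------------------------------------------------------
# late-replicating segments


@dataclass(frozen=True)
class LateRule:
    """kind "repli_chip_below" (strict <, Repli-chip only, conventionally
    -0.8) or "score_below" (strict <, Repli-seq scores, where lower score =
    later replication)."""

    kind: str
    threshold: float

    def compatible(self, source: str) -> bool:
        if self.kind == "repli_chip_below":
            return source == "repli_chip_log2ratio"
        if self.kind == "score_below":
            return source == "repli_seq_score"
        return False


@dataclass
class LateSegmentSet:
    segments: list[GenomicInterval]
    rule: str


def late_segments(track: TimingTrack, rule: LateRule) -> LateSegmentSet:
    """Maximal runs of segments satisfying the rule, merged when adjacent."""
    if not rule.compatible(track.source):
        raise ValueError(f"rule {rule} incompatible with track source {track.source}")
    out: list[GenomicInterval] = []
    for chrom in track.chroms:
        s, e, v = track.segments(chrom)
        sel = v < rule.threshold
        out.extend(GenomicInterval(chrom, int(a), int(b))
                   for a, b in zip(s[sel], e[sel]))
    return LateSegmentSet(segments=merge_intervals(out, gap=0),
                          rule=f"{rule.kind}({rule.threshold})")


def late_segments_from_bed(intervals: list[GenomicInterval], rule_name: str) -> LateSegmentSet:
    """Accept a precomputed late-segment classification (e.g. the external
    Repli-seq mid-S4-to-G2 segmentation) as-is."""
    return LateSegmentSet(segments=merge_intervals(intervals, gap=0), rule=rule_name)


# ---------------------------------------------------------------------------
# interval set helpers (sorted, merged inputs)


def _intersect_lists(a: list[GenomicInterval], b: list[GenomicInterval]) -> list[GenomicInterval]:
    a = merge_intervals(a)
    b = merge_intervals(b)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in b:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out = []
    for iv in a:
        for other in by_chrom.get(iv.chrom, ()):
            lo, hi = max(iv.start, other.start), min(iv.end, other.end)
            if lo < hi:
                out.append(GenomicInterval(iv.chrom, lo, hi))
    return merge_intervals(out)


def _subtract_lists(a: list[GenomicInterval], b: list[GenomicInterval]) -> list[GenomicInterval]:
    a = merge_intervals(a)
    b = merge_intervals(b)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in b:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out = []
    for iv in a:
        pos = iv.start
        for other in by_chrom.get(iv.chrom, ()):
            if other.end <= pos or other.start >= iv.end:
                continue
            if other.start > pos:
                out.append(GenomicInterval(iv.chrom, pos, other.start))
            pos = max(pos, other.end)
        if pos < iv.end:
            out.append(GenomicInterval(iv.chrom, pos, iv.end))
    return out


def _collect_weighted(track: TimingTrack, intervals: list[GenomicInterval]):
    """(values, bp weights) of all track-segment pieces inside ``intervals``."""
    vals, wts = [], []
    for iv in intervals:
        if iv.chrom not in track.chroms:
            continue
        s, e, v = track.segments(iv.chrom)
        i = int(np.searchsorted(e, iv.start, side="right"))
        j = int(np.searchsorted(s, iv.end, side="left"))
        if j <= i:
            continue
        ss = np.maximum(s[i:j], iv.start)
        ee = np.minimum(e[i:j], iv.end)
        vals.append(v[i:j])
        wts.append((ee - ss).astype(float))
    if not vals:
        return np.empty(0), np.empty(0)
    return np.concatenate(vals), np.concatenate(wts)


def weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    if len(values) == 0:
        return float("nan")
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    return float(v[np.searchsorted(cum, 0.5 * cum[-1])])


def _histogram_pct(values, weights, edges) -> np.ndarray:
    h, _ = np.histogram(values, bins=edges, weights=weights)
    total = h.sum()
    return 100.0 * h / total if total > 0 else h


# ---------------------------------------------------------------------------
# stratifications


def stratify_timing_by_transcription(
    genome: MappableGenome,
    tus,
    track: TimingTrack,
    n_hist_bins: int = 40,
    bin_edges: np.ndarray | None = None,
) -> dict[str, pd.DataFrame]:
    """bp-weighted timing histograms (each summing to 100%) for the whole
    mappable genome and its transcribed / untranscribed partition, plus
    aggregate bp and mean TU RPKM per stratum."""
    mappable = genome.mappable_intervals()
    transcribed = _intersect_lists([t.span for t in tus], mappable) if tus else []
    untranscribed = _subtract_lists(mappable, transcribed)
    if bin_edges is None:
        vals = track.values()
        bin_edges = np.linspace(float(vals.min()), float(vals.max()) + 1e-9, n_hist_bins + 1)
    strata = {"genome": mappable, "transcribed": transcribed, "untranscribed": untranscribed}
    hist_rows, summary_rows = [], []
    tu_bp = sum(t.length for t in tus)
    mean_rpkm_txn = (sum(t.rpkm * t.length for t in tus) / tu_bp) if tu_bp else 0.0
    for name, ivs in strata.items():
        values, weights = _collect_weighted(track, ivs)
        pct = _histogram_pct(values, weights, bin_edges)
        for b in range(len(bin_edges) - 1):
            hist_rows.append({"stratum": name, "bin_left": bin_edges[b],
                              "bin_right": bin_edges[b + 1], "percent": pct[b]})
        bp = sum(iv.length for iv in ivs)
        txn_bp = sum(iv.length for iv in transcribed)
        if name == "transcribed":
            mean_rpkm = mean_rpkm_txn
        elif name == "genome" and bp:
            mean_rpkm = mean_rpkm_txn * txn_bp / bp  # untranscribed bp counts as 0
        else:
            mean_rpkm = 0.0
        summary_rows.append({
            "stratum": name, "bp": bp, "mean_rpkm": mean_rpkm,
            "mean_timing": float(np.average(values, weights=weights)) if len(values) else float("nan"),
        })
    return {"histograms": pd.DataFrame(hist_rows), "summary": pd.DataFrame(summary_rows)}


def timing_by_tu_length(
    tus,
    track: TimingTrack,
    bin_width: int = 200_000,
    genome: MappableGenome | None = None,
) -> tuple[pd.DataFrame, float]:
    """Median per-TU mean timing in TU-length bins of ``bin_width`` bp.

    Returns (table, genome-wide bp-weighted median timing as reference;
    NaN when no genome is given). Empty bins are omitted. TUs without
    timing coverage are excluded and counted in the ``n_no_timing`` attr.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    per_tu = [(t.length, interval_timing(t.span, track)) for t in tus]
    n_missing = sum(1 for _, x in per_tu if np.isnan(x))
    per_tu = [(l, x) for l, x in per_tu if not np.isnan(x)]
    rows = []
    if per_tu:
        lengths = np.asarray([l for l, _ in per_tu])
        values = np.asarray([x for _, x in per_tu])
        bins = (lengths - 1) // bin_width
        for b in np.unique(bins):
            m = bins == b
            rows.append({
                "bin_left": int(b) * bin_width, "bin_right": (int(b) + 1) * bin_width,
                "n_tus": int(m.sum()), "median_timing": float(np.median(values[m])),
            })
    df = pd.DataFrame(rows)
    df.attrs["n_no_timing"] = n_missing
    if genome is not None:
        values, weights = _collect_weighted(track, genome.mappable_intervals())
        ref = weighted_median(values, weights)
    else:
        ref = float("nan")
    return df, ref


def timing_by_expression(
    tus,
    track: TimingTrack,
    quantile_edges: tuple[float, ...] = (0.25, 0.5, 0.75),
    n_hist_bins: int = 40,
    bin_edges: np.ndarray | None = None,
) -> pd.DataFrame:
    """Timing histograms of TU bp partitioned by TU RPKM quantile stratum."""
    if any(q2 <= q1 for q1, q2 in zip(quantile_edges, quantile_edges[1:])):
        raise ValueError("quantile edges must be increasing")
    if not tus:
        return pd.DataFrame(columns=["stratum", "bin_left", "bin_right", "percent"])
    if bin_edges is None:
        vals = track.values()
        bin_edges = np.linspace(float(vals.min()), float(vals.max()) + 1e-9, n_hist_bins + 1)
    rpkms = np.asarray([t.rpkm for t in tus])
    cuts = np.quantile(rpkms, quantile_edges) if quantile_edges else np.empty(0)
    stratum = np.searchsorted(cuts, rpkms, side="right")
    rows = []
    for s in range(len(cuts) + 1):
        sel = [t for t, st in zip(tus, stratum) if st == s]
        if not sel:
            continue
        values, weights = _collect_weighted(track, merge_intervals([t.span for t in sel]))
        pct = _histogram_pct(values, weights, bin_edges)
        lo = 0.0 if s == 0 else quantile_edges[s - 1]
        hi = 1.0 if s == len(cuts) else quantile_edges[s]
        for b in range(len(bin_edges) - 1):
            rows.append({"stratum": f"rpkm_q{lo:g}-{hi:g}", "bin_left": bin_edges[b],
                         "bin_right": bin_edges[b + 1], "percent": pct[b]})
    return pd.DataFrame(rows)
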