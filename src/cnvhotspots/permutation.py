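"""Monte-Carlo permutation statistics for CNV clustering and enrichment.

The null model places each interval (a merged CNV region, an individual CNV
call, or a TU) at a position drawn uniformly among all start coordinates for
which the interval fits entirely in mappable sequence, genome-wide. Sampling
is exact (inverse-CDF over the valid-slot counts of the mappable runs), so a
chromosome's probability is proportional to the number of valid slots it
offers for that interval length. Placements of different intervals are
independent and may overlap unless ``allow_overlap=False``.

Empirical p-values always use the add-one rule
``p = (1 + #{iterations at least as extreme}) / (n_iter + 1)`` and are
therefore never zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import FeatureSet, GenomicInterval, IntervalIndex, MappableGenome
from .regions import CNVCall, CNVRegion

SCORE_KINDS = ("boolean", "fraction_of_span", "longest_feature_bp", "length_weighted_mean")


@dataclass
class PermutationResult:
    actual: float
    iterations: np.ndarray
    n_iter: int
    seed: int
    p_emp: float
    direction: str  # "enriched" | "depleted"


def _p_emp(actual: float, iterations: np.ndarray, direction: str | None = None) -> tuple[float, str]:
    if direction is None:
        direction = "enriched" if actual >= float(np.median(iterations)) else "depleted"
    if direction == "enriched":
        extreme = int(np.sum(iterations >= actual))
    else:
        extreme = int(np.sum(iterations <= actual))
    return (1 + extreme) / (len(iterations) + 1), direction


class _Placer:
    """Exact uniform sampler over valid mappable start positions."""

    def __init__(self, genome: MappableGenome):
        self.genome = genome
        self.chroms = list(genome.chrom_sizes)
        starts, lens, codes = [], [], []
        for ci, chrom in enumerate(self.chroms):
            rs, re = genome.mappable_runs(chrom)
            starts.append(rs)
            lens.append(re - rs)
            codes.append(np.full(len(rs), ci))
        self.run_start = np.concatenate(starts) if starts else np.empty(0, dtype=np.int64)
        self.run_len = np.concatenate(lens) if lens else np.empty(0, dtype=np.int64)
        self.run_chrom = np.concatenate(codes) if codes else np.empty(0, dtype=np.int64)

    def sample(self, length: int, n: int, rng: np.random.Generator,
               chrom: str | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Return (chrom_codes, starts) for ``n`` independent placements."""
        mask = slice(None) if chrom is None else (self.run_chrom == self.chroms.index(chrom))
        run_start = self.run_start[mask]
        run_len = self.run_len[mask]
        run_chrom = self.run_chrom[mask]
        valid = np.maximum(run_len - length + 1, 0)
        total = int(valid.sum())
        if total == 0:
            raise ValueError(f"no mappable stretch can hold an interval of {length} bp")
        cum = np.cumsum(valid)
        u = rng.integers(0, total, size=n)
        r = np.searchsorted(cum, u, side="right")
        starts = run_start[r] + (u - (cum[r] - valid[r]))
        return run_chrom[r], starts


def permute_regions(
    regions: list[CNVRegion] | list[GenomicInterval],
    genome: MappableGenome,
    n_iter: int,
    seed: int,
    placement: str = "genome",
    allow_overlap: bool = True,
    max_attempts: int = 10_000,
):
    """Yield ``n_iter`` lists of randomly placed intervals (lengths preserved)."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if placement not in ("genome", "same_chrom"):
        raise ValueError(f"unknown placement {placement!r}")
    ivs = [r.span if isinstance(r, CNVRegion) else r for r in regions]
    placer = _Placer(genome)
    rng = np.random.default_rng(seed)
    for _ in range(n_iter):
        placed: list[GenomicInterval] = []
        for iv in ivs:
            chrom_arg = iv.chrom if placement == "same_chrom" else None
            for attempt in range(max_attempts):
                codes, starts = placer.sample(iv.length, 1, rng, chrom=chrom_arg)
                cand = GenomicInterval(placer.chroms[int(codes[0])],
                                       int(starts[0]), int(starts[0]) + iv.length)
                if allow_overlap or all(
                    cand.chrom != p.chrom or cand.end <= p.start or p.end <= cand.start
                    for p in placed
                ):
                    placed.append(cand)
                    break
            else:
                raise RuntimeError(
                    f"could not place interval of {iv.length} bp without overlap "
                    f"in {max_attempts} attempts"
                )
        yield placed


# ---------------------------------------------------------------------------
# overlap scoring


def _feature_arrays(features: FeatureSet) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in features.features:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    return {
        c: (np.asarray([iv.start for iv in ivs]), np.asarray([iv.end for iv in ivs]))
        for c, ivs in by_chrom.items()
    }


def _longest_overlapping(chrom_arrays, chrom: str, qs: int, qe: int) -> int:
    if chrom not in chrom_arrays:
        return 0
    s, e = chrom_arrays[chrom]
    j = np.searchsorted(s, qe, side="left")
    if j == 0:
        return 0
    hit = e[:j] > qs
    if not hit.any():
        return 0
    return int(np.max((e[:j] - s[:j])[hit]))


def score_overlap(
    intervals: list[GenomicInterval] | list[CNVRegion],
    features: FeatureSet,
    kind: str,
    signal=None,
) -> np.ndarray:
    """Per-interval overlap score against a feature set (or signal track).

    kinds: boolean (any overlap), fraction_of_span (overlapped bp / span bp),
    longest_feature_bp (max length of any intersecting feature), and
    length_weighted_mean (bp-weighted mean of ``signal`` over the span;
    requires an object with ``interval_mean_many(chrom, starts, ends)``).
    """
    if kind not in SCORE_KINDS:
        raise ValueError(f"unknown score kind {kind!r}")
    ivs = [r.span if isinstance(r, CNVRegion) else r for r in intervals]
    if kind == "length_weighted_mean":
        if signal is None:
            raise ValueError("length_weighted_mean requires a signal track")
        out = np.empty(len(ivs))
        for i, iv in enumerate(ivs):
            out[i] = float(signal.interval_mean_many(iv.chrom, [iv.start], [iv.end])[0])
        return out
    index = IntervalIndex(features.features)
    if kind == "longest_feature_bp":
        arrays = _feature_arrays(features)
        return np.asarray([
            _longest_overlapping(arrays, iv.chrom, iv.start, iv.end) for iv in ivs
        ], dtype=float)
    ov = np.asarray([
        int(index.overlap_bp(iv.chrom, iv.start, iv.end)[0]) for iv in ivs
    ], dtype=float)
    if kind == "boolean":
        return (ov > 0).astype(float)
    return ov / np.asarray([iv.length for iv in ivs], dtype=float)


def enrichment_test(
    groups: dict[str, list[CNVRegion]],
    features: FeatureSet,
    kind: str,
    genome: MappableGenome,
    n_iter: int = 1000,
    seed: int = 0,
    signal=None,
    direction: str | None = None,
) -> dict[str, PermutationResult]:
    """Permutation enrichment of the group-mean overlap score, per region group.

    ``direction=None`` (default) tests one-sided in the observed direction
    (sign of actual minus iteration median), which is what the reported
    stars mean; note the resulting p is then at most ~0.5 under the null.
    Pass ``"enriched"`` or ``"depleted"`` for a prespecified one-sided test
    (uniform null p-values)."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    placer = _Placer(genome)
    index = (IntervalIndex(features.features)
             if kind in ("boolean", "fraction_of_span") else None)
    arrays = _feature_arrays(features) if kind == "longest_feature_bp" else None
    results: dict[str, PermutationResult] = {}
    for gi, (gname, regions) in enumerate(groups.items()):
        if not regions:
            raise ValueError(f"empty region group {gname!r}")
        ivs = [r.span if isinstance(r, CNVRegion) else r for r in regions]
        actual = float(np.mean(score_overlap(ivs, features, kind, signal=signal)))
        rng = np.random.default_rng(np.random.SeedSequence([seed, gi]))
        totals = np.zeros(n_iter)
        for iv in ivs:
            codes, starts = placer.sample(iv.length, n_iter, rng)
            ends = starts + iv.length
            scores = np.empty(n_iter)
            if kind in ("boolean", "fraction_of_span"):
                for ci, chrom in enumerate(placer.chroms):
                    m = codes == ci
                    if not m.any():
                        continue
                    ov = index.overlap_bp(chrom, starts[m], ends[m]).astype(float)
                    scores[m] = (ov > 0) if kind == "boolean" else ov / iv.length
            elif kind == "longest_feature_bp":
                for j in range(n_iter):
                    scores[j] = _longest_overlapping(
                        arrays, placer.chroms[int(codes[j])], int(starts[j]), int(ends[j]))
            else:  # length_weighted_mean
                for ci, chrom in enumerate(placer.chroms):
                    m = codes == ci
                    if not m.any():
                        continue
                    scores[m] = signal.interval_mean_many(chrom, starts[m], ends[m])
            totals += scores
        iterations = totals / len(ivs)
        p, dirn = _p_emp(actual, iterations, direction=direction)
        results[gname] = PermutationResult(actual, iterations, n_iter, seed, p, dirn)
    return results


# ---------------------------------------------------------------------------
# clustering significance


def _merge_stats(gstarts: np.ndarray, gends: np.ndarray, max_gap: int):
    """(max members, n regions, total span) after gap-merging.

    Inputs are *global* coordinates (chromosomes offset so that no two
    chromosomes come within max_gap of each other), unsorted.
    """
    order = np.argsort(gstarts, kind="stable")
    s = gstarts[order]
    e = np.maximum.accumulate(gends[order])
    new = np.empty(len(s), dtype=bool)
    new[0] = True
    new[1:] = s[1:] - e[:-1] > max_gap
    region_id = np.cumsum(new) - 1
    counts = np.bincount(region_id)
    # span per region: last cumulative end minus first start
    firsts = s[new]
    last_idx = np.flatnonzero(np.append(new[1:], True))
    spans = e[last_idx] - firsts
    return int(counts.max()), len(counts), int(spans.sum())


def _globalize(cnv_chrom_codes, starts, ends, chrom_sizes_by_code, max_gap):
    offsets = np.concatenate([[0], np.cumsum(chrom_sizes_by_code + max_gap + 1)])
    off = offsets[cnv_chrom_codes]
    return starts + off, ends + off


def clustering_significance(
    cnvs: list[CNVCall],
    genome: MappableGenome,
    max_gap: int,
    k: int,
    n_iter: int = 1000,
    seed: int = 0,
) -> float:
    """Probability (add-one corrected) that uniformly re-placed CNVs yield
    any merged region with >= k members."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    hits = sum(
        stats[0] >= k for stats in _iterate_merge_stats(cnvs, genome, max_gap, n_iter, seed)
    )
    return (1 + hits) / (n_iter + 1)


def clustering_pvalue(
    cnvs: list[CNVCall],
    genome: MappableGenome,
    max_gap: int,
    n_iter: int = 1000,
    seed: int = 0,
    statistic: str = "total_span",
) -> PermutationResult:
    """Empirical p for observed clustering against uniform re-placement.

    statistic "total_span" (continuous; smaller total merged-region span =
    more clustered, lower tail) or "max_members" (integer; larger = more
    clustered, upper tail).
    """
    if statistic not in ("total_span", "max_members"):
        raise ValueError(f"unknown clustering statistic {statistic!r}")
    idx = 2 if statistic == "total_span" else 0
    chroms = list(genome.chrom_sizes)
    codes = np.asarray([chroms.index(c.interval.chrom) for c in cnvs])
    starts = np.asarray([c.interval.start for c in cnvs], dtype=np.int64)
    ends = np.asarray([c.interval.end for c in cnvs], dtype=np.int64)
    sizes = np.asarray([genome.chrom_sizes[c] for c in chroms], dtype=np.int64)
    gs, ge = _globalize(codes, starts, ends, sizes, max_gap)
    actual = float(_merge_stats(gs, ge, max_gap)[idx])
    iterations = np.asarray([
        float(stats[idx])
        for stats in _iterate_merge_stats(cnvs, genome, max_gap, n_iter, seed)
    ])
    direction = "depleted" if statistic == "total_span" else "enriched"
    p, direction = _p_emp(actual, iterations, direction=direction)
    return PermutationResult(actual, iterations, n_iter, seed, p, direction)


def _iterate_merge_stats(cnvs, genome, max_gap, n_iter, seed):
    placer = _Placer(genome)
    rng = np.random.default_rng(seed)
    lengths = np.asarray([c.interval.length for c in cnvs], dtype=np.int64)
    sizes = np.asarray([genome.chrom_sizes[c] for c in placer.chroms], dtype=np.int64)
    # placements for all CNVs x all iterations at once, one sampling pass per CNV
    all_codes = np.empty((len(cnvs), n_iter), dtype=np.int64)
    all_starts = np.empty((len(cnvs), n_iter), dtype=np.int64)
    for i, L in enumerate(lengths):
        codes, starts = placer.sample(int(L), n_iter, rng)
        all_codes[i], all_starts[i] = codes, starts
    for j in range(n_iter):
        gs, ge = _globalize(all_codes[:, j], all_starts[:, j],
                            all_starts[:, j] + lengths, sizes, max_gap)
        yield _merge_stats(gs, ge, max_gap)


# ---------------------------------------------------------------------------
# reciprocal TU permutation


def permute_tus(
    tus,
    genome: MappableGenome,
    cnvs: list[CNVCall],
    n_iter: int,
    seed: int,
    length_bins: list[int],
) -> pd.DataFrame:
    """Per TU-length bin: actual % of TUs overlapping >= 1 CNV vs the
    randomly-placed-TU distribution (lengths preserved, bins unchanged)."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    edges = np.asarray(length_bins, dtype=np.int64)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("length_bins must be increasing with >= 2 edges")
    spans = [t.span for t in tus]
    lengths = np.asarray([iv.length for iv in spans], dtype=np.int64)
    if lengths.min() < edges[0] or lengths.max() > edges[-1]:
        raise ValueError("length_bins do not cover the TU length range")
    bin_of = np.clip(np.searchsorted(edges, lengths, side="right") - 1, 0, len(edges) - 2)

    cnv_index = IntervalIndex([c.interval for c in cnvs]) if cnvs else None

    def hit(chrom, s, e):
        s = np.atleast_1d(s)
        if cnv_index is None:
            return np.zeros(s.shape, dtype=bool)
        return cnv_index.overlap_bp(chrom, s, np.atleast_1d(e)) > 0

    actual_hits = np.asarray([bool(hit(iv.chrom, iv.start, iv.end)[0]) for iv in spans])
    placer = _Placer(genome)
    rng = np.random.default_rng(seed)
    perm_hits = np.empty((len(spans), n_iter), dtype=bool)
    for i, iv in enumerate(spans):
        codes, starts = placer.sample(iv.length, n_iter, rng)
        row = np.zeros(n_iter, dtype=bool)
        for ci, chrom in enumerate(placer.chroms):
            m = codes == ci
            if m.any():
                row[m] = hit(chrom, starts[m], starts[m] + iv.length)
        perm_hits[i] = row

    rows = []
    for b in range(len(edges) - 1):
        m = bin_of == b
        if not m.any():
            continue
        actual_pct = 100.0 * actual_hits[m].mean()
        perm_pct = 100.0 * perm_hits[m].mean(axis=0)
        p, direction = _p_emp(actual_pct, perm_pct)
        rows.append({
            "bin_left": int(edges[b]), "bin_right": int(edges[b + 1]),
            "n_tus": int(m.sum()), "actual_pct": actual_pct,
            "perm_mean_pct": float(perm_pct.mean()),
            "perm_q05_pct": float(np.quantile(perm_pct, 0.05)),
            "perm_q95_pct": float(np.quantile(perm_pct, 0.95)),
            "p_emp": p, "direction": direction,
        })
    return pd.DataFrame(rows)


def write_permutation_results(results: dict[str, PermutationResult], kind: str, path) -> None:
    rows = []
    for group, r in results.items():
        rows.append({
            "group": group, "score_kind": kind, "actual": r.actual,
            "iter_mean": float(np.mean(r.iterations)),
            "iter_q025": float(np.quantile(r.iterations, 0.025)),
            "iter_median": float(np.median(r.iterations)),
            "iter_q975": float(np.quantile(r.iterations, 0.975)),
            "n_iter": r.n_iter, "p_emp": r.p_emp, "direction": r.direction,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
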