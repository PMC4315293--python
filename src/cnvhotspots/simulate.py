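"""Synthetic datasets with the statistical structure the analysis assumes.

The generator emulates the study conditions end to end: a small
multi-chromosome genome with an exclusion mask; a TU population with a
heavy upper length tail (log-normal body plus a handful of planted
multi-Mb units); strand-specific Poisson read coverage proportional to TU
intensity over uniform background noise; a replication-timing field that is
early over transcribed bp, late elsewhere, with a mid-TU delay growing with
TU length; and CNVs placed by a double-fork-failure risk model in which a
TU of length L carries weight proportional to (L / N_s)^2 (N_s = median
fork travel before stalling), deletions concentrated mid-TU and
duplications on the flanks.

All randomness flows from a single seed through named substreams, so the
same model always yields the identical dataset.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome import GenomicInterval, MappableGenome, write_bed, write_chrom_sizes
from .permutation import _Placer
from .profiles import from_relative
from .regions import CNVCall, write_cnv_table
from .timing import TimingTrack, write_timing_bedgraph
from .tucall import CoverageTrack, TranscriptionUnit, write_coverage_bedgraph, write_tus_bed

CONDITIONS = ("NT", "APH", "HU", "IR")


@dataclass(frozen=True)
class GenomeSpec:
    n_chroms: int = 3
    chrom_length: int = 60_000_000
    excluded_fraction: float = 0.02
    gaps_per_chrom: int = 4


@dataclass(frozen=True)
class TUSpec:
    n_tus: int = 200                      # total, including the planted large tail
    length_median: int = 60_000           # log-normal body
    length_sigma: float = 1.0
    large_lengths: tuple[int, ...] = (1_000_000, 1_200_000, 1_400_000, 1_700_000, 2_000_000)
    min_tu_gap: int = 50_000
    rpkm_log10_mean: float = 0.0
    rpkm_log10_sigma: float = 0.5
    rpkm_length_anticorr: float = 0.5     # large TUs tend to lower intensity
    min_rpkm: float = 0.05


@dataclass(frozen=True)
class CoverageSpec:
    bin_size: int = 1000
    background_lambda: float = 0.1        # Poisson reads/bin/strand off-TU
    reads_per_rpkm_bin: float = 20.0      # expected reads per bin per RPKM unit


@dataclass(frozen=True)
class TimingSpec:
    # Repli-seq style score: higher = earlier replication
    early: float = 75.0                   # transcribed baseline
    late: float = 35.0                    # untranscribed baseline
    mid_delay_per_mb: float = 25.0        # sinusoidal mid-TU delay amplitude
    max_delay: float = 60.0
    noise_sd: float = 1.0
    segment_bp: int = 10_000


@dataclass(frozen=True)
class CNVSpec:
    n_deletions: int = 200
    n_duplications: int = 100
    baseline_rate_per_bp: float = 3e-7    # background weight per mappable bp
    transcription_multiplier: float = 1.0
    ns_bp: int = 300_000                  # fork-failure scale N_s
    length_median: int = 186_000
    length_sigma: float = 0.8
    del_center_mean: float = 50.0         # percent of TU
    del_center_sd: float = 15.0
    dup_center_offsets: tuple[float, float] = (-25.0, 125.0)
    dup_center_sd: float = 15.0


@dataclass(frozen=True)
class SyntheticModel:
    genome: GenomeSpec = field(default_factory=GenomeSpec)
    tus: TUSpec = field(default_factory=TUSpec)
    coverage: CoverageSpec = field(default_factory=CoverageSpec)
    timing: TimingSpec = field(default_factory=TimingSpec)
    cnvs: CNVSpec = field(default_factory=CNVSpec)
    seed: int = 0


@dataclass
class SyntheticDataset:
    model: SyntheticModel
    genome: MappableGenome
    tus: list[TranscriptionUnit]
    tu_is_large: np.ndarray
    coverage_plus: CoverageTrack
    coverage_minus: CoverageTrack
    timing: TimingTrack
    cnvs: list[CNVCall]
    truth: dict

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_chrom_sizes(self.genome.chrom_sizes, out / "genome.chrom.sizes")
        write_bed(self.genome.excluded, out / "excluded.bed")
        write_tus_bed(self.tus, out / "tus_truth.bed")
        write_coverage_bedgraph(self.coverage_plus, out / "coverage_plus.bedgraph")
        write_coverage_bedgraph(self.coverage_minus, out / "coverage_minus.bedgraph")
        with open(out / "coverage_totals.json", "w") as fh:
            json.dump({"plus": self.coverage_plus.total_mapped_reads,
                       "minus": self.coverage_minus.total_mapped_reads,
                       "bin_size": self.coverage_plus.bin_size}, fh)
        write_timing_bedgraph(self.timing, out / "timing.bedgraph")
        write_cnv_table(self.cnvs, out / "cnvs.tsv")
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1)


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(seed)
    names = ("genome", "tus", "coverage", "timing", "cnvs")
    return {n: np.random.default_rng(s) for n, s in zip(names, root.spawn(len(names)))}


def _make_genome(spec: GenomeSpec, rng: np.random.Generator) -> MappableGenome:
    sizes = {f"chr{i + 1}": spec.chrom_length for i in range(spec.n_chroms)}
    excluded: list[GenomicInterval] = []
    gap_len = int(spec.excluded_fraction * spec.chrom_length / max(spec.gaps_per_chrom, 1))
    for chrom in sizes:
        placed: list[tuple[int, int]] = []
        for _ in range(spec.gaps_per_chrom):
            for _attempt in range(1000):
                s = int(rng.integers(0, spec.chrom_length - gap_len))
                if all(s + gap_len <= a or s >= b for a, b in placed):
                    placed.append((s, s + gap_len))
                    break
            else:
                raise ValueError("could not place exclusion gaps; genome spec infeasible")
        excluded.extend(GenomicInterval(chrom, a, b) for a, b in sorted(placed))
    return MappableGenome(sizes, excluded)


def _place_tus(spec: TUSpec, genome: MappableGenome, rng: np.random.Generator):
    n_small = spec.n_tus - len(spec.large_lengths)
    if n_small < 0:
        raise ValueError("n_tus smaller than the planted large-TU count")
    lengths = list(spec.large_lengths) + [
        int(x) for x in rng.lognormal(np.log(spec.length_median), spec.length_sigma, n_small)
    ]
    lengths = [max(1000, L) for L in lengths]
    is_large = np.array([True] * len(spec.large_lengths) + [False] * n_small)
    chroms = list(genome.chrom_sizes)
    occupied: dict[str, list[tuple[int, int]]] = {
        c: [(iv.start, iv.end) for iv in genome.excluded if iv.chrom == c] for c in chroms
    }
    order = np.argsort(lengths)[::-1]  # longest first: easier packing
    spans: list[GenomicInterval | None] = [None] * len(lengths)
    large_rank = 0
    for idx in order:
        L = lengths[idx]
        for _attempt in range(10_000):
            if is_large[idx]:
                chrom = chroms[large_rank % len(chroms)]
            else:
                chrom = chroms[int(rng.integers(0, len(chroms)))]
            size = genome.chrom_sizes[chrom]
            if size <= L:
                continue
            s = int(rng.integers(0, size - L))
            e = s + L
            if all(e + spec.min_tu_gap <= a or s >= b + spec.min_tu_gap
                   for a, b in occupied[chrom]):
                occupied[chrom].append((s, e))
                spans[idx] = GenomicInterval(chrom, s, e)
                break
        else:
            raise ValueError(f"could not place TU of {L} bp; TU spec infeasible")
        if is_large[idx]:
            large_rank += 1
    strands = rng.choice(["+", "-"], size=len(lengths))
    # intensity: log10 RPKM anticorrelated with log length
    loglen = np.log(np.asarray(lengths, dtype=float))
    z_len = (loglen - loglen.mean()) / max(loglen.std(), 1e-12)
    rho = spec.rpkm_length_anticorr
    eps = rng.standard_normal(len(lengths))
    log10_rpkm = (spec.rpkm_log10_mean
                  + spec.rpkm_log10_sigma * (-rho * z_len + np.sqrt(1 - rho ** 2) * eps))
    rpkms = np.maximum(spec.min_rpkm, 10.0 ** log10_rpkm)
    tus = [TranscriptionUnit(span=spans[i], strand=str(strands[i]),
                             rpkm=float(rpkms[i]), name=f"TU_{i:04d}")
           for i in range(len(lengths))]
    return tus, is_large


def _make_coverage(tus, is_large, genome, spec: CoverageSpec, rng):
    tracks = {}
    for strand in ("+", "-"):
        counts = {
            c: rng.poisson(spec.background_lambda, size=-(-size // spec.bin_size)).astype(np.int64)
            for c, size in genome.chrom_sizes.items()
        }
        for tu in tus:
            if tu.strand != strand:
                continue
            arr = counts[tu.span.chrom]
            b0 = tu.span.start // spec.bin_size
            b1 = -(-tu.span.end // spec.bin_size)
            lam = np.full(b1 - b0, spec.reads_per_rpkm_bin * tu.rpkm)
            # partial edge bins scale by overlap fraction
            first_ov = min(tu.span.end, (b0 + 1) * spec.bin_size) - tu.span.start
            last_ov = tu.span.end - max(tu.span.start, (b1 - 1) * spec.bin_size)
            lam[0] *= first_ov / spec.bin_size
            lam[-1] *= last_ov / spec.bin_size
            arr[b0:b1] += rng.poisson(lam)
        tracks[strand] = counts
    total = int(sum(int(a.sum()) for t in tracks.values() for a in t.values()))
    total = max(total, 1)
    return (CoverageTrack("+", spec.bin_size, tracks["+"], total),
            CoverageTrack("-", spec.bin_size, tracks["-"], total))


def _make_timing(tus, genome, spec: TimingSpec, rng) -> TimingTrack:
    segments = {}
    for chrom, size in genome.chrom_sizes.items():
        starts = np.arange(0, size, spec.segment_bp, dtype=np.int64)
        ends = np.minimum(starts + spec.segment_bp, size)
        vals = np.full(len(starts), spec.late, dtype=float)
        mids = (starts + ends) // 2
        for tu in tus:
            if tu.span.chrom != chrom:
                continue
            amp = min(spec.max_delay, spec.mid_delay_per_mb * tu.length / 1e6)
            sel = (ends > tu.span.start) & (starts < tu.span.end)
            p = np.clip((mids[sel] - tu.span.start) / tu.length, 0.0, 1.0)
            vals[sel] = spec.early - amp * np.sin(np.pi * p)
        vals += rng.normal(0.0, spec.noise_sd, size=len(vals))
        segments[chrom] = (starts, ends, vals)
    return TimingTrack("repli_seq_score", segments)


def _tu_weights(tus, spec: CNVSpec) -> np.ndarray:
    L = np.asarray([t.length for t in tus], dtype=float)
    return spec.transcription_multiplier * (L / spec.ns_bp) ** 2


def _place_cnv_in_tu(tu: TranscriptionUnit, cnv_len: int, center_pct: float,
                     chrom_len: int) -> GenomicInterval:
    center = from_relative(center_pct, tu)
    s = int(round(center - cnv_len / 2))
    e = s + cnv_len
    s, e = max(0, s), min(chrom_len, e)
    if e - s < 1:  # fully clipped off the chromosome end: keep a 1-kb stub inside
        s, e = max(0, min(s, chrom_len - 1000)), max(1000, min(e, chrom_len))
    return GenomicInterval(tu.span.chrom, s, e)


def _make_cnvs(tus, genome, spec: CNVSpec, rng, uniform: bool = False):
    placer = _Placer(genome)
    w_tu = _tu_weights(tus, spec)
    w_bg = spec.baseline_rate_per_bp * genome.mappable_bp
    weights = np.concatenate([[w_bg], w_tu])
    if uniform or weights.sum() <= 0 or w_bg == weights.sum():
        probs = None  # all background
    else:
        probs = weights / weights.sum()
    longest_run = max(
        int((re - rs).max())
        for rs, re in (genome.mappable_runs(c) for c in genome.chrom_sizes)
    )
    calls: list[CNVCall] = []
    assignments = []
    specs = [("deletion", spec.n_deletions), ("duplication", spec.n_duplications)]
    k = 0
    for cnv_type, n in specs:
        for _ in range(n):
            length = max(1000, int(rng.lognormal(np.log(spec.length_median), spec.length_sigma)))
            locus = 0 if probs is None else int(rng.choice(len(weights), p=probs))
            if locus == 0:
                L = min(length, longest_run)
                codes, starts = placer.sample(L, 1, rng)
                chrom = placer.chroms[int(codes[0])]
                iv = GenomicInterval(chrom, int(starts[0]), int(starts[0]) + L)
                assignments.append("background")
            else:
                tu = tus[locus - 1]
                if cnv_type == "deletion":
                    center = float(np.clip(
                        rng.normal(spec.del_center_mean, spec.del_center_sd), 0.0, 100.0))
                else:
                    lobe = spec.dup_center_offsets[int(rng.integers(0, 2))]
                    center = float(rng.normal(lobe, spec.dup_center_sd))
                iv = _place_cnv_in_tu(tu, length, center,
                                      genome.chrom_sizes[tu.span.chrom])
                assignments.append(tus[locus - 1].name)
            calls.append(CNVCall(
                interval=iv, cnv_type=cnv_type,
                sample_id=f"clone_{k:03d}",
                condition=CONDITIONS[k % len(CONDITIONS)],
            ))
            k += 1
    return calls, assignments


def generate(model: SyntheticModel, uniform_cnvs: bool = False) -> SyntheticDataset:
    """Build the full synthetic dataset from a model (deterministic in seed)."""
    rngs = _substreams(model.seed)
    genome = _make_genome(model.genome, rngs["genome"])
    tus, is_large = _place_tus(model.tus, genome, rngs["tus"])
    cov_plus, cov_minus = _make_coverage(tus, is_large, genome, model.coverage, rngs["coverage"])
    timing = _make_timing(tus, genome, model.timing, rngs["timing"])
    cnvs, assignments = _make_cnvs(tus, genome, model.cnvs, rngs["cnvs"],
                                   uniform=uniform_cnvs)
    w_tu = _tu_weights(tus, model.cnvs)
    truth = {
        "seed": model.seed,
        "uniform_cnvs": uniform_cnvs,
        "model": dataclasses.asdict(model),
        "tus": [{
            "name": t.name, "chrom": t.span.chrom, "start": t.span.start,
            "end": t.span.end, "strand": t.strand, "rpkm": t.rpkm,
            "length": t.length, "is_large": bool(is_large[i]),
            "risk_weight": float(w_tu[i]),
        } for i, t in enumerate(tus)],
        "cnv_loci": assignments,
        "planted_hotspots": [t.name for i, t in enumerate(tus) if is_large[i]],
    }
    return SyntheticDataset(model=model, genome=genome, tus=tus, tu_is_large=is_large,
                            coverage_plus=cov_plus, coverage_minus=cov_minus,
                            timing=timing, cnvs=cnvs, truth=truth)


def null_dataset(model: SyntheticModel) -> SyntheticDataset:
    """Same genome/TUs/signal, but CNVs placed by the permutation engine's
    own uniform mappable-placement law (risk effects disabled)."""
    return generate(model, uniform_cnvs=True)
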