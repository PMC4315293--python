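"""Independent brute-force oracles used by the test suite.

Everything here works on per-bp bitmaps or naive enumeration and stays
deliberately independent of the implementation code paths it checks.
"""

from __future__ import annotations

import numpy as np


def bitmap_overlap_len(a: tuple[int, int], b: tuple[int, int], size: int) -> int:
    """Set-intersection size of two intervals via an explicit bp bitmap."""
    bm_a = np.zeros(size, dtype=bool)
    bm_b = np.zeros(size, dtype=bool)
    bm_a[a[0]:a[1]] = True
    bm_b[b[0]:b[1]] = True
    return int(np.sum(bm_a & bm_b))


def bitmap_subtract(iv: tuple[int, int], gaps: list[tuple[int, int]], size: int):
    """Mappable sub-intervals of iv as (start, end) runs via a bitmap."""
    bm = np.zeros(size, dtype=bool)
    bm[iv[0]:iv[1]] = True
    for g in gaps:
        bm[g[0]:g[1]] = False
    out, start = [], None
    for i, v in enumerate(bm):
        if v and start is None:
            start = i
        elif not v and start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, len(bm)))
    return out


def bitmap_fraction_overlap(region: tuple[int, int], features: list[tuple[int, int]], size: int) -> float:
    bm = np.zeros(size, dtype=bool)
    for f in features:
        bm[f[0]:f[1]] = True
    span = np.zeros(size, dtype=bool)
    span[region[0]:region[1]] = True
    return float(np.sum(bm & span)) / (region[1] - region[0])


def brute_merge(intervals: list[tuple[int, int]], max_gap: int) -> list[set[int]]:
    """Transitive closure of the 'overlap or gap <= max_gap' relation.

    Returns the partition of interval indices (single chromosome)."""
    n = len(intervals)
    adj = [[False] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            (s1, e1), (s2, e2) = intervals[i], intervals[j]
            gap = max(s1, s2) - min(e1, e2)
            adj[i][j] = gap <= max_gap
    groups: list[set[int]] = []
    seen: set[int] = set()
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            k = stack.pop()
            if k in comp:
                continue
            comp.add(k)
            stack.extend(j for j in range(n) if adj[k][j] and j not in comp)
        groups.append(comp)
        seen |= comp
    return groups


def nearest_probe_values(positions: np.ndarray, ratios: np.ndarray, size: int) -> np.ndarray:
    """Per-bp nearest-probe assignment (ties to the left probe)."""
    out = np.empty(size)
    for bp in range(size):
        d = np.abs(positions - bp)
        k = int(np.argmin(d))  # argmin takes the first (left) probe on ties
        out[bp] = ratios[k]
    return out


def perbp_weighted_mean(starts, ends, values, q: tuple[int, int]) -> float:
    """bp-resolution weighted mean of a piecewise-constant track over q."""
    total = wsum = 0
    for s, e, v in zip(starts, ends, values):
        ov = min(e, q[1]) - max(s, q[0])
        if ov > 0:
            total += ov
            wsum += ov * v
    return wsum / total if total else float("nan")


def rank_then_pearson(x, y) -> float:
    """Spearman rho oracle: mid-rank then Pearson."""
    def midrank(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j < len(v) and sv[j] == sv[i]:
                j += 1
            ranks[order[i:j]] = (i + j - 1) / 2 + 1
            i = j
        return ranks

    rx, ry = midrank(x), midrank(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float(np.sum(rx * ry) / np.sqrt(np.sum(rx ** 2) * np.sum(ry ** 2)))
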