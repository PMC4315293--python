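"""Closed-form association statistics used across the analysis.

Fisher's exact test (two-sided, probability-at-most-observed convention),
Spearman rank correlation with a seeded permutation p-value, and pairwise
two-sided Mann-Whitney U for group differences between region strata.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import scipy.stats as ss


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("all-zero contingency table")

    def as_array(self) -> np.ndarray:
        return np.asarray([[self.a, self.b], [self.c, self.d]])


@dataclass
class CorrelationResult:
    r: float
    n: int
    p: float


def fisher_exact(table: ContingencyTable2x2 | np.ndarray) -> tuple[float, float]:
    """(odds ratio, two-sided p) by exact hypergeometric enumeration.

    Two-sided p sums the probabilities of all tables with the same margins
    whose probability is at most that of the observed table — the
    probability-at-most-observed convention. Table weights are exact
    integers (products of binomial coefficients) and the sum is an exact
    rational, so ties are resolved without floating-point slack."""
    if not isinstance(table, ContingencyTable2x2):
        t = np.asarray(table)
        table = ContingencyTable2x2(int(t[0, 0]), int(t[0, 1]), int(t[1, 0]), int(t[1, 1]))
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    w_obs = comb(r1, a) * comb(r2, c1 - a)
    num = tot = 0
    for aa in range(lo, hi + 1):
        w = comb(r1, aa) * comb(r2, c1 - aa)
        tot += w
        if w <= w_obs:
            num += w
    p = float(Fraction(num, tot))
    if b * c == 0:
        odds = float("nan") if a * d == 0 else float("inf")
    else:
        odds = (a * d) / (b * c)
    return odds, p


def spearman(x, y, n_perm: int = 10_000, seed: int = 0) -> CorrelationResult:
    """Spearman rho (mid-ranks for ties) with a permutation p-value.

    p is two-sided: the add-one-corrected fraction of y-permutations whose
    |rho| is at least the observed |rho|. Constant input gives an undefined
    rho, reported as NaN/NaN."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need >= 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult(float("nan"), len(x), float("nan"))
    rx = ss.rankdata(x)
    ry = ss.rankdata(y)
    zx = (rx - rx.mean()) / rx.std()
    zy = (ry - ry.mean()) / ry.std()
    rho = float(np.clip(np.mean(zx * zy), -1.0, 1.0))
    rng = np.random.default_rng(seed)
    perm = np.empty(n_perm)
    for i in range(n_perm):
        perm[i] = np.mean(zx * rng.permutation(zy))
    p = (1 + int(np.sum(np.abs(perm) >= abs(rho) - 1e-12))) / (n_perm + 1)
    return CorrelationResult(rho, len(x), p)


def mann_whitney(u: np.ndarray, v: np.ndarray) -> float:
    """Two-sided Mann-Whitney U p-value with tie correction."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if len(u) == 0 or len(v) == 0:
        raise ValueError("groups must be non-empty")
    pooled = np.concatenate([u, v])
    if np.all(pooled == pooled[0]):
        return 1.0  # both groups constant and equal
    return float(ss.mannwhitneyu(u, v, alternative="two-sided").pvalue)


def group_difference(groups: dict[str, list[float]]) -> pd.DataFrame:
    """Pairwise two-sided Mann-Whitney over named groups."""
    rows = []
    for (na, va), (nb, vb) in itertools.combinations(groups.items(), 2):
        rows.append({"group_a": na, "group_b": nb,
                     "n_a": len(va), "n_b": len(vb),
                     "p": mann_whitney(np.asarray(va), np.asarray(vb))})
    return pd.DataFrame(rows)
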