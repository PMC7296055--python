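"""Group comparison of distance distributions.

Chromosomes are split by genus into an experimentally supported
"Transconjugants" group and an "Others" group, and their Mahalanobis
distance distributions are compared with Cliff's delta (a nonparametric
dominance effect size in [-1, 1]) and an asymptotic Wilcoxon-Mann-Whitney
test (mid-ranks, tie-corrected normal approximation, no continuity
correction by default). A negative delta means the Transconjugant distances
tend to be smaller, i.e. the plasmid is compositionally closer to the
chromosomes of genera that actually received it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "InsufficientDataError",
    "DegenerateDataError",
    "cliffs_delta",
    "wmw_asymptotic",
    "compare_groups",
]

log = logging.getLogger(__name__)


class InsufficientDataError(ValueError):
    """A group has too few non-NA observations for the comparison."""


class DegenerateDataError(ValueError):
    """All pooled values identical: the rank test variance is zero."""


@dataclass
class GroupComparison:
    """Cliff's delta + asymptotic WMW result for one k."""

    k: int
    n_transconjugants: int
    n_others: int
    cliffs_delta: float
    z_statistic: float
    p_value_two_sided: float
    median_transconjugants: float
    median_others: float

    @property
    def medians(self) -> Tuple[float, float]:
        return (self.median_transconjugants, self.median_others)

    def summary(self) -> str:
        return "\n".join(
            [
                f"Group comparison of Mahalanobis D2 (k={self.k})",
                f"  Transconjugants: n={self.n_transconjugants}, "
                f"median D2={self.median_transconjugants:.6g}",
                f"  Others:          n={self.n_others}, "
                f"median D2={self.median_others:.6g}",
                f"  Cliff's delta: {self.cliffs_delta:+.4f}"
                "  (negative: Transconjugant distances smaller)",
                f"  asymptotic WMW: z={self.z_statistic:.4f}, "
                f"two-sided p={self.p_value_two_sided:.3g}",
            ]
        )


def cliffs_delta(x: Sequence[float], y: Sequence[float]) -> float:
    """Cliff's delta: (#{x_i > y_j} - #{x_i < y_j}) / (|x| |y|).

    Exact pair counting via sorting (O((n+m) log(n+m))); +1/-1 indicate
    complete separation, 0 complete overlap.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("cliffs_delta requires non-empty vectors")
    ys = np.sort(y)
    n_less = np.searchsorted(ys, x, side="left")      # per x_i: #{y_j < x_i}
    n_leq = np.searchsorted(ys, x, side="right")      # per x_i: #{y_j <= x_i}
    greater = int(n_less.sum())                       # pairs with x > y
    less = int((y.size - n_leq).sum())                # pairs with x < y
    return (greater - less) / (x.size * y.size)


def wmw_asymptotic(
    x: Sequence[float], y: Sequence[float], continuity: bool = False
) -> Tuple[float, float]:
    """Asymptotic Wilcoxon-Mann-Whitney test.

    Mid-ranks for ties, tie-corrected variance, normal approximation,
    two-sided p. No continuity correction unless requested. Returns
    ``(z, p)``; z < 0 when x tends to be smaller than y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError("wmw_asymptotic requires >= 2 values per group")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    tie_factor = sps.tiecorrect(ranks)
    if tie_factor == 0:
        raise DegenerateDataError("all pooled values identical; WMW undefined")
    n = n1 + n2
    u_x = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mean_u = n1 * n2 / 2.0
    var_u = tie_factor * n1 * n2 * (n + 1) / 12.0
    num = u_x - mean_u
    if continuity:
        num -= 0.5 * np.sign(num)
    z = num / np.sqrt(var_u)
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return float(z), float(p)


def compare_groups(table: pd.DataFrame, k: int, value: str = "d2") -> GroupComparison:
    """Compare Transconjugant vs Other distance distributions at one k.

    ``table`` is a host-prediction table with a ``group`` column and a
    ``{value}_k{k}`` column; NA rows are dropped per group before testing.
    """
    col = f"{value}_k{k}"
    if col not in table.columns:
        raise KeyError(f"table has no column {col!r}")
    if "group" not in table.columns:
        raise KeyError("table has no 'group' column; run assign_groups first")
    vals = pd.to_numeric(table[col], errors="coerce")
    t = vals[(table["group"] == "Transconjugants") & vals.notna()].to_numpy()
    o = vals[(table["group"] == "Others") & vals.notna()].to_numpy()
    if t.size < 2 or o.size < 2:
        raise InsufficientDataError(
            f"k={k}: need >= 2 non-NA rows per group, got "
            f"{t.size} Transconjugants and {o.size} Others"
        )
    z, p = wmw_asymptotic(t, o)
    return GroupComparison(
        k=k,
        n_transconjugants=int(t.size),
        n_others=int(o.size),
        cliffs_delta=cliffs_delta(t, o),
        z_statistic=z,
        p_value_two_sided=p,
        median_transconjugants=float(np.median(t)),
        median_others=float(np.median(o)),
    )
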