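"""Concordance analytics between prediction algorithms and test results.

Covers the dichotomized SIFT/PolyPhen-2 2x2 table with odds ratio and
chi-square, Spearman rank correlation of per-gene p-values, and top-k
overlap (Venn region) counts between ranked gene lists.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class ContingencyTable2x2:
    """Counts a=P+S+, b=P+S-, c=P-S+, d=P-S- of jointly scored variants."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


def dichotomize_scores(
    sift_scores: Sequence[float],
    polyphen_scores: Sequence[float],
    sift_damaging_below: float = 0.05,
    polyphen_damaging_above: float = 0.2,
) -> ContingencyTable2x2:
    """Cross-classify variants by both algorithms' damaging calls.

    SIFT calls damaging when the raw score is below ``sift_damaging_below``
    (equivalently 1 - score above 0.95); PolyPhen-2 when its score exceeds
    ``polyphen_damaging_above``. Variants missing either score are excluded.
    """
    s = np.asarray(sift_scores, dtype=float)
    p = np.asarray(polyphen_scores, dtype=float)
    if s.shape != p.shape:
        raise ValueError("score vectors have mismatched lengths")
    ok = ~np.isnan(s) & ~np.isnan(p)
    if not ok.any():
        raise ValueError("no variants with both scores present")
    s_plus = s[ok] < sift_damaging_below
    p_plus = p[ok] > polyphen_damaging_above
    return ContingencyTable2x2(
        a=int(np.sum(p_plus & s_plus)),
        b=int(np.sum(p_plus & ~s_plus)),
        c=int(np.sum(~p_plus & s_plus)),
        d=int(np.sum(~p_plus & ~s_plus)),
    )


def odds_ratio(table: ContingencyTable2x2) -> float:
    """OR = (a*d)/(b*c); a zero cell triggers the Haldane-Anscombe +0.5 fix."""
    a, b, c, d = table.a, table.b, table.c, table.d
    if (a + b == 0 or c + d == 0) or (a + c == 0 or b + d == 0):
        raise ValueError("a margin of the table is zero; odds ratio undefined")
    if min(a, b, c, d) == 0:
        warnings.warn("zero cell: applying Haldane-Anscombe +0.5 correction")
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def chi_square(table: ContingencyTable2x2) -> tuple[float, float]:
    """Pearson chi-square of independence, 1 df, no continuity correction."""
    if table.total == 0:
        raise ValueError("empty table")
    arr = table.as_array()
    expected = stats.contingency.expected_freq(arr)
    if (expected < 1).any():
        warnings.warn("expected cell count below 1; chi-square approximation is poor")
    res = stats.chi2_contingency(arr, correction=False)
    return float(res.statistic), float(res.pvalue)


def spearman_rho(p1: Sequence[float], p2: Sequence[float]) -> float:
    """Spearman rank correlation with average ranks for ties."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if p1.shape != p2.shape or p1.size < 3:
        raise ValueError("need two aligned vectors of length >= 3")
    if np.ptp(p1) == 0 or np.ptp(p2) == 0:
        raise ValueError("rank correlation undefined for a constant vector")
    return float(stats.spearmanr(p1, p2).statistic)


@dataclass
class OverlapReport:
    """Venn decomposition of top-k gene sets.

    ``regions`` maps a frozenset of list names to the count of genes in
    exactly those lists' top k (exclusive regions).
    """

    k: int
    names: list[str]
    regions: dict[frozenset, int]

    def pairwise_overlap(self, name1: str, name2: str) -> int:
        """Genes in both lists' top k (inclusive of triple regions)."""
        return sum(
            n for region, n in self.regions.items() if {name1, name2} <= region
        )


def rank_genes(genes: Sequence[str], p_values: Sequence[float]) -> list[str]:
    """Order genes by ascending p-value, ties broken by gene id."""
    return [g for g, _ in sorted(zip(genes, p_values), key=lambda t: (t[1], t[0]))]


def top_k_overlap(
    result_sets: Mapping[str, Sequence[str]] | Sequence[Sequence[str]], k: int
) -> OverlapReport:
    """Exclusive Venn region counts of the top-k genes of 2 or 3 ranked lists.

    Input lists must already be ranked (see :func:`rank_genes`, which
    breaks p-value ties at the k boundary by gene id).
    """
    if isinstance(result_sets, Mapping):
        named = list(result_sets.items())
    else:
        named = [(f"set{i + 1}", lst) for i, lst in enumerate(result_sets)]
    if len(named) not in (2, 3):
        raise ValueError("top_k_overlap takes 2 or 3 ranked lists")
    for name, lst in named:
        if len(lst) < k:
            raise ValueError(f"list {name!r} has fewer than k={k} genes")
    tops = {name: set(lst[:k]) for name, lst in named}
    names = [name for name, _ in named]
    logger.info("top-%d sets: %s", k, {n: len(s) for n, s in tops.items()})
    regions: dict[frozenset, int] = {}
    universe = set().union(*tops.values())
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(tops[n] for n in combo))
            outside = set().union(*(tops[n] for n in names if n not in combo)) if r < len(names) else set()
            regions[frozenset(combo)] = len(inside - outside)
    assert sum(regions.values()) == len(universe)
    return OverlapReport(k=k, names=names, regions=regions)
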