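"""Locus-level statistics for DMR quantification panels.

Rank-based (Mann-Whitney/Wilcoxon rank-sum) comparison of DMR
methylation between tissue groups, with the conventional significance
stars, and ordinary least-squares regression of DMR methylation against
linear-scale gene expression (microarray intensity, normalized counts
or CPM — never log-transformed here).

Tests are two-sided.  No multiple-testing correction is applied by
default (stars report raw p-values, as in the quantification panels
this mirrors); Benjamini-Hochberg adjustment is available behind a
flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

STAR_LEVELS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def p_to_stars(p: float) -> str:
    """Significance stars: ****<1e-4, ***<1e-3, **<0.01, *<0.05, else ns."""
    for cut, stars in STAR_LEVELS:
        if p < cut:
            return stars
    return "ns"


def rank_sum_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U for two groups.

    Exact null when the combined sample size is at most 20 and there
    are no ties; otherwise the normal approximation with tie
    correction.  Two groups that are all one identical value carry no
    rank information; that degenerate case returns p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return float(len(a) * len(b)) / 2.0, 1.0
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= 20 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class GroupComparison:
    """Pairwise rank tests of one DMR's methylation across tissues."""

    dmr_id: str
    groups: dict[str, np.ndarray]
    pairwise: dict[tuple[str, str], tuple[float, float, str]]  # (U, p, stars)
    degenerate: list[tuple[str, str]]                          # flagged p=1 pairs


def compare_groups(values_by_tissue: Mapping[str, Sequence[float]],
                   dmr_id: str = "", mode: str = "all_vs_ref",
                   reference: str = "Bl",
                   bh_correct: bool = False) -> GroupComparison:
    """Rank-based comparison of a DMR's methylation between tissues.

    ``mode='all_vs_ref'`` (default) tests every tissue against the
    ``reference`` group (blood by default, as in quantification vs the
    circulating population); ``mode='all_pairs'`` tests every pair.
    ``bh_correct=True`` applies Benjamini-Hochberg across the tested
    pairs before assigning stars.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_tissue.items()}
    if mode == "all_vs_ref":
        if reference not in groups:
            raise KeyError(f"reference group {reference!r} absent")
        pairs = [(t, reference) for t in groups if t != reference]
    elif mode == "all_pairs":
        pairs = list(combinations(sorted(groups), 2))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    raw = {}
    degenerate = []
    for a, b in pairs:
        u, p = rank_sum_test(groups[a], groups[b])
        pooled = np.concatenate([groups[a], groups[b]])
        if np.all(pooled == pooled[0]):
            degenerate.append((a, b))
        raw[(a, b)] = (u, p)
    pvals = np.array([raw[pair][1] for pair in pairs])
    if bh_correct and len(pvals):
        from statsmodels.stats.multitest import multipletests
        pvals = multipletests(pvals, method="fdr_bh")[1]
    pairwise = {pair: (raw[pair][0], float(p), p_to_stars(float(p)))
                for pair, p in zip(pairs, pvals)}
    return GroupComparison(dmr_id, groups, pairwise, degenerate)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r: float
    r_squared: float
    p: float
    n: int


def regress_meth_expr(meth: Sequence[float], expr: Sequence[float]) -> RegressionResult:
    """Simple linear regression of expression on DMR methylation.

    ``meth`` is a fraction in [0,1] per sample, ``expr`` linear-scale
    expression.  p is the two-sided t-test on the slope.  Constant
    methylation leaves the slope undefined and raises.
    """
    x = np.asarray(meth, dtype=float)
    y = np.asarray(expr, dtype=float)
    if len(x) != len(y):
        raise ValueError("meth and expr lengths differ")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in methylation: slope undefined")
    res = sps.linregress(x, y)
    return RegressionResult(slope=float(res.slope), intercept=float(res.intercept),
                            r=float(res.rvalue), r_squared=float(res.rvalue) ** 2,
                            p=float(res.pvalue), n=len(x))


def comparisons_table(comps: Sequence[GroupComparison]) -> pd.DataFrame:
    """Long TSV-ready table: dmr_id, group_a, group_b, U, p, stars."""
    rows = []
    for c in comps:
        for (a, b), (u, p, stars) in c.pairwise.items():
            rows.append((c.dmr_id, a, b, u, p, stars))
    return pd.DataFrame(rows, columns=["dmr_id", "group_a", "group_b", "U", "p", "stars"])
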