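"""Nonparametric group comparisons used throughout the pipeline.

Two-sample comparisons use the two-tailed Mann-Whitney U test (exact by
enumeration for small tie-free samples, tie-corrected normal approximation
otherwise); multi-group comparisons use the Kruskal-Wallis test followed by
Dunn's pairwise post-hoc z tests (Bonferroni-adjusted by default); binned
category tables (persistence intervals, rose bins) use Pearson chi-square.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .io import ValidationError

__all__ = [
    "GroupComparison",
    "mann_whitney_u",
    "kruskal_wallis",
    "dunn_posthoc",
    "chi_square_table",
]

EXACT_MWU_MAX_N = 12  # enumeration bound for the exact two-sample test


@dataclass
class GroupComparison:
    test: str
    statistic: float
    p_value: float
    group_sizes: tuple[int, ...]
    groups: tuple[str, ...] = ()
    adjustment: Optional[str] = None
    df: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")
        if not math.isfinite(self.statistic):
            raise ValidationError("non-finite test statistic")


def _as_sample(x, name: str) -> np.ndarray:
    arr = np.asarray(list(x), dtype=float)
    if arr.size == 0:
        raise ValidationError(f"sample {name!r} is empty")
    if not np.isfinite(arr).all():
        raise ValidationError(f"sample {name!r} contains non-finite values")
    return arr


def mann_whitney_u(x, y, mode: str = "auto",
                   names: tuple[str, str] = ("x", "y")) -> GroupComparison:
    """Two-tailed Mann-Whitney U test.

    The reported statistic is min(U_x, U_y).  ``mode='auto'`` uses exact
    enumeration of rank assignments when n_x + n_y <= 12 and there are no
    ties, and the tie-corrected normal approximation (with continuity
    correction) otherwise; 'exact' and 'normal' force the method.
    """
    xs = _as_sample(x, names[0])
    ys = _as_sample(y, names[1])
    pooled = np.concatenate([xs, ys])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if mode == "auto":
        method = "exact" if (len(pooled) <= EXACT_MWU_MAX_N
                             and not has_ties) else "asymptotic"
    elif mode == "exact":
        method = "exact"
    elif mode == "normal":
        method = "asymptotic"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    res = sps.mannwhitneyu(xs, ys, alternative="two-sided", method=method)
    u_x = float(res.statistic)
    u_min = min(u_x, len(xs) * len(ys) - u_x)
    return GroupComparison(
        test=f"mann-whitney-u ({method})",
        statistic=u_min,
        p_value=float(min(res.pvalue, 1.0)),
        group_sizes=(len(xs), len(ys)),
        groups=names,
    )


def kruskal_wallis(groups: Sequence, names: Optional[Sequence[str]] = None,
                   ) -> GroupComparison:
    """Tie-corrected Kruskal-Wallis H test with a chi-square p (k-1 df)."""
    if len(groups) < 2:
        raise ValidationError("kruskal_wallis needs >= 2 groups")
    names = tuple(names) if names else tuple(f"g{i}" for i in range(len(groups)))
    samples = [_as_sample(g, n) for g, n in zip(groups, names)]
    if sum(len(s) for s in samples) < 3:
        raise ValidationError("kruskal_wallis needs total n >= 3")
    pooled = np.concatenate(samples)
    if np.ptp(pooled) == 0:
        # every pooled observation identical: H = 0 by definition
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*samples)
    return GroupComparison(test="kruskal-wallis", statistic=float(h),
                           p_value=float(p), df=len(samples) - 1,
                           group_sizes=tuple(len(s) for s in samples),
                           groups=names)


def dunn_posthoc(groups: Sequence, names: Optional[Sequence[str]] = None,
                 adjustment: str = "bonferroni") -> list[GroupComparison]:
    """Dunn's pairwise post-hoc comparisons after Kruskal-Wallis.

    z_ij = (mean rank_i - mean rank_j) / sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j))
    with pooled midranks and tie correction T = sum(t^3 - t) / (12(N - 1)).
    Two-sided normal p-values, Bonferroni-adjusted over all pairs by
    default (``adjustment='none'`` gives raw p-values).
    """
    if len(groups) < 2:
        raise ValidationError("dunn_posthoc needs >= 2 groups")
    if adjustment not in ("none", "bonferroni"):
        raise ValueError(f"unknown adjustment {adjustment!r}")
    names = tuple(names) if names else tuple(f"g{i}" for i in range(len(groups)))
    samples = [_as_sample(g, n) for g, n in zip(groups, names)]
    sizes = np.array([len(s) for s in samples])
    pooled = np.concatenate(samples)
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)  # midranks
    bounds = np.cumsum(sizes)
    mean_ranks = [ranks[b - s:b].mean() for s, b in zip(sizes, bounds)]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts).sum())
                     / (12.0 * (n_total - 1)))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    pairs = list(itertools.combinations(range(len(samples)), 2))
    m = len(pairs)
    out = []
    for i, j in pairs:
        se = math.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
        p_raw = 2.0 * sps.norm.sf(abs(z))
        p_adj = min(1.0, m * p_raw) if adjustment == "bonferroni" else p_raw
        out.append(GroupComparison(
            test="dunn", statistic=float(z), p_value=float(min(p_adj, 1.0)),
            group_sizes=(int(sizes[i]), int(sizes[j])),
            groups=(names[i], names[j]),
            adjustment=adjustment))
    return out


def chi_square_table(table) -> GroupComparison:
    """Pearson chi-square test on a counts table.

    A 2D table is tested against independence (df = (r-1)(c-1), no Yates
    correction); a 1D vector of bin counts is tested against uniform
    (df = k-1).  Every row and column total must be positive.
    """
    arr = np.asarray(table, dtype=float)
    if (arr < 0).any():
        raise ValidationError("counts must be non-negative")
    if arr.ndim == 1:
        if arr.sum() <= 0:
            raise ValidationError("zero total count")
        stat, p = sps.chisquare(arr)
        return GroupComparison(test="chi-square (uniform)", statistic=float(stat),
                               p_value=float(p), df=len(arr) - 1,
                               group_sizes=(int(arr.sum()),))
    if arr.ndim != 2:
        raise ValidationError("table must be 1D or 2D")
    if (arr.sum(axis=0) <= 0).any() or (arr.sum(axis=1) <= 0).any():
        raise ValidationError("every row and column total must be positive")
    stat, p, df, _ = sps.chi2_contingency(arr, correction=False)
    return GroupComparison(test="chi-square (independence)",
                           statistic=float(stat), p_value=float(p),
                           df=int(df),
                           group_sizes=tuple(int(s) for s in arr.sum(axis=1)))
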