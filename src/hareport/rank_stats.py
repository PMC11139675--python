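"""Rank-based k-sample tests: Kruskal–Wallis, Dunn post hoc, BH adjustment.

These are the nonparametric tests used throughout the pipeline to compare
activity offsets across seasons and daily distances across months. Mid-ranks
are used for ties; the Kruskal–Wallis p-value comes from the chi-square
approximation with k−1 degrees of freedom (group sizes in this pipeline are
large, so no exact small-sample tables). Dunn z statistics use the pooled
mean-rank variance with tie correction and two-sided p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class RankTestResult:
    H: float
    df: int
    p: float
    group_sizes: tuple[int, ...]
    tie_correction: float  # C in H_corrected = H / C; 1.0 when no ties
    warning: str | None = None


@dataclass(frozen=True)
class PairwiseResult:
    group_a: int | str
    group_b: int | str
    z: float
    p_raw: float
    p_adjusted: float


def _pooled_ranks(groups: list[np.ndarray]) -> tuple[np.ndarray, list[np.ndarray]]:
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)  # mid-ranks for ties
    out, i = [], 0
    for g in groups:
        out.append(ranks[i : i + len(g)])
        i += len(g)
    return ranks, out


def _tie_term(ranks: np.ndarray) -> float:
    """Σ (t³ − t) over tie groups of the pooled sample."""
    _, counts = np.unique(ranks, return_counts=True)
    t = counts.astype(float)
    return float(np.sum(t**3 - t))


def kruskal_wallis(groups) -> RankTestResult:
    """Kruskal–Wallis H test across k ≥ 2 groups.

    Raises on empty groups. When every observation is tied (zero rank
    variance) H is defined as 0 with a warning rather than 0/0.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in gs):
        raise ValueError("empty group passed to kruskal_wallis")
    n = sum(len(g) for g in gs)
    ranks, per_group = _pooled_ranks(gs)
    h = 12.0 / (n * (n + 1)) * sum(
        r.sum() ** 2 / len(r) for r in per_group
    ) - 3.0 * (n + 1)
    tie = _tie_term(ranks)
    c = 1.0 - tie / (n**3 - n)
    df = len(gs) - 1
    if c <= 0.0:  # all observations identical
        return RankTestResult(
            H=0.0, df=df, p=1.0, group_sizes=tuple(len(g) for g in gs),
            tie_correction=0.0, warning="all observations tied; H defined as 0",
        )
    h_corr = h / c
    h_corr = max(h_corr, 0.0)  # guard tiny negative rounding
    p = float(sps.chi2.sf(h_corr, df))
    return RankTestResult(
        H=float(h_corr), df=df, p=p,
        group_sizes=tuple(len(g) for g in gs), tie_correction=float(c),
    )


def dunn_posthoc(groups, labels=None) -> list[PairwiseResult]:
    """Dunn's pairwise mean-rank comparisons with BH-adjusted p-values.

    z_ij = (R̄_i − R̄_j) / sqrt( (N(N+1)/12 − T/(12(N−1))) (1/n_i + 1/n_j) )
    where T = Σ(t³ − t) over pooled tie groups. p-values are two-sided
    normal tails, adjusted across all pairs by Benjamini–Hochberg.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in gs):
        raise ValueError("empty group passed to dunn_posthoc")
    if labels is None:
        labels = list(range(len(gs)))
    n = sum(len(g) for g in gs)
    ranks, per_group = _pooled_ranks(gs)
    mean_ranks = [r.mean() for r in per_group]
    tie = _tie_term(ranks)
    var_base = n * (n + 1) / 12.0 - tie / (12.0 * (n - 1))
    pairs, zs, praw = [], [], []
    for i in range(len(gs)):
        for j in range(i + 1, len(gs)):
            se = np.sqrt(var_base * (1.0 / len(gs[i]) + 1.0 / len(gs[j])))
            z = 0.0 if se == 0.0 else (mean_ranks[i] - mean_ranks[j]) / se
            pairs.append((labels[i], labels[j]))
            zs.append(float(z))
            praw.append(float(2.0 * sps.norm.sf(abs(z))))
    padj = bh_adjust(praw)
    return [
        PairwiseResult(a, b, z, pr, pa)
        for (a, b), z, pr, pa in zip(pairs, zs, praw, padj)
    ]


def bh_adjust(p_values) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, original order kept."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank down, cap at 1
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out.tolist()
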