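"""Rank-rank hypergeometric overlap (RRHO) between two ranked gene lists.

Two differential tables are each ranked by signed log2 fold-change; for every
pair of rank thresholds (i, j) the overlap k between the two top lists is
scored with the upper tail of the hypergeometric distribution,

    p(i, j) = P(X >= k),  X ~ Hypergeom(N, i, j),

over the common gene universe of size N. The matrix of p-values is corrected
jointly with the Benjamini-Yekutieli step-up procedure, which controls the FDR
under the arbitrary positive dependence created by nested prefixes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: cap for -log10(p) values; avoids infinities when p underflows
NEGLOG_CAP = 320.0


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """Exact upper-tail hypergeometric probability ``P(X >= k)``.

    X counts the overlap between a fixed set of size ``K`` and a uniformly
    random subset of size ``n`` drawn without replacement from a universe of
    size ``N``.

    Parameters
    ----------
    k : smallest overlap included in the tail.
    N : universe size.
    K : size of the fixed set.
    n : size of the random draw.
    """
    if not (0 <= k and K <= N and n <= N and k <= min(K, n)):
        raise ValueError(
            f"inconsistent hypergeometric parameters k={k}, N={N}, K={K}, n={n}"
        )
    if k == 0:
        return 1.0
    # sf(k-1) = P(X >= k); scipy computes this with log-space internals
    return float(stats.hypergeom.sf(k - 1, N, K, n))


@dataclass
class RankedGeneList:
    """Gene ids ordered by signed log2 fold-change (descending by default)."""

    ids: list[str]
    log2fc: np.ndarray

    def __post_init__(self) -> None:
        if len(self.ids) != len(set(self.ids)):
            raise ValueError("ranked list ids must be unique")
        self.log2fc = np.asarray(self.log2fc, dtype=float)

    def __len__(self) -> int:
        return len(self.ids)


def rank_by_fold_change(
    table: pd.DataFrame, direction: str = "descending"
) -> RankedGeneList:
    """Order a differential table by signed log2FC; ties break by feature id.

    ``direction='descending'`` puts the most upregulated feature first.
    """
    if direction not in ("descending", "ascending"):
        raise ValueError(f"unknown direction {direction!r}")
    fc = table["log2fc"].to_numpy(dtype=float)
    if not np.all(np.isfinite(fc)):
        raise ValueError("log2fc contains non-finite values")
    sub = table[["feature_id", "log2fc"]].sort_values(
        ["log2fc", "feature_id"],
        ascending=[direction == "ascending", True],
        kind="mergesort",
    )
    return RankedGeneList(
        ids=sub["feature_id"].tolist(),
        log2fc=sub["log2fc"].to_numpy(dtype=float),
    )


@dataclass
class RRHOMap:
    """Grid of overlap counts and (corrected) hypergeometric significance."""

    step: int
    thresholds_a: np.ndarray
    thresholds_b: np.ndarray
    k_matrix: np.ndarray
    neglog_p: np.ndarray
    neglog_p_adj: np.ndarray
    universe_n: int
    universe: list[str] = field(default_factory=list)

    @property
    def max_neglog_p_adj(self) -> float:
        return float(self.neglog_p_adj.max())

    def any_significant(self, alpha: float = 0.05) -> bool:
        """Whether any cell survives BY correction at level ``alpha``."""
        return bool(self.max_neglog_p_adj > -np.log10(alpha))


def by_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjusted p-values (order preserved)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p.ravel(), method="fdr_by")[1].reshape(p.shape)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserved)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p.ravel(), method="fdr_bh")[1].reshape(p.shape)


def default_step(n: int) -> int:
    """Default threshold step: ~100x100 grid regardless of universe size."""
    return max(1, n // 100)


def rrho_map(a: RankedGeneList, b: RankedGeneList, step: int | None = None) -> RRHOMap:
    """Overlap significance over all pairs of rank thresholds.

    Both lists are restricted to their common universe (preserving each list's
    own order); thresholds run over multiples of ``step`` up to N. Prefix
    overlap counts are accumulated from a single pass over joint ranks, so the
    cost is ~N plus the number of grid cells.
    """
    common = set(a.ids) & set(b.ids)
    if not common:
        raise ValueError("ranked lists share no genes; RRHO undefined")
    ids_a = [g for g in a.ids if g in common]
    ids_b = [g for g in b.ids if g in common]
    n = len(common)
    if step is None:
        step = default_step(n)
    if step < 1:
        raise ValueError("step must be >= 1")

    rank_b = {g: r for r, g in enumerate(ids_b)}
    # joint (rank in a, rank in b) per gene, both 0-based
    ra = np.arange(n)
    rb = np.array([rank_b[g] for g in ids_a])

    thresholds = np.arange(step, n + 1, step)
    if thresholds[-1] != n:
        thresholds = np.append(thresholds, n)
    # cell (i, j) counts genes with rank_a < t_i and rank_b < t_j:
    # bin each gene by the first threshold that includes it, then cumsum
    ia = np.searchsorted(thresholds, ra + 1)
    ib = np.searchsorted(thresholds, rb + 1)
    grid = np.zeros((len(thresholds), len(thresholds)), dtype=np.int64)
    np.add.at(grid, (ia, ib), 1)
    k = np.cumsum(np.cumsum(grid, axis=0), axis=1)

    ti = thresholds[:, None].astype(float)
    tj = thresholds[None, :].astype(float)
    with np.errstate(divide="ignore"):
        p = stats.hypergeom.sf(k - 1, n, ti, tj)
    p = np.clip(p, 0.0, 1.0)
    p_adj = by_adjust(p)

    tiny = 10.0 ** (-NEGLOG_CAP)
    neglog_p = -np.log10(np.maximum(p, tiny))
    neglog_p_adj = -np.log10(np.maximum(p_adj, tiny))
    return RRHOMap(
        step=step,
        thresholds_a=thresholds,
        thresholds_b=thresholds,
        k_matrix=k,
        neglog_p=neglog_p,
        neglog_p_adj=neglog_p_adj,
        universe_n=n,
        universe=sorted(common),
    )


def shared_top_signature(
    a: RankedGeneList, b: RankedGeneList, n_top: int = 150
) -> list[str]:
    """The strongest shared upregulated signature between two ranked lists.

    Prefixes of both lists are grown jointly one rank at a time; genes present
    in both current prefixes are collected until ``n_top`` are found. The
    result is ordered by the mean of the two ranks, so genes high in both
    lists come first.
    """
    common = set(a.ids) & set(b.ids)
    ids_a = [g for g in a.ids if g in common]
    ids_b = [g for g in b.ids if g in common]
    rank_a = {g: r for r, g in enumerate(ids_a)}
    rank_b = {g: r for r, g in enumerate(ids_b)}

    shared: list[str] = []
    in_a: set[str] = set()
    in_b: set[str] = set()
    for depth in range(len(ids_a)):
        for g, seen_here, seen_other in (
            (ids_a[depth], in_a, in_b),
            (ids_b[depth], in_b, in_a),
        ):
            seen_here.add(g)
            if g in seen_other:
                shared.append(g)
        if len(shared) >= n_top:
            break
    if len(shared) < n_top:
        warnings.warn(
            f"only {len(shared)} shared genes available; requested {n_top}",
            stacklevel=2,
        )
    shared = shared[:n_top] if len(shared) > n_top else shared
    return sorted(shared, key=lambda g: ((rank_a[g] + rank_b[g]) / 2.0, g))
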