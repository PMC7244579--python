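"""Weighted co-expression networks: adjacency, topological overlap, modules.

The network is unsigned: adjacency ``a_ij = |cor(x_i, x_j)|^beta`` with the
soft-threshold power ``beta`` chosen per layer (10 for transcripts, 14 for
proteins by default). Pairwise similarity is the topological overlap

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),

with connectivity ``k_i = sum_{u != i} a_iu`` and ``TOM_ii = 1``. Modules are
average-linkage clusters of ``1 - TOM`` cut at a fixed height, merged when
their eigengenes (first principal components) correlate strongly, and scored
for quality by a resampling Z of density and separability.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)


def normalize_within_group(
    values: pd.DataFrame, meta: pd.DataFrame, group_by: str = "time_h"
) -> pd.DataFrame:
    """Z-score each feature within each sample group (mean 0, sd 1; ddof=1).

    Zero-variance features within a group become zeros with a warning; groups
    of a single sample are rejected because the sample sd is undefined.
    """
    out = values.copy().astype(float)
    n_degenerate = 0
    for _, idx in meta.groupby(group_by).groups.items():
        cols = meta.loc[idx, "sample"].tolist()
        if len(cols) < 2:
            raise ValueError(f"group of a single sample under {group_by!r}")
        block = out[cols]
        mu = block.mean(axis=1)
        sd = block.std(axis=1, ddof=1)
        zero = sd == 0
        n_degenerate += int(zero.sum())
        sd = sd.replace(0, 1.0)
        out[cols] = block.sub(mu, axis=0).div(sd, axis=0)
        out.loc[zero, cols] = 0.0
    if n_degenerate:
        warnings.warn(
            f"{n_degenerate} zero-variance feature/group blocks set to 0",
            stacklevel=2,
        )
    return out


@dataclass
class CoexpressionNetwork:
    feature_ids: list[str]
    adjacency: np.ndarray
    tom: np.ndarray
    soft_power: int


def adjacency_from_values(values: np.ndarray, soft_power: int) -> np.ndarray:
    """Unsigned soft-threshold adjacency from a features x samples array."""
    sd = values.std(axis=1)
    if np.any(sd == 0):
        raise ValueError("constant feature: correlation undefined")
    corr = np.corrcoef(values)
    adj = np.abs(np.clip(corr, -1.0, 1.0)) ** soft_power
    np.fill_diagonal(adj, 1.0)
    return adj


def tom_from_adjacency(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of an unsigned adjacency."""
    a = adjacency
    # shared-neighbor term excluding u in {i, j}; a_ii = a_jj = 1
    shared = a @ a - 2.0 * a
    k = a.sum(axis=1) - 1.0
    kmin = np.minimum.outer(k, k)
    tom = (shared + a) / (kmin + 1.0 - a)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def build_network(
    values: pd.DataFrame, soft_power: int
) -> CoexpressionNetwork:
    """Adjacency + TOM for a features x samples expression matrix."""
    if values.shape[1] < 4:
        raise ValueError("need >= 4 samples to estimate correlations")
    if soft_power < 1:
        raise ValueError("soft_power must be >= 1")
    adj = adjacency_from_values(values.to_numpy(dtype=float), soft_power)
    tom = tom_from_adjacency(adj)
    return CoexpressionNetwork(
        feature_ids=list(values.index), adjacency=adj, tom=tom, soft_power=soft_power
    )


@dataclass
class ModuleSet:
    """Feature-to-module assignment; label 0 marks unassigned features."""

    assignment: pd.Series  # index = feature id, value = int label
    eigengenes: dict[int, np.ndarray] = field(default_factory=dict)
    merge_history: list[tuple[int, int]] = field(default_factory=list)

    def members(self, label: int) -> list[str]:
        return self.assignment.index[self.assignment == label].tolist()

    @property
    def labels(self) -> list[int]:
        return sorted(set(self.assignment) - {0})

    def sizes(self) -> dict[int, int]:
        return {m: int((self.assignment == m).sum()) for m in self.labels}


def detect_modules(
    network: CoexpressionNetwork,
    min_module_size: int = 20,
    cut_height: float = 0.99,
) -> ModuleSet:
    """Average-linkage clustering of ``1 - TOM`` with a static height cut.

    Clusters smaller than ``min_module_size`` are left unassigned (label 0);
    surviving modules are relabelled 1..M by decreasing size.
    """
    diss = 1.0 - network.tom
    np.fill_diagonal(diss, 0.0)
    condensed = squareform(diss, checks=False)
    linkage = hierarchy.linkage(condensed, method="average")
    raw = hierarchy.fcluster(linkage, t=cut_height, criterion="distance")

    ids = network.feature_ids
    counts = pd.Series(raw).value_counts()
    keep = counts[counts >= min_module_size]
    # order surviving clusters by decreasing size, ties by cluster id
    ordered = sorted(keep.items(), key=lambda kv: (-kv[1], kv[0]))
    relabel = {old: new for new, (old, _) in enumerate(ordered, start=1)}
    labels = np.array([relabel.get(c, 0) for c in raw], dtype=int)
    if labels.max(initial=0) == 0:
        warnings.warn("no module reached min_module_size; all unassigned",
                      stacklevel=2)
    return ModuleSet(assignment=pd.Series(labels, index=ids))


def module_eigengene(values: pd.DataFrame, members: list[str]) -> np.ndarray:
    """First principal component of the standardized member submatrix.

    Returned with unit variance (ddof=1) and oriented so that it correlates
    non-negatively with the mean member profile, i.e. the eigengene tracks,
    rather than mirrors, its members.
    """
    if len(members) < 2:
        raise ValueError("eigengene needs >= 2 member features")
    sub = values.loc[members].to_numpy(dtype=float)
    if sub.shape[1] < 2:
        raise ValueError("eigengene needs >= 2 samples")
    mu = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (sub - mu) / sd
    # PC1 across samples: right singular vector of the standardized matrix
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    pc1 = vt[0]
    mean_profile = z.mean(axis=0)
    if np.dot(pc1, mean_profile) < 0:
        pc1 = -pc1
    sd1 = pc1.std(ddof=1)
    if sd1 == 0:
        raise ValueError("degenerate eigengene (constant PC1)")
    return (pc1 - pc1.mean()) / sd1


def _all_eigengenes(values: pd.DataFrame, modules: ModuleSet) -> dict[int, np.ndarray]:
    return {
        m: module_eigengene(values, modules.members(m)) for m in modules.labels
    }


def merge_modules(
    modules: ModuleSet,
    values: pd.DataFrame,
    dissimilarity_threshold: float = 0.25,
) -> ModuleSet:
    """Iteratively merge the closest eigengene pair while d = 1 - cor < threshold.

    Eigengenes are recomputed after every merge, so the procedure reaches a
    fixed point where every surviving pair has dissimilarity >= threshold.
    """
    assignment = modules.assignment.copy()
    history: list[tuple[int, int]] = []
    while True:
        current = ModuleSet(assignment=assignment)
        labels = current.labels
        if len(labels) < 2:
            break
        eig = _all_eigengenes(values, current)
        best: tuple[float, int, int] | None = None
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                d = 1.0 - float(np.corrcoef(eig[a], eig[b])[0, 1])
                if best is None or d < best[0]:
                    best = (d, a, b)
        assert best is not None
        d, a, b = best
        if d >= dissimilarity_threshold:
            break
        assignment[assignment == b] = a
        history.append((b, a))
    merged = ModuleSet(assignment=assignment)
    # relabel 1..M by decreasing size for a stable public labelling
    ordered = sorted(merged.sizes().items(), key=lambda kv: (-kv[1], kv[0]))
    relabel = {old: new for new, (old, _) in enumerate(ordered, start=1)}
    relabel[0] = 0
    final = ModuleSet(
        assignment=merged.assignment.map(relabel),
        merge_history=history,
    )
    final.eigengenes = _all_eigengenes(values, final)
    return final


def module_density_separability(
    adjacency: np.ndarray, member_idx: np.ndarray
) -> tuple[float, float]:
    """Observed quality statistics of one module on a given adjacency.

    density = mean intra-module adjacency (off-diagonal);
    separability = density - mean adjacency from members to non-members.
    """
    n = adjacency.shape[0]
    mask = np.zeros(n, dtype=bool)
    mask[member_idx] = True
    intra = adjacency[np.ix_(mask, mask)]
    m = intra.shape[0]
    density = float((intra.sum() - m) / (m * (m - 1)))
    if mask.all():
        return density, float("nan")
    cross = adjacency[np.ix_(mask, ~mask)]
    separability = density - float(cross.mean())
    return density, separability


@dataclass
class PreservationStats:
    """Resampling Z-scores of module density and separability."""

    table: pd.DataFrame  # module, size, density, separability, z_density, z_separability, z_summary
    n_resamples: int

    def z_summary(self, module: int) -> float:
        row = self.table[self.table["module"] == module]
        return float(row["z_summary"].iloc[0])


def module_quality(
    values: pd.DataFrame,
    modules: ModuleSet,
    soft_power: int,
    n_resamples: int = 100,
    seed: int = 0,
) -> PreservationStats:
    """Resampling quality Z_summary per module.

    For each resample, samples (columns) are bootstrapped, the network is
    rebuilt, and a size-matched random feature set plays the module's role;
    the observed density/separability are standardized against this null.
    Z_summary is the median of the two Z statistics; >2 reads as moderate and
    >10 as high quality.
    """
    if n_resamples < 20:
        raise ValueError("need >= 20 resamples for a stable null")
    rng = np.random.default_rng(seed)
    x = values.to_numpy(dtype=float)
    n_feat, n_samp = x.shape
    ids = list(values.index)
    pos = {f: i for i, f in enumerate(ids)}

    adj_obs = adjacency_from_values(x, soft_power)
    rows = []
    observed = {}
    for m in modules.labels:
        idx = np.array([pos[f] for f in modules.members(m)])
        observed[m] = (idx, module_density_separability(adj_obs, idx))

    null_d = {m: np.empty(n_resamples) for m in modules.labels}
    null_s = {m: np.empty(n_resamples) for m in modules.labels}
    for r in range(n_resamples):
        cols = rng.integers(0, n_samp, size=n_samp)
        xb = x[:, cols]
        # guard against bootstrap-constant features
        sd = xb.std(axis=1)
        if np.any(sd == 0):
            xb = xb + rng.normal(scale=1e-9, size=xb.shape)
        adj_b = adjacency_from_values(xb, soft_power)
        for m in modules.labels:
            size = observed[m][0].size
            rand_idx = rng.choice(n_feat, size=size, replace=False)
            d, s = module_density_separability(adj_b, rand_idx)
            null_d[m][r] = d
            null_s[m][r] = s

    for m in modules.labels:
        idx, (d_obs, s_obs) = observed[m]
        zd = _z(d_obs, null_d[m])
        zs = _z(s_obs, null_s[m])
        rows.append(
            {
                "module": m,
                "size": idx.size,
                "density": d_obs,
                "separability": s_obs,
                "z_density": zd,
                "z_separability": zs,
                "z_summary": float(np.median([zd, zs])),
            }
        )
    return PreservationStats(table=pd.DataFrame(rows), n_resamples=n_resamples)


def _z(obs: float, null: np.ndarray) -> float:
    sd = float(null.std(ddof=1))
    if sd == 0:
        warnings.warn("null sd = 0; Z reported as +inf", stacklevel=2)
        return float("inf") if obs > float(null.mean()) else float("-inf")
    return (obs - float(null.mean())) / sd
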