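"""Cross-layer integration: DEG/DAP selection, module overlap, splicing strata.

mRNA and protein co-expression modules are first restricted to differentially
expressed genes (|FC| > 1.5, FDR < 0.05) and differentially abundant proteins
(t-test p < 0.05); every (mRNA module, protein module) pair is then scored by
the hypergeometric tail of its common-member count, Benjamini-Hochberg
corrected across pairs, and retained when FDR < 0.05 with >= 10 members in
common. Protein changes can further be stratified by retained-intron delta-PSI
to test the coupling between intron removal and protein induction.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from omixlink.coexpression import ModuleSet
from omixlink.rrho import bh_adjust, hypergeom_tail

logger = logging.getLogger(__name__)


def derive_status(
    table: pd.DataFrame, fc: float = 1.5, fdr: float = 0.05
) -> pd.DataFrame:
    """Add/refresh the status column from fold-change and FDR thresholds."""
    out = table.copy()
    linear_fc = 2.0 ** out["log2fc"].to_numpy(dtype=float)
    abs_fc = np.maximum(linear_fc, 1.0 / linear_fc)
    sig = (abs_fc > fc) & (out["fdr"].to_numpy() < fdr)
    out["status"] = np.where(
        sig & (out["log2fc"] > 0), "up", np.where(sig, "down", "stable")
    )
    return out


def select_deg(table: pd.DataFrame, fc: float = 1.5, fdr: float = 0.05) -> set[str]:
    """Differentially expressed features: absolute linear FC > fc, FDR < fdr.

    Both tails; inequalities strict.
    """
    linear_fc = 2.0 ** table["log2fc"].to_numpy(dtype=float)
    abs_fc = np.maximum(linear_fc, 1.0 / linear_fc)
    mask = (abs_fc > fc) & (table["fdr"].to_numpy() < fdr)
    return set(table.loc[mask, "feature_id"])


def select_dap(table: pd.DataFrame, p: float = 0.05) -> set[str]:
    """Differentially abundant proteins: raw t-test p-value < p (strict)."""
    mask = table["p_value"].to_numpy() < p
    return set(table.loc[mask, "feature_id"])


def restrict_modules(modules: ModuleSet, keep: set[str]) -> dict[int, set[str]]:
    """Module membership restricted to a feature subset; empty modules drop."""
    out = {}
    for m in modules.labels:
        members = set(modules.members(m)) & keep
        if members:
            out[m] = members
    return out


def module_overlap(
    mrna_modules: dict[int, set[str]],
    prot_modules: dict[int, set[str]],
    universe: set[str] | None = None,
    overlap_fdr: float = 0.05,
    overlap_min: int = 10,
) -> pd.DataFrame:
    """Hypergeometric overlap of every (mRNA module, protein module) pair.

    The default universe is the union of all module members in both layers
    (after restriction), which keeps p-values conservative. Pairs are
    significant when BH FDR < ``overlap_fdr`` and the common-member count is
    at least ``overlap_min``.
    """
    if universe is None:
        universe = set().union(*mrna_modules.values(), *prot_modules.values()) \
            if (mrna_modules or prot_modules) else set()
    if not universe:
        raise ValueError("empty overlap universe")
    n_universe = len(universe)

    rows = []
    for ma, seta in sorted(mrna_modules.items()):
        a = seta & universe
        for mb, setb in sorted(prot_modules.items()):
            b = setb & universe
            common = a & b
            k = len(common)
            p = hypergeom_tail(k, n_universe, len(a), len(b)) if k else 1.0
            rows.append(
                {
                    "mrna_module": ma,
                    "prot_module": mb,
                    "n_mrna": len(a),
                    "n_prot": len(b),
                    "k_common": k,
                    "p": p,
                    "shared_ids": ",".join(sorted(common)),
                }
            )
    result = pd.DataFrame(rows)
    if len(result):
        result["fdr"] = bh_adjust(result["p"].to_numpy())
        result["significant"] = (result["fdr"] < overlap_fdr) & (
            result["k_common"] >= overlap_min
        )
    return result


def validate_splicing_events(events: pd.DataFrame) -> pd.DataFrame:
    required = {"event_id", "gene_id", "dpsi", "fdr", "event_type"}
    missing = required - set(events.columns)
    if missing:
        raise ValueError(f"splicing event table missing columns {sorted(missing)}")
    if (events["dpsi"].abs() > 1).any():
        raise ValueError("|dpsi| exceeds 1")
    return events


def stratify_protein_by_dpsi(
    events: pd.DataFrame,
    proteins: pd.DataFrame,
    dpsi_cut: float = 0.2,
    fdr_cut: float = 0.05,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> dict:
    """Protein log2FC stratified by retained-intron delta-PSI direction.

    Groups: removal (dpsi < -cut, FDR < fdr_cut), retention (dpsi > cut,
    FDR < fdr_cut), unchanged (everything else). A one-way permutation ANOVA
    (F statistic, label permutation) tests for any between-group difference.
    """
    events = validate_splicing_events(events)
    ri = events[events["event_type"] == "retained_intron"]
    merged = ri.merge(
        proteins[["feature_id", "log2fc"]],
        left_on="gene_id",
        right_on="feature_id",
        how="inner",
    )
    sig = merged["fdr"] < fdr_cut
    group = np.where(
        sig & (merged["dpsi"] < -dpsi_cut),
        "removal",
        np.where(sig & (merged["dpsi"] > dpsi_cut), "retention", "unchanged"),
    )
    merged["group"] = group

    summaries = {}
    for g in ("removal", "retention", "unchanged"):
        vals = merged.loc[merged["group"] == g, "log2fc"].to_numpy()
        summaries[g] = {
            "n": int(vals.size),
            "mean": float(vals.mean()) if vals.size else np.nan,
            "sem": float(vals.std(ddof=1) / np.sqrt(vals.size))
            if vals.size > 1
            else np.nan,
        }

    if any(summaries[g]["n"] == 0 for g in summaries):
        warnings.warn("empty delta-PSI group; permutation test skipped",
                      stacklevel=2)
        return {"summaries": summaries, "anova_p": None}

    values = merged["log2fc"].to_numpy(dtype=float)
    labels = merged["group"].to_numpy()
    observed = _f_statistic(values, labels)
    rng = np.random.default_rng(seed)
    perm_labels = labels.copy()
    count = 0
    for _ in range(n_permutations):
        rng.shuffle(perm_labels)
        if _f_statistic(values, perm_labels) >= observed:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return {"summaries": summaries, "anova_f": observed, "anova_p": float(p)}


def _f_statistic(values: np.ndarray, labels: np.ndarray) -> float:
    grand = values.mean()
    ss_between = 0.0
    ss_within = 0.0
    k = 0
    for g in np.unique(labels):
        vals = values[labels == g]
        ss_between += vals.size * (vals.mean() - grand) ** 2
        ss_within += ((vals - vals.mean()) ** 2).sum()
        k += 1
    df1 = k - 1
    df2 = values.size - k
    if df1 == 0 or df2 == 0 or ss_within == 0:
        return float("inf") if ss_between > 0 else 0.0
    return float((ss_between / df1) / (ss_within / df2))
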