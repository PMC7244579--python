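"""Synthetic multi-omics data with planted, recoverable structure.

Each generator is a pure function of its parameters and a seed, and emits the
ground truth alongside the data so downstream stages have recovery tests:

* paired mRNA/protein log-scale matrices over 2 conditions x 2 time points
  with planted correlated modules and planted per-module treatment effects,
  the protein layer being an attenuated, noisier echo of the mRNA layer
  (weaker still for downregulated features);
* peak sets where gained peaks preferentially sit within the TSS window of
  upregulated genes;
* pairs of ranked lists with an exact planted top-of-list overlap;
* Erdos-Renyi background networks with planted high-connectivity connectors.

The matrices are Gaussian on the log2 scale: the downstream statistics act on
log fold-changes and correlations, so a count layer would add nuisance without
exercising more of the analysis. Differential tables are produced by plain
two-sample Welch t-tests with Benjamini-Hochberg correction - generator
scaffolding, not an analysis claim.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from omixlink.integration import derive_status
from omixlink.rrho import RankedGeneList, bh_adjust

TIME_POINTS = (8.0, 24.0)


@dataclass
class SimTruth:
    """Ground truth planted by the generators (JSON-serializable)."""

    module_assignment: dict[str, int] = field(default_factory=dict)
    protein_module_assignment: dict[str, int] = field(default_factory=dict)
    module_pairs: list[dict] = field(default_factory=list)
    true_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    peak_targets: dict[str, str | None] = field(default_factory=dict)
    shared_top: list[str] = field(default_factory=list)
    connectors: list[str] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _sample_meta(n_per_group: int) -> pd.DataFrame:
    rows = []
    for cond in ("control", "treated"):
        for t in TIME_POINTS:
            for r in range(n_per_group):
                rows.append(
                    {
                        "sample": f"{cond}_{int(t)}h_r{r}",
                        "condition": cond,
                        "time_h": t,
                        "replicate": r,
                    }
                )
    return pd.DataFrame(rows)


def _differential_from_matrix(
    values: pd.DataFrame, meta: pd.DataFrame, time_h: float
) -> pd.DataFrame:
    """Welch t-test treated vs control at one time point, BH-corrected."""
    treated = meta[(meta["condition"] == "treated") & (meta["time_h"] == time_h)]
    control = meta[(meta["condition"] == "control") & (meta["time_h"] == time_h)]
    xt = values[treated["sample"]].to_numpy(dtype=float)
    xc = values[control["sample"]].to_numpy(dtype=float)
    log2fc = xt.mean(axis=1) - xc.mean(axis=1)
    t, p = stats.ttest_ind(xt, xc, axis=1, equal_var=False)
    p = np.nan_to_num(p, nan=1.0)
    table = pd.DataFrame(
        {
            "feature_id": values.index,
            "log2fc": log2fc,
            "p_value": p,
            "fdr": bh_adjust(p),
        }
    )
    return derive_status(table)


def simulate_multiomics(
    n_genes: int = 300,
    n_modules: int = 3,
    module_size: int = 40,
    n_samples_per_group: int = 5,
    intra_cor: float = 0.8,
    effect_sd: float = 1.0,
    noise_sd: float = 0.5,
    protein_attenuation: float = 0.8,
    down_decoupling_sd: float = 0.5,
    seed: int = 0,
) -> tuple[dict, dict, dict, SimTruth]:
    """Paired mRNA/protein matrices with planted modules and effects.

    Module members load on a shared per-module latent factor so that the
    expected pairwise correlation of members is ``intra_cor``; treated samples
    at each time point receive a per-module mean shift with magnitude
    ``effect_sd * (0.5 + |N(0,1)|)``. Shift signs are structured like the
    emulated response:
    two of every three modules are upregulated, one downregulated, with the
    direction persisting across time points.
    The protein layer carries ``protein_attenuation`` times the mRNA effect,
    plus extra decoupling noise on downregulated modules (mirroring the weaker
    down-concordance between transcript and protein layers), and has its own
    latent factors so within-layer module structure is preserved.

    Returns ``(mrna, protein, differential, truth)`` where ``mrna`` and
    ``protein`` are dicts with ``values``/``meta`` and ``differential`` maps
    ``(layer, time_h)`` to a differential table.
    """
    if n_modules * module_size > n_genes:
        raise ValueError("n_modules * module_size exceeds n_genes")
    rng = np.random.default_rng(seed)
    meta = _sample_meta(n_samples_per_group)
    n_samples = len(meta)
    genes = [f"g{i:05d}" for i in range(n_genes)]

    assignment = np.zeros(n_genes, dtype=int)
    for m in range(n_modules):
        assignment[m * module_size: (m + 1) * module_size] = m + 1

    # per-module, per-time treatment shifts (log2 units); signs follow the
    # emulated response structure: predominance of upregulation (2 of every 3
    # modules up), direction persistent across time points
    # magnitude bounded away from zero (strong, reliable induction as in the
    # emulated response); effect_sd = 0 still yields an exact null
    magnitudes = effect_sd * (
        0.5 + np.abs(rng.standard_normal((n_modules, len(TIME_POINTS))))
    )
    signs = np.array([-1.0 if (m + 1) % 3 == 0 else 1.0
                      for m in range(n_modules)])
    shifts = magnitudes * signs[:, None]
    treated = (meta["condition"] == "treated").to_numpy()
    time_idx = meta["time_h"].map({t: i for i, t in enumerate(TIME_POINTS)}).to_numpy()

    def layer(atten: float, decouple_sd: float) -> np.ndarray:
        latents = rng.standard_normal((n_modules, n_samples))
        x = np.sqrt(1.0 - intra_cor) * rng.standard_normal((n_genes, n_samples))
        for m in range(n_modules):
            rows = assignment == m + 1
            x[rows] += np.sqrt(intra_cor) * latents[m]
        x *= noise_sd
        for m in range(n_modules):
            rows = assignment == m + 1
            for ti in range(len(TIME_POINTS)):
                cols = treated & (time_idx == ti)
                eff = shifts[m, ti] * atten
                if atten < 1.0 and shifts[m, ti] < 0:
                    # protein layer: decouple downregulated modules
                    eff += rng.normal(scale=decouple_sd)
                x[np.ix_(rows, cols)] += eff
        return x

    x_mrna = layer(1.0, 0.0)
    x_prot = layer(protein_attenuation, down_decoupling_sd)

    mrna_values = pd.DataFrame(x_mrna, index=genes, columns=meta["sample"])
    prot_values = pd.DataFrame(x_prot, index=genes, columns=meta["sample"])

    differential = {
        (layer_name, t): _differential_from_matrix(vals, meta, t)
        for layer_name, vals in (("mrna", mrna_values), ("protein", prot_values))
        for t in TIME_POINTS
    }

    truth = SimTruth(
        module_assignment={g: int(a) for g, a in zip(genes, assignment)},
        protein_module_assignment={g: int(a) for g, a in zip(genes, assignment)},
        module_pairs=[
            {"mrna_module": m + 1, "prot_module": m + 1, "k": module_size}
            for m in range(n_modules)
        ],
        true_effects={
            g: {
                str(t): float(shifts[assignment[i] - 1, ti]) if assignment[i] else 0.0
                for ti, t in enumerate(TIME_POINTS)
            }
            for i, g in enumerate(genes)
        },
        params={
            "n_genes": n_genes,
            "n_modules": n_modules,
            "module_size": module_size,
            "n_samples_per_group": n_samples_per_group,
            "intra_cor": intra_cor,
            "effect_sd": effect_sd,
            "noise_sd": noise_sd,
            "protein_attenuation": protein_attenuation,
            "down_decoupling_sd": down_decoupling_sd,
            "seed": seed,
        },
    )
    return (
        {"values": mrna_values, "meta": meta},
        {"values": prot_values, "meta": meta},
        differential,
        truth,
    )


def simulate_annotation(
    n_genes: int = 300,
    n_chroms: int = 4,
    gene_spacing: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Evenly spaced strand-alternating TSS annotation on ``n_chroms`` chromosomes."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_genes):
        chrom = f"chr{i % n_chroms + 1}"
        tss = 50_000 + (i // n_chroms) * gene_spacing
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append({"gene_id": f"g{i:05d}", "chrom": chrom, "tss": tss,
                     "strand": strand})
    return pd.DataFrame(rows)


def simulate_peaks(
    annotation: pd.DataFrame,
    up_genes: set[str],
    p_gain_near_up: float = 0.9,
    p_gain_background: float = 0.1,
    n_peaks: int = 500,
    window_bp: int = 40_000,
    peak_width: int = 200,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Peaks inside TSS windows; gained more often near upregulated genes.

    Each peak targets a uniformly chosen gene and is placed entirely inside
    the gene's ``window_bp`` window; its label is gained with probability
    ``p_gain_near_up`` when the target is upregulated, ``p_gain_background``
    otherwise, and stable in the remaining cases.
    """
    if len(annotation) == 0:
        raise ValueError("empty annotation")
    if not p_gain_near_up > p_gain_background:
        raise ValueError("p_gain_near_up must exceed p_gain_background")
    rng = np.random.default_rng(seed)
    half = window_bp // 2
    rows = []
    targets: dict[str, str | None] = {}
    for i in range(n_peaks):
        gene = annotation.iloc[int(rng.integers(len(annotation)))]
        lo = max(0, gene["tss"] - half)
        hi = gene["tss"] + half - peak_width
        start = int(rng.integers(lo, max(lo + 1, hi)))
        p_gain = p_gain_near_up if gene["gene_id"] in up_genes else p_gain_background
        label = "gained" if rng.random() < p_gain else "stable"
        peak_id = f"peak_{i}"
        rows.append(
            {
                "peak_id": peak_id,
                "chrom": gene["chrom"],
                "start": start,
                "end": start + peak_width,
                "label": label,
            }
        )
        targets[peak_id] = str(gene["gene_id"])
    peaks = pd.DataFrame(
        rows, columns=["peak_id", "chrom", "start", "end", "label"]
    )
    truth = SimTruth(
        peak_targets=targets,
        params={
            "p_gain_near_up": p_gain_near_up,
            "p_gain_background": p_gain_background,
            "n_peaks": n_peaks,
            "window_bp": window_bp,
            "seed": seed,
        },
    )
    return peaks, truth


def simulate_ranked_pair(
    n: int = 1000,
    n_shared_top: int = 150,
    top_size: int = 200,
    seed: int = 0,
) -> tuple[RankedGeneList, RankedGeneList, SimTruth]:
    """Two rankings of the same ids with an exact planted prefix overlap.

    Exactly ``n_shared_top`` ids occur in both ``top_size`` prefixes; the
    prefix fillers of one list are forced into the other list's suffix, and
    everything else is uniformly shuffled.
    """
    if not (n_shared_top <= top_size <= n):
        raise ValueError("need n_shared_top <= top_size <= n")
    n_only = top_size - n_shared_top
    if 2 * top_size - n_shared_top > n:
        raise ValueError("prefixes cannot be made disjoint outside the shared set")
    rng = np.random.default_rng(seed)
    ids = np.array([f"g{i:05d}" for i in range(n)])
    perm = rng.permutation(n)
    shared = ids[perm[:n_shared_top]]
    a_only = ids[perm[n_shared_top: n_shared_top + n_only]]
    b_only = ids[perm[n_shared_top + n_only: n_shared_top + 2 * n_only]]
    rest = ids[perm[n_shared_top + 2 * n_only:]]

    def assemble(prefix_pool: np.ndarray, suffix_pool: np.ndarray) -> list[str]:
        prefix = prefix_pool[rng.permutation(len(prefix_pool))]
        suffix = suffix_pool[rng.permutation(len(suffix_pool))]
        return list(prefix) + list(suffix)

    list_a = assemble(
        np.concatenate([shared, a_only]), np.concatenate([b_only, rest])
    )
    list_b = assemble(
        np.concatenate([shared, b_only]), np.concatenate([a_only, rest])
    )
    scores = np.sort(rng.standard_normal(n))[::-1]
    ranked_a = RankedGeneList(ids=list_a, log2fc=scores.copy())
    ranked_b = RankedGeneList(ids=list_b, log2fc=scores.copy())
    truth = SimTruth(
        shared_top=sorted(shared.tolist()),
        params={"n": n, "n_shared_top": n_shared_top, "top_size": top_size,
                "seed": seed},
    )
    return ranked_a, ranked_b, truth


def simulate_background_network(
    n_nodes: int = 500,
    p_edge: float = 0.01,
    module: set[str] | None = None,
    module_size: int = 20,
    connectors: int = 3,
    k_connector: int = 8,
    planted_clique: int = 0,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Erdos-Renyi background plus planted high-connectivity connector nodes.

    ``module`` defaults to the first ``module_size`` background nodes. Each of
    ``connectors`` extra nodes is wired to ``k_connector`` distinct module
    members (and to background nodes at the background rate), so its
    module-neighborhood is far above the hypergeometric expectation.
    ``planted_clique > 0`` additionally makes the first that many module
    members a clique, giving the community stage a recoverable structure.
    """
    rng = np.random.default_rng(seed)
    nodes = [f"n{i:04d}" for i in range(n_nodes)]
    if module is None:
        module = set(nodes[:module_size])
    if k_connector > len(module):
        raise ValueError("k_connector exceeds module size")

    iu = np.triu_indices(n_nodes, k=1)
    present = rng.random(len(iu[0])) < p_edge
    edges = [
        (nodes[i], nodes[j])
        for i, j in zip(iu[0][present], iu[1][present])
    ]
    module_list = sorted(module)
    if planted_clique:
        clique = module_list[: min(planted_clique, len(module_list))]
        edges.extend(
            (clique[i], clique[j])
            for i in range(len(clique))
            for j in range(i + 1, len(clique))
        )
    connector_ids = []
    for c in range(connectors):
        cid = f"conn{c:02d}"
        connector_ids.append(cid)
        chosen = rng.choice(len(module_list), size=k_connector, replace=False)
        edges.extend((cid, module_list[i]) for i in chosen)
        background = [v for v in nodes if v not in module]
        extra = rng.random(len(background)) < p_edge
        edges.extend((cid, v) for v, keep in zip(background, extra) if keep)

    frame = pd.DataFrame(edges, columns=["source", "target"])
    lo = np.minimum(frame["source"], frame["target"])
    hi = np.maximum(frame["source"], frame["target"])
    frame = (
        pd.DataFrame({"source": lo, "target": hi})
        .drop_duplicates()
        .reset_index(drop=True)
    )
    frame.attrs["directed"] = False
    truth = SimTruth(
        connectors=connector_ids,
        params={
            "n_nodes": n_nodes,
            "p_edge": p_edge,
            "module": sorted(module),
            "connectors": connectors,
            "k_connector": k_connector,
            "planted_clique": planted_clique,
            "seed": seed,
        },
    )
    return frame, truth
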