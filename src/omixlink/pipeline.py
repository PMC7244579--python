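"""End-to-end pipeline: stage orchestration, output bundle, run manifest.

Runs the stages in order (simulate, rrho, link-ocr, modules, overlap,
network), writes each stage's outputs as delimited text under an output
directory, and finishes with a JSON manifest recording the seed, thresholds,
and per-stage counts. Given identical config and seed the manifest is
byte-identical between runs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from omixlink import chromatin, coexpression, integration, io, network, rrho
from omixlink import simulate as sim
from omixlink.io import RunConfig

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "rrho", "link-ocr", "modules", "overlap", "network")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the underlying cause."""


class ConfigurationError(ValueError):
    pass


def _write_matrix_tsv(mat: np.ndarray, rows: np.ndarray, cols: np.ndarray,
                      path: Path) -> None:
    frame = pd.DataFrame(mat, index=rows, columns=cols)
    frame.to_csv(path, sep="\t", float_format="%.6g")


def run_pipeline(
    config: RunConfig,
    out_dir: str | Path,
    stages: tuple[str, ...] | list[str] | None = None,
    inputs: dict[str, str] | None = None,
    make_plots: bool = False,
) -> dict:
    """Run the requested stages and write the result bundle under ``out_dir``.

    With ``inputs=None`` the pipeline runs in synthetic mode: the generators
    produce every dataset from ``config.seed``. With a dict of input paths
    (keys: ``mrna_table``, ``prot_table``, ``peaks``, ``annotation``,
    ``mrna_matrix``/``mrna_meta``, ``prot_matrix``/``prot_meta``, ``edges``)
    only the stages whose inputs are present can run; a stage with missing
    inputs raises :class:`ConfigurationError`.

    Returns the manifest dict (also written to ``manifest.json``).
    """
    stages = tuple(stages) if stages else ALL_STAGES
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ConfigurationError(f"unknown stages: {sorted(unknown)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    synthetic = inputs is None

    manifest: dict = {
        "config": config.to_dict(),
        "seed": config.seed,
        "synthetic": synthetic,
        "stages": {},
    }
    state: dict = {}

    # data always materialises in memory first (generated or loaded); the
    # simulate stage's on-disk bundle is written only when requested
    try:
        if synthetic:
            _stage_simulate(config, out, state, manifest,
                            write="simulate" in stages)
        else:
            _load_inputs(inputs, state)
    except Exception as exc:
        raise PipelineError(f"stage 'simulate' failed: {exc}") from exc

    for stage in ALL_STAGES[1:]:
        if stage not in stages:
            continue
        try:
            if stage == "rrho":
                _stage_rrho(config, out, state, manifest, make_plots)
            elif stage == "link-ocr":
                _stage_linkage(config, out, state, manifest)
            elif stage == "modules":
                _stage_modules(config, out, state, manifest)
            elif stage == "overlap":
                _stage_overlap(config, out, state, manifest)
            elif stage == "network":
                _stage_network(config, out, state, manifest)
        except ConfigurationError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


def _require(state: dict, keys: list[str], stage: str) -> None:
    missing = [k for k in keys if k not in state]
    if missing:
        raise ConfigurationError(f"stage {stage!r} needs inputs {missing}")


def _load_inputs(inputs: dict[str, str], state: dict) -> None:
    if "mrna_table" in inputs:
        state["mrna_table"] = io.read_differential_table(inputs["mrna_table"])
    if "prot_table" in inputs:
        state["prot_table"] = io.read_differential_table(inputs["prot_table"])
    if "peaks" in inputs:
        state["peaks"] = io.read_bed_peaks(inputs["peaks"])
    if "annotation" in inputs:
        state["annotation"] = io.read_gene_annotation(inputs["annotation"])
    if "mrna_matrix" in inputs:
        vals, meta = io.read_expression_matrix(
            inputs["mrna_matrix"], inputs["mrna_meta"]
        )
        state["mrna_values"], state["mrna_meta"] = vals, meta
    if "prot_matrix" in inputs:
        vals, meta = io.read_expression_matrix(
            inputs["prot_matrix"], inputs["prot_meta"]
        )
        state["prot_values"], state["prot_meta"] = vals, meta
    if "edges" in inputs:
        state["edges"] = io.read_edge_list(inputs["edges"])


def _stage_simulate(config: RunConfig, out: Path, state: dict,
                    manifest: dict, write: bool = True) -> None:
    rng = np.random.default_rng(config.seed)
    seeds = rng.integers(0, 2**31 - 1, size=4)

    mrna, prot, differential, truth = sim.simulate_multiomics(seed=int(seeds[0]))
    state["mrna_values"], state["mrna_meta"] = mrna["values"], mrna["meta"]
    state["prot_values"], state["prot_meta"] = prot["values"], prot["meta"]
    state["mrna_table"] = differential[("mrna", 8.0)]
    state["mrna_table_24"] = differential[("mrna", 24.0)]
    state["prot_table"] = differential[("protein", 8.0)]
    state["prot_table_24"] = differential[("protein", 24.0)]
    state["truth"] = truth

    annotation = sim.simulate_annotation(
        n_genes=len(mrna["values"]), seed=int(seeds[1])
    )
    up = set(
        state["mrna_table"].loc[state["mrna_table"]["status"] == "up", "feature_id"]
    )
    peaks, peak_truth = sim.simulate_peaks(
        annotation, up, window_bp=config.window_bp, seed=int(seeds[2])
    )
    state["annotation"], state["peaks"] = annotation, peaks
    state["peak_truth"] = peak_truth

    edges, net_truth = sim.simulate_background_network(
        planted_clique=7, seed=int(seeds[3])
    )
    state["edges"], state["net_truth"] = edges, net_truth

    if not write:
        return
    data_dir = out / "data"
    data_dir.mkdir(exist_ok=True)
    io.write_expression_matrix(
        mrna["values"], mrna["meta"],
        data_dir / "mrna_matrix.tsv", data_dir / "mrna_meta.tsv",
    )
    io.write_expression_matrix(
        prot["values"], prot["meta"],
        data_dir / "prot_matrix.tsv", data_dir / "prot_meta.tsv",
    )
    for (layer, t), table in differential.items():
        io.write_differential_table(table, data_dir / f"{layer}_{int(t)}h.tsv")
    io.write_bed_peaks(peaks, data_dir / "peaks.bed")
    io.write_gene_annotation(annotation, data_dir / "annotation.bed")
    io.write_edge_list(edges, data_dir / "edges.tsv")
    (data_dir / "net_module.txt").write_text(
        "\n".join(sorted(net_truth.params["module"])) + "\n"
    )
    truth.to_json(data_dir / "truth.json")
    manifest["stages"]["simulate"] = {
        "n_genes": int(len(mrna["values"])),
        "n_samples": int(len(mrna["meta"])),
        "n_peaks": int(len(peaks)),
        "n_edges": int(len(edges)),
        "n_up_8h": int(len(up)),
    }


def _stage_rrho(config: RunConfig, out: Path, state: dict, manifest: dict,
                make_plots: bool) -> None:
    _require(state, ["mrna_table"], "rrho")
    second = state.get("mrna_table_24", state.get("prot_table"))
    if second is None:
        raise ConfigurationError("rrho needs a second differential table")
    stage_dir = out / "rrho"
    stage_dir.mkdir(exist_ok=True)
    a = rrho.rank_by_fold_change(state["mrna_table"])
    b = rrho.rank_by_fold_change(second)
    rmap = rrho.rrho_map(a, b, step=config.rrho_step)
    for name, mat in (
        ("k", rmap.k_matrix),
        ("neglog_p", rmap.neglog_p),
        ("neglog_p_adj", rmap.neglog_p_adj),
    ):
        _write_matrix_tsv(mat, rmap.thresholds_a, rmap.thresholds_b,
                          stage_dir / f"{name}.tsv")
    n_top = min(150, rmap.universe_n)
    signature = rrho.shared_top_signature(a, b, n_top=n_top)
    pd.DataFrame({"gene_id": signature}).to_csv(
        stage_dir / "signature.tsv", sep="\t", index=False
    )
    if make_plots:
        _plot_rrho(rmap, stage_dir / "heatmap.png")
    state["rrho_map"] = rmap
    manifest["stages"]["rrho"] = {
        "universe_n": rmap.universe_n,
        "step": rmap.step,
        "max_neglog_p_adj": round(rmap.max_neglog_p_adj, 4),
        "any_significant": rmap.any_significant(),
        "signature_size": len(signature),
    }


def _plot_rrho(rmap: rrho.RRHOMap, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(rmap.neglog_p_adj, origin="lower", aspect="auto",
                   extent=(0, rmap.universe_n, 0, rmap.universe_n))
    fig.colorbar(im, ax=ax, label="-log10 adjusted p")
    ax.set_xlabel("rank threshold, list B")
    ax.set_ylabel("rank threshold, list A")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _stage_linkage(config: RunConfig, out: Path, state: dict,
                   manifest: dict) -> None:
    _require(state, ["peaks", "annotation", "mrna_table"], "link-ocr")
    stage_dir = out / "linkage"
    stage_dir.mkdir(exist_ok=True)
    links = chromatin.link_peaks_to_genes(
        state["peaks"], state["annotation"], window_bp=config.window_bp
    )
    links.counts.to_csv(stage_dir / "link_counts.tsv", sep="\t", index=False)
    links.links.to_csv(stage_dir / "links.tsv", sep="\t", index=False)
    freq = chromatin.status_frequency_by_links(links, state["mrna_table"])
    freq.to_csv(stage_dir / "frequency.tsv", sep="\t", index=False,
                float_format="%.6g")

    up_table = state["mrna_table"][state["mrna_table"]["status"] == "up"]
    stats: dict = {}
    if len(up_table) >= 10:
        trend = chromatin.effect_by_gained_count(
            links, up_table, seed=config.seed
        )
        stats["trend"] = trend
    if "prot_table" in state:
        conc = chromatin.mrna_protein_concordance(
            state["mrna_table"], state["prot_table"]
        )
        stats["concordance"] = conc.to_dict(orient="records")
    with open(stage_dir / "stats.json", "w") as fh:
        json.dump(stats, fh, indent=1, sort_keys=True, default=float)
    state["links"] = links
    manifest["stages"]["link-ocr"] = {
        "n_links": int(len(links.links)),
        "n_genes_with_gained": int(len(links.genes_with_gained())),
        "trend_p": round(stats["trend"]["trend_p"], 6) if "trend" in stats else None,
    }


def _stage_modules(config: RunConfig, out: Path, state: dict,
                   manifest: dict) -> None:
    _require(state, ["mrna_values", "prot_values"], "modules")
    stage_dir = out / "modules"
    stage_dir.mkdir(exist_ok=True)
    counts = {}
    for layer, power in (("mrna", config.soft_power_rna),
                         ("prot", config.soft_power_prot)):
        values, meta = state[f"{layer}_values"], state[f"{layer}_meta"]
        # z-score within each condition x time group so the network reflects
        # co-variation rather than the treatment design itself
        meta = meta.assign(
            group=meta["condition"].astype(str) + "_" + meta["time_h"].astype(str)
        )
        values = coexpression.normalize_within_group(values, meta, "group")
        net = coexpression.build_network(values, soft_power=power)
        detected = coexpression.detect_modules(
            net, min_module_size=config.min_module_size,
            cut_height=config.cut_height,
        )
        n_pre_merge = len(detected.labels)
        merged = coexpression.merge_modules(
            detected, values, dissimilarity_threshold=config.merge_dissimilarity
        )
        quality = coexpression.module_quality(
            values, merged, soft_power=power,
            n_resamples=config.n_resamples, seed=config.seed,
        )
        merged.assignment.rename("module").to_csv(
            stage_dir / f"{layer}_assignment.tsv", sep="\t",
            index_label="feature_id",
        )
        eig = pd.DataFrame(
            {f"module_{m}": v for m, v in merged.eigengenes.items()},
            index=meta["sample"],
        )
        eig.to_csv(stage_dir / f"{layer}_eigengenes.tsv", sep="\t",
                   float_format="%.6g", index_label="sample")
        quality.table.to_csv(stage_dir / f"{layer}_quality.tsv", sep="\t",
                             index=False, float_format="%.6g")
        state[f"{layer}_modules"] = merged
        state[f"{layer}_quality"] = quality
        counts[layer] = {
            "n_modules_detected": n_pre_merge,
            "n_modules_merged": len(merged.labels),
            "min_z_summary": round(float(quality.table["z_summary"].min()), 3)
            if len(quality.table) else None,
        }
    manifest["stages"]["modules"] = counts


def _stage_overlap(config: RunConfig, out: Path, state: dict,
                   manifest: dict) -> None:
    _require(
        state, ["mrna_modules", "prot_modules", "mrna_table", "prot_table"],
        "overlap",
    )
    stage_dir = out / "overlap"
    stage_dir.mkdir(exist_ok=True)
    deg = integration.select_deg(
        state["mrna_table"], fc=config.deg_fc, fdr=config.deg_fdr
    )
    if "mrna_table_24" in state:
        deg |= integration.select_deg(
            state["mrna_table_24"], fc=config.deg_fc, fdr=config.deg_fdr
        )
    dap = integration.select_dap(state["prot_table"], p=config.dap_p)
    if "prot_table_24" in state:
        dap |= integration.select_dap(state["prot_table_24"], p=config.dap_p)
    mrna_mods = integration.restrict_modules(state["mrna_modules"], deg)
    prot_mods = integration.restrict_modules(state["prot_modules"], dap)
    result = integration.module_overlap(
        mrna_mods, prot_mods,
        overlap_fdr=config.overlap_fdr, overlap_min=config.overlap_min,
    )
    result.to_csv(stage_dir / "overlap.tsv", sep="\t", index=False,
                  float_format="%.6g")
    sig = result[result["significant"]]
    sig.to_csv(stage_dir / "significant.tsv", sep="\t", index=False,
               float_format="%.6g")
    state["overlap"] = result
    manifest["stages"]["overlap"] = {
        "n_deg": len(deg),
        "n_dap": len(dap),
        "n_pairs": int(len(result)),
        "n_significant": int(len(sig)),
    }


def _stage_network(config: RunConfig, out: Path, state: dict,
                   manifest: dict) -> None:
    _require(state, ["edges"], "network")
    stage_dir = out / "network"
    stage_dir.mkdir(exist_ok=True)
    edges = state["edges"]
    if "net_truth" in state:
        module = set(state["net_truth"].params["module"])
    elif "overlap" in state and len(state["overlap"]):
        top = state["overlap"].sort_values("p").iloc[0]
        module = set(str(top["shared_ids"]).split(","))
    else:
        raise ConfigurationError("network stage needs a module definition")

    connectors = network.connector_enrichment(
        edges, module,
        min_connections=config.connector_min_ppi,
        fdr_threshold=config.connector_fdr,
    )
    connectors.table.to_csv(stage_dir / "connectors.tsv", sep="\t",
                            index=False, float_format="%.6g")
    sub_edges, annotation = network.build_module_network(
        edges, module, connectors, differential=None
    )
    io.write_edge_list(sub_edges, stage_dir / "subgraph.tsv")
    annotation.to_csv(stage_dir / "node_annotation.tsv", sep="\t", index=False)
    communities = network.detect_communities(
        sub_edges, clique_size=config.clique_size,
        complex_size=config.complex_size,
    )
    with open(stage_dir / "communities.json", "w") as fh:
        json.dump(
            {
                "eq": communities.eq,
                "communities": [sorted(c) for c in communities.communities],
            },
            fh, indent=1, sort_keys=True,
        )
    manifest["stages"]["network"] = {
        "n_candidates": int(len(connectors.table)),
        "n_admitted": int(len(connectors.admitted)),
        "admitted": sorted(connectors.admitted),
        "n_communities": len(communities.communities),
    }
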