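"""Readers/writers for the delimited formats the pipeline exchanges.

All genomic coordinates are kept 0-based half-open (BED convention)
internally; GTF input (1-based closed) is converted on read. Tables travel as
pandas DataFrames with validated columns so every stage can assume its
invariants hold.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

PEAK_LABELS = ("gained", "stable", "lost")
STATUS_LABELS = ("up", "down", "stable", "not_expressed")


@dataclass
class RunConfig:
    """Every tunable of the pipeline, with its default.

    Defaults follow the source study's stated thresholds; ``n_resamples``
    defaults to a desk-scale 100 (1000 at full scale).
    """

    window_bp: int = 40_000
    rrho_step: int | None = None  # None -> ~100x100 grid
    soft_power_rna: int = 10
    soft_power_prot: int = 14
    merge_dissimilarity: float = 0.25
    n_resamples: int = 100
    deg_fc: float = 1.5
    deg_fdr: float = 0.05
    dap_p: float = 0.05
    overlap_fdr: float = 0.05
    overlap_min: int = 10
    connector_fdr: float = 0.01
    connector_min_ppi: int = 5
    connector_min_grn: int = 4
    expressed_rpkm: float = 0.5
    clique_size: int = 6
    complex_size: int = 2
    min_module_size: int = 20
    cut_height: float = 0.99
    seed: int = 0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if f.name in ("seed", "rrho_step"):
                continue
            val = getattr(self, f.name)
            if val is not None and val <= 0:
                raise ValueError(f"config field {f.name} must be positive, got {val}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def validate_differential_table(table: pd.DataFrame) -> pd.DataFrame:
    """Enforce the invariants of a differential feature table."""
    required = ["feature_id", "log2fc", "p_value", "fdr"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"differential table missing column(s): {missing}")
    if table["feature_id"].duplicated().any():
        dups = table.loc[table["feature_id"].duplicated(), "feature_id"].tolist()[:5]
        raise ValueError(f"duplicate feature_id values: {dups}")
    for col in ("log2fc", "p_value", "fdr"):
        vals = pd.to_numeric(table[col], errors="coerce")
        if vals.isna().any():
            bad = table.loc[vals.isna(), "feature_id"].tolist()[:5]
            raise ValueError(f"non-numeric {col} for features {bad}")
        table[col] = vals.astype(float)
    for col in ("p_value", "fdr"):
        if ((table[col] < 0) | (table[col] > 1)).any():
            raise ValueError(f"{col} outside [0, 1]")
    if "status" in table.columns:
        bad = set(table["status"].dropna()) - set(STATUS_LABELS)
        if bad:
            raise ValueError(f"unknown status labels: {sorted(bad)}")
    return table.reset_index(drop=True)


def read_differential_table(path: str | Path) -> pd.DataFrame:
    """Read a per-feature differential table (TSV with named header)."""
    table = pd.read_csv(path, sep="\t")
    return validate_differential_table(table)


def write_differential_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_bed_peaks(path: str | Path, label_column: int = 3) -> pd.DataFrame:
    """Read peak intervals from BED; column ``label_column`` (0-based) holds
    the accessibility label (gained/stable/lost).

    Returns a DataFrame (chrom, start, end, label) in 0-based half-open
    coordinates, plus a stable ``peak_id``.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) <= max(2, label_column):
                raise ValueError(f"{path}:{lineno}: expected >= {label_column + 1} columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or start >= end:
                raise ValueError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})"
                )
            label = fields[label_column]
            if label not in PEAK_LABELS:
                raise ValueError(f"{path}:{lineno}: unknown peak label {label!r}")
            records.append((fields[0], start, end, label))
    if not records:
        logger.warning("no peaks read from %s", path)
        return pd.DataFrame(columns=["peak_id", "chrom", "start", "end", "label"])
    peaks = pd.DataFrame(records, columns=["chrom", "start", "end", "label"])
    peaks.insert(0, "peak_id", [f"peak_{i}" for i in range(len(peaks))])
    return peaks


def write_bed_peaks(peaks: pd.DataFrame, path: str | Path) -> None:
    peaks[["chrom", "start", "end", "label"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    """Read gene annotation as 4-column BED-like TSV or minimal GTF.

    BED-like: gene intervals ``chrom start end gene_id [score] strand`` with
    0-based half-open coordinates; TSS taken strand-aware (start for ``+``,
    end for ``-``). GTF (detected by 9 columns with ``gene`` feature rows):
    1-based closed, converted on read.
    """
    with open(path) as fh:
        first = fh.readline()
    ncol = len(first.rstrip("\n").split("\t"))
    if ncol == 9:
        return _read_gtf_genes(path)
    cols = ["chrom", "start", "end", "gene_id", "score", "strand"]
    ann = pd.read_csv(path, sep="\t", header=None, comment="#")
    if ann.shape[1] < 6:
        raise ValueError("annotation BED needs 6 columns (chrom..strand)")
    ann = ann.iloc[:, :6]
    ann.columns = cols
    return _finalize_annotation(ann)


def _read_gtf_genes(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 9 or f[2] != "gene":
                continue
            attrs = dict(
                kv.strip().split(" ", 1)
                for kv in f[8].rstrip(";").split(";")
                if kv.strip()
            )
            gene_id = attrs.get("gene_id", "").strip('"')
            # GTF is 1-based closed -> 0-based half-open
            rows.append((f[0], int(f[3]) - 1, int(f[4]), gene_id, ".", f[6]))
    ann = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "gene_id", "score", "strand"]
    )
    return _finalize_annotation(ann)


def _finalize_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    if ann["gene_id"].duplicated().any():
        raise ValueError("duplicate gene_id in annotation")
    if not set(ann["strand"]) <= {"+", "-"}:
        raise ValueError("strand must be + or -")
    tss = np.where(ann["strand"] == "+", ann["start"], ann["end"])
    out = pd.DataFrame(
        {
            "gene_id": ann["gene_id"],
            "chrom": ann["chrom"],
            "tss": tss.astype(int),
            "strand": ann["strand"],
        }
    )
    if (out["tss"] < 0).any():
        raise ValueError("negative TSS coordinate")
    return out.reset_index(drop=True)


def write_gene_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    """Write TSS annotation as 6-column BED (1 bp interval at the TSS)."""
    bed = pd.DataFrame(
        {
            "chrom": annotation["chrom"],
            "start": annotation["tss"],
            "end": annotation["tss"] + 1,
            "gene_id": annotation["gene_id"],
            "score": ".",
            "strand": annotation["strand"],
        }
    )
    # point annotation: strand-aware TSS already resolved, so start=TSS for both
    bed.loc[annotation["strand"] == "-", "start"] = annotation["tss"] - 1
    bed.loc[annotation["strand"] == "-", "end"] = annotation["tss"]
    bed.to_csv(path, sep="\t", index=False, header=False)


def read_tss_bed(path: str | Path) -> pd.DataFrame:
    """Read back a TSS point-annotation written by :func:`write_gene_annotation`."""
    ann = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "gene_id", "score", "strand"],
    )
    tss = np.where(ann["strand"] == "+", ann["start"], ann["end"])
    return pd.DataFrame(
        {
            "gene_id": ann["gene_id"],
            "chrom": ann["chrom"],
            "tss": tss.astype(int),
            "strand": ann["strand"],
        }
    )


def read_expression_matrix(
    matrix_path: str | Path, meta_path: str | Path
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a features x samples matrix (TSV, first column = feature id) and
    its per-sample metadata (sample, condition, time_h, replicate)."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t")
    required = {"sample", "condition", "time_h", "replicate"}
    if not required <= set(meta.columns):
        raise ValueError(f"sample metadata needs columns {sorted(required)}")
    if list(values.columns) != list(meta["sample"]):
        raise ValueError("matrix columns do not match metadata sample order")
    if not np.all(np.isfinite(values.to_numpy())):
        raise ValueError("expression matrix contains non-finite values")
    bad = set(meta["condition"]) - {"control", "treated"}
    if bad:
        raise ValueError(f"unknown conditions: {sorted(bad)}")
    return values, meta


def write_expression_matrix(
    values: pd.DataFrame,
    meta: pd.DataFrame,
    matrix_path: str | Path,
    meta_path: str | Path,
) -> None:
    values.to_csv(matrix_path, sep="\t", float_format="%.10g")
    meta.to_csv(meta_path, sep="\t", index=False)


def read_edge_list(path: str | Path, directed: bool = False) -> pd.DataFrame:
    """Read a two-column TSV edge list; self-loops dropped, duplicates collapsed.

    Undirected edges are canonicalized (source <= target) before deduplication.
    """
    edges = pd.read_csv(path, sep="\t", header=None, names=["source", "target"],
                        dtype=str, comment="#")
    edges = edges[edges["source"] != edges["target"]]
    if not directed:
        lo = np.minimum(edges["source"], edges["target"])
        hi = np.maximum(edges["source"], edges["target"])
        edges = pd.DataFrame({"source": lo, "target": hi})
    edges = edges.drop_duplicates().reset_index(drop=True)
    edges.attrs["directed"] = directed
    return edges


def write_edge_list(edges: pd.DataFrame, path: str | Path) -> None:
    edges[["source", "target"]].to_csv(path, sep="\t", index=False, header=False)
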