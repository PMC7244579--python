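"""Open-chromatin-to-gene linkage through TSS windows and its statistics.

A peak is linked to a gene when it overlaps, by at least one base, a window of
``window_bp`` centered on the gene's TSS (default 40 kb, i.e. within 20 kb of
the TSS). Downstream statistics summarise how transcript/protein regulation
tracks the number of linked gained open-chromatin regions, and test modules
for enrichment in gained regions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class OCRLinkTable:
    """Per-gene counts of linked peaks by accessibility label."""

    counts: pd.DataFrame  # gene_id, n_gained, n_stable, n_lost
    links: pd.DataFrame  # gene_id, peak_id, label
    window_bp: int

    def genes_with_gained(self) -> set[str]:
        sub = self.counts[self.counts["n_gained"] > 0]
        return set(sub["gene_id"])


def link_peaks_to_genes(
    peaks: pd.DataFrame, annotation: pd.DataFrame, window_bp: int = 40_000
) -> OCRLinkTable:
    """Link every peak to every gene whose TSS window it overlaps.

    Windows are half-open ``[tss - window_bp/2, tss + window_bp/2)``; a peak
    may link to several genes and is counted once per gene. Peaks on
    chromosomes absent from the annotation stay unlinked (with a warning).
    """
    if window_bp <= 0 or window_bp % 2:
        raise ValueError("window_bp must be even and positive")
    half = window_bp // 2

    trees: dict[str, IntervalTree] = {}
    for row in annotation.itertuples():
        lo = max(0, row.tss - half)
        hi = row.tss + half
        trees.setdefault(row.chrom, IntervalTree()).addi(lo, hi, row.gene_id)

    link_rows = []
    missing_chroms = set()
    for row in peaks.itertuples():
        tree = trees.get(row.chrom)
        if tree is None:
            missing_chroms.add(row.chrom)
            continue
        for iv in tree.overlap(row.start, row.end):
            link_rows.append((iv.data, row.peak_id, row.label))
    if missing_chroms:
        logger.warning(
            "peak chromosomes absent from annotation (peaks unlinked): %s",
            sorted(missing_chroms),
        )

    links = pd.DataFrame(link_rows, columns=["gene_id", "peak_id", "label"])
    counts = pd.DataFrame({"gene_id": annotation["gene_id"]})
    for label in ("gained", "stable", "lost"):
        per_gene = (
            links[links["label"] == label].groupby("gene_id").size()
            if len(links)
            else pd.Series(dtype=int)
        )
        counts[f"n_{label}"] = (
            counts["gene_id"].map(per_gene).fillna(0).astype(int)
        )
    links = links.sort_values(["gene_id", "peak_id"]).reset_index(drop=True)
    return OCRLinkTable(counts=counts, links=links, window_bp=window_bp)


def _status_from_table(
    genes: pd.Series, table: pd.DataFrame
) -> pd.Series:
    """Status per gene; genes absent from the table are 'not_expressed'."""
    if "status" not in table.columns:
        raise ValueError("differential table lacks a status column")
    status = genes.map(table.set_index("feature_id")["status"])
    return status.fillna("not_expressed")


def status_frequency_by_links(
    links: OCRLinkTable, table: pd.DataFrame, by: str = "count_of_gained"
) -> pd.DataFrame:
    """Proportion of up/down/stable/not_expressed genes per linkage stratum.

    ``by='count_of_gained'`` stratifies genes into 0, 1, 2, >=3 linked gained
    peaks; ``by='any_gained'`` into gained vs stable-only linkage. Proportions
    in each stratum sum to 1; empty strata yield NaN rows with a warning.
    """
    counts = links.counts
    status = _status_from_table(counts["gene_id"], table)

    if by == "count_of_gained":
        strata = np.minimum(counts["n_gained"], 3)
        labels = {0: "0", 1: "1", 2: "2", 3: ">=3"}
        stratum = strata.map(labels)
        order = ["0", "1", "2", ">=3"]
    elif by == "any_gained":
        has_gained = counts["n_gained"] > 0
        has_stable_only = (counts["n_stable"] > 0) & ~has_gained
        stratum = pd.Series(
            np.where(has_gained, "gained", np.where(has_stable_only, "stable_only", "unlinked")),
            index=counts.index,
        )
        order = ["gained", "stable_only", "unlinked"]
    else:
        raise ValueError(f"unknown stratification {by!r}")

    rows = []
    for name in order:
        mask = stratum == name
        n = int(mask.sum())
        if n == 0:
            warnings.warn(f"empty linkage stratum {name!r}", stacklevel=2)
            rows.append([name, 0] + [np.nan] * 4)
            continue
        sub = status[mask]
        rows.append(
            [name, n]
            + [float((sub == s).mean()) for s in ("up", "down", "stable", "not_expressed")]
        )
    return pd.DataFrame(
        rows, columns=["stratum", "n", "up", "down", "stable", "not_expressed"]
    )


def effect_by_gained_count(
    links: OCRLinkTable,
    table: pd.DataFrame,
    max_count: int = 3,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> dict:
    """Effect-size distribution by number of linked gained peaks + trend test.

    Genes are stratified into 0..max_count-or-more linked gained peaks. The
    monotone-trend p-value is one-sided (increasing effect with more gained
    peaks) and computed by permutation of stratum labels, using the Pearson
    covariance between stratum index and log2FC as the statistic.
    """
    merged = links.counts.merge(
        table[["feature_id", "log2fc"]],
        left_on="gene_id",
        right_on="feature_id",
        how="inner",
    )
    strata_idx = np.minimum(merged["n_gained"].to_numpy(), max_count)
    effects = merged["log2fc"].to_numpy(dtype=float)

    summaries = []
    for s in range(max_count + 1):
        vals = effects[strata_idx == s]
        name = str(s) if s < max_count else f">={max_count}"
        summaries.append(
            {
                "stratum": name,
                "n": int(vals.size),
                "mean": float(np.mean(vals)) if vals.size else np.nan,
                "median": float(np.median(vals)) if vals.size else np.nan,
            }
        )
    non_empty = sum(1 for s in summaries if s["n"] > 0)
    if non_empty < 2:
        raise ValueError("trend test needs >= 2 non-empty strata")

    rng = np.random.default_rng(seed)
    x = strata_idx.astype(float)
    observed = float(np.cov(x, effects, bias=True)[0, 1])
    perm = np.empty(n_permutations)
    y = effects.copy()
    for i in range(n_permutations):
        rng.shuffle(y)
        perm[i] = np.cov(x, y, bias=True)[0, 1]
    p = float((1 + np.sum(perm >= observed)) / (1 + n_permutations))
    return {"summaries": summaries, "trend_statistic": observed, "trend_p": p}


def gained_enrichment_chi2(
    links: OCRLinkTable, module_genes: set[str], universe: set[str]
) -> tuple[float, float, np.ndarray]:
    """One-sided chi-square test for gained-OCR enrichment in a module.

    Builds the 2x2 table (in/out of module) x (has/has-no linked gained peak)
    over ``universe`` and halves the two-sided chi-square p-value when the
    module is enriched; a depleted module gets ``1 - p/2``. No continuity
    correction.
    """
    if not module_genes <= universe:
        raise ValueError("module genes must be a subset of the universe")
    with_gained = links.genes_with_gained() & universe
    in_mod = module_genes
    out_mod = universe - module_genes
    a = len(in_mod & with_gained)
    b = len(in_mod - with_gained)
    c = len(out_mod & with_gained)
    d = len(out_mod - with_gained)
    table = np.array([[a, b], [c, d]], dtype=int)
    if any(m == 0 for m in (a + b, c + d, a + c, b + d)):
        raise ValueError("zero margin in 2x2 table; use an exact Fisher test")
    chi2, p_two, _, _ = stats.chi2_contingency(table, correction=False)
    frac_in = a / (a + b)
    frac_out = c / (c + d)
    if frac_in > frac_out:
        p_one = p_two / 2.0
    elif frac_in < frac_out:
        p_one = 1.0 - p_two / 2.0
    else:
        p_one = 0.5
    return float(chi2), float(p_one), table


def mrna_protein_concordance(
    mrna: pd.DataFrame,
    protein: pd.DataFrame,
    mrna_fc: float = 0.58,
    mrna_fdr: float = 0.05,
    prot_fc: float = 0.58,
    prot_fdr: float = 0.15,
) -> pd.DataFrame:
    """Concordance of protein vs mRNA log2FC by regulation category.

    Features are categorised per layer (up: log2FC > fc and FDR < fdr; down:
    log2FC < -fc and FDR < fdr; equal otherwise; strict inequalities) and the
    Pearson r^2 of protein against mRNA log2FC is computed within the mRNA-up
    and mRNA-down categories. Categories with fewer than 3 pairs report NaN.
    """
    merged = mrna.merge(
        protein, on="feature_id", suffixes=("_mrna", "_prot"), how="inner"
    )

    def categorize(fc_col: str, fdr_col: str, fc_thr: float, fdr_thr: float) -> pd.Series:
        fc = merged[fc_col]
        fdr = merged[fdr_col]
        return pd.Series(
            np.where(
                (fc > fc_thr) & (fdr < fdr_thr),
                "up",
                np.where((fc < -fc_thr) & (fdr < fdr_thr), "down", "equal"),
            ),
            index=merged.index,
        )

    merged["cat_mrna"] = categorize("log2fc_mrna", "fdr_mrna", mrna_fc, mrna_fdr)
    merged["cat_prot"] = categorize("log2fc_prot", "fdr_prot", prot_fc, prot_fdr)

    rows = []
    for cat in ("up", "down", "equal"):
        sub = merged[merged["cat_mrna"] == cat]
        n = len(sub)
        if n >= 3 and sub["log2fc_mrna"].std() > 0 and sub["log2fc_prot"].std() > 0:
            r = float(np.corrcoef(sub["log2fc_mrna"], sub["log2fc_prot"])[0, 1])
            r2 = r * r
        else:
            r2 = np.nan
        n_prot_up = int((sub["cat_prot"] == "up").sum())
        n_prot_down = int((sub["cat_prot"] == "down").sum())
        rows.append(
            {
                "mrna_category": cat,
                "n": n,
                "r2": r2,
                "n_protein_up": n_prot_up,
                "n_protein_down": n_prot_down,
            }
        )
    return pd.DataFrame(rows)
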