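#!/usr/bin/env python
"""Step 3 — link open-chromatin peaks to genes and relate chromatin to output.

Each peak is linked to every gene whose 40 kb TSS window it overlaps by at
least one base. We then ask three questions: (a) does the fraction of
upregulated genes grow with the number of linked gained peaks, (b) are gained
peaks enriched near upregulated genes (one-sided chi-square), and (c) how well
does protein fold change track mRNA fold change by regulation category.
"""

import argparse
import json
from pathlib import Path

from omixlink import chromatin, io


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, default=Path("results/run"))
    parser.add_argument("--seed", type=int, default=1,
                        help="seed of the permutation trend test")
    args = parser.parse_args()

    data = args.out / "data"
    peaks = io.read_bed_peaks(data / "peaks.bed")
    annotation = io.read_gene_annotation(data / "annotation.bed")
    mrna = io.read_differential_table(data / "mrna_8h.tsv")
    prot = io.read_differential_table(data / "protein_8h.tsv")

    links = chromatin.link_peaks_to_genes(peaks, annotation, window_bp=40_000)
    stage = args.out / "linkage"
    stage.mkdir(parents=True, exist_ok=True)
    links.counts.to_csv(stage / "link_counts.tsv", sep="\t", index=False)
    links.links.to_csv(stage / "links.tsv", sep="\t", index=False)

    freq = chromatin.status_frequency_by_links(links, mrna)
    freq.to_csv(stage / "frequency.tsv", sep="\t", index=False,
                float_format="%.6g")
    print(f"{len(links.links)} peak-gene links; "
          f"{len(links.genes_with_gained())} genes with >= 1 gained peak")
    print(freq.to_string(index=False))

    up = set(mrna.loc[mrna["status"] == "up", "feature_id"])
    universe = set(mrna["feature_id"])
    chi2, p_one, table = chromatin.gained_enrichment_chi2(links, up, universe)
    print(f"gained-OCR enrichment in upregulated genes: chi2 = {chi2:.2f}, "
          f"one-sided p = {p_one:.3g}, table = {table.tolist()}")

    trend = chromatin.effect_by_gained_count(links, mrna[mrna["status"] == "up"],
                                             seed=args.seed)
    print(f"dose trend (log2FC vs gained-peak count) permutation p = "
          f"{trend['trend_p']:.3g}")

    conc = chromatin.mrna_protein_concordance(mrna, prot)
    conc.to_csv(stage / "concordance.tsv", sep="\t", index=False,
                float_format="%.6g")
    print(conc.to_string(index=False))

    with open(stage / "stats.json", "w") as fh:
        json.dump({"chi2": chi2, "chi2_one_sided_p": p_one,
                   "trend_p": trend["trend_p"]},
                  fh, indent=1, sort_keys=True, default=float)


if __name__ == "__main__":
    main()
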