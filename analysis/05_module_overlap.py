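#!/usr/bin/env python
"""Step 5 — cross-layer overlap of transcript and protein modules.

Module memberships from step 4 are restricted to differentially expressed
genes (linear |FC| > 1.5 at FDR < 0.05, either time point) and differentially
abundant proteins (p < 0.05), then every mRNA-module x protein-module pair is
scored with a hypergeometric upper tail over the union of members,
BH-corrected. A pair counts as significant at FDR < 0.05 with at least 10
shared members.
"""

import argparse
from pathlib import Path

import pandas as pd

from omixlink import coexpression, integration, io


def _load_modules(path: Path) -> coexpression.ModuleSet:
    assign = pd.read_csv(path, sep="\t", index_col="feature_id")["module"]
    return coexpression.ModuleSet(assignment=assign)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, default=Path("results/run"))
    args = parser.parse_args()

    data = args.out / "data"
    deg = integration.select_deg(io.read_differential_table(data / "mrna_8h.tsv"))
    deg |= integration.select_deg(io.read_differential_table(data / "mrna_24h.tsv"))
    dap = integration.select_dap(io.read_differential_table(data / "protein_8h.tsv"))
    dap |= integration.select_dap(io.read_differential_table(data / "protein_24h.tsv"))
    print(f"{len(deg)} DEG, {len(dap)} DAP")

    modules_dir = args.out / "modules"
    mrna = integration.restrict_modules(
        _load_modules(modules_dir / "mrna_assignment.tsv"), deg)
    prot = integration.restrict_modules(
        _load_modules(modules_dir / "prot_assignment.tsv"), dap)

    result = integration.module_overlap(mrna, prot)
    stage = args.out / "overlap"
    stage.mkdir(parents=True, exist_ok=True)
    result.to_csv(stage / "overlap.tsv", sep="\t", index=False,
                  float_format="%.6g")
    sig = result[result["significant"]]
    sig.to_csv(stage / "significant.tsv", sep="\t", index=False,
               float_format="%.6g")
    cols = ["mrna_module", "prot_module", "k_common", "p", "fdr", "significant"]
    print(result[cols].to_string(index=False))
    print(f"{len(sig)} of {len(result)} pairs significant")


if __name__ == "__main__":
    main()
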