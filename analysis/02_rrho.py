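#!/usr/bin/env python
"""Step 2 — rank-rank hypergeometric overlap between the two time points.

Ranks the 8 h and 24 h mRNA differential tables by fold change and scans all
rank-threshold pairs for overlap enrichment (hypergeometric upper tail,
Benjamini-Yekutieli corrected across the whole grid). A hot diagonal means the
response is concordant and persistent across time. Also extracts the shared
top signature: genes jointly high in both rankings.
"""

import argparse
from pathlib import Path

import pandas as pd

from omixlink import io, rrho


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, default=Path("results/run"))
    parser.add_argument("--n-top", type=int, default=150)
    args = parser.parse_args()

    data = args.out / "data"
    a = rrho.rank_by_fold_change(io.read_differential_table(data / "mrna_8h.tsv"))
    b = rrho.rank_by_fold_change(io.read_differential_table(data / "mrna_24h.tsv"))
    rmap = rrho.rrho_map(a, b)

    stage = args.out / "rrho"
    stage.mkdir(parents=True, exist_ok=True)
    for name, mat in (("k", rmap.k_matrix), ("neglog_p", rmap.neglog_p),
                      ("neglog_p_adj", rmap.neglog_p_adj)):
        pd.DataFrame(mat, index=rmap.thresholds_a,
                     columns=rmap.thresholds_b).to_csv(
            stage / f"{name}.tsv", sep="\t", float_format="%.6g")
    signature = rrho.shared_top_signature(a, b, n_top=min(args.n_top,
                                                          rmap.universe_n))
    pd.DataFrame({"gene_id": signature}).to_csv(stage / "signature.tsv",
                                                sep="\t", index=False)

    print(f"universe {rmap.universe_n} genes, grid step {rmap.step}")
    print(f"max -log10 BY-adjusted p = {rmap.max_neglog_p_adj:.2f} "
          f"(significant: {rmap.any_significant()})")
    print(f"shared top signature: {len(signature)} genes "
          f"-> {stage / 'signature.tsv'}")


if __name__ == "__main__":
    main()
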