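#!/usr/bin/env python
"""Step 4 — weighted co-expression modules on each omics layer.

Expression is z-scored within each condition x time group (so the network
reflects co-variation, not the treatment design), turned into an unsigned
soft-threshold adjacency (power 10 for mRNA, 14 for protein), and clustered on
1 - TOM. Modules are merged while their eigengenes stay closer than 0.25 in
correlation distance, and scored with a resampling quality Z_summary
(bootstrap samples vs size-matched random modules; > 10 reads as high quality).
"""

import argparse
from pathlib import Path

import pandas as pd

from omixlink import coexpression, io


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, default=Path("results/run"))
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-resamples", type=int, default=100)
    args = parser.parse_args()

    data = args.out / "data"
    stage = args.out / "modules"
    stage.mkdir(parents=True, exist_ok=True)

    for layer, power in (("mrna", 10), ("prot", 14)):
        values, meta = io.read_expression_matrix(
            data / f"{layer}_matrix.tsv", data / f"{layer}_meta.tsv")
        meta = meta.assign(
            group=meta["condition"].astype(str) + "_" + meta["time_h"].astype(str)
        )
        values = coexpression.normalize_within_group(values, meta, "group")

        net = coexpression.build_network(values, soft_power=power)
        detected = coexpression.detect_modules(net, min_module_size=20,
                                               cut_height=0.99)
        merged = coexpression.merge_modules(detected, values,
                                            dissimilarity_threshold=0.25)
        quality = coexpression.module_quality(
            values, merged, soft_power=power,
            n_resamples=args.n_resamples, seed=args.seed)

        merged.assignment.rename("module").to_csv(
            stage / f"{layer}_assignment.tsv", sep="\t",
            index_label="feature_id")
        pd.DataFrame(
            {f"module_{m}": v for m, v in merged.eigengenes.items()},
            index=meta["sample"],
        ).to_csv(stage / f"{layer}_eigengenes.tsv", sep="\t",
                 float_format="%.6g", index_label="sample")
        quality.table.to_csv(stage / f"{layer}_quality.tsv", sep="\t",
                             index=False, float_format="%.6g")

        print(f"{layer}: {len(detected.labels)} modules detected, "
              f"{len(merged.labels)} after merging; sizes {merged.sizes()}")
        print(quality.table[["module", "size", "z_density",
                             "z_separability", "z_summary"]]
              .round(2).to_string(index=False))


if __name__ == "__main__":
    main()
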