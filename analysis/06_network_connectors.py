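#!/usr/bin/env python
"""Step 6 — connector nodes and overlapping communities around a module.

Every background-network node is scored for how many of its neighbors fall in
the module of interest (hypergeometric upper tail against the node's degree,
BH-corrected); nodes at FDR < 0.01 with >= 5 module connections are admitted
as connectors. The module-plus-connectors subgraph is then decomposed into
overlapping communities by maximal-clique agglomeration cut at maximal
extended modularity.
"""

import argparse
import json
from pathlib import Path

from omixlink import io, network


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, default=Path("results/run"))
    args = parser.parse_args()

    data = args.out / "data"
    edges = io.read_edge_list(data / "edges.tsv")
    module = {line.strip()
              for line in (data / "net_module.txt").read_text().splitlines()
              if line.strip()}

    result = network.connector_enrichment(edges, module,
                                          min_connections=5,
                                          fdr_threshold=0.01)
    stage = args.out / "network"
    stage.mkdir(parents=True, exist_ok=True)
    result.table.to_csv(stage / "connectors.tsv", sep="\t", index=False,
                        float_format="%.6g")
    admitted = result.table[result.table["admitted"]]
    print(f"module of {len(module)} nodes in a network of "
          f"{len(set(edges['source']) | set(edges['target']))}")
    print(f"{len(admitted)} connectors admitted:")
    print(admitted[["node", "degree", "k_to_module", "p", "fdr"]]
          .to_string(index=False))

    sub_edges, annotation = network.build_module_network(edges, module, result)
    io.write_edge_list(sub_edges, stage / "subgraph.tsv")
    annotation.to_csv(stage / "node_annotation.tsv", sep="\t", index=False)

    communities = network.detect_communities(sub_edges)
    with open(stage / "communities.json", "w") as fh:
        json.dump({"eq": communities.eq,
                   "communities": [sorted(c) for c in communities.communities]},
                  fh, indent=1, sort_keys=True)
    print(f"{len(communities.communities)} overlapping communities "
          f"(EQ = {communities.eq:.3f})")


if __name__ == "__main__":
    main()
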