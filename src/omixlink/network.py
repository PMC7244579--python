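"""Background-network analyses: connector enrichment and overlapping communities.

A "connector" is a node of the background network (protein-protein interaction
or regulatory) whose neighborhood overlaps a module more than a hypergeometric
null allows. For a candidate v with degree d_v (out-degree in a directed
regulatory network) and k neighbors inside a module of effective size m', the
enrichment p-value is ``P(X >= k)`` with ``X ~ Hypergeom(N - 1, m', d_v)``,
BH-corrected across candidates; admission additionally requires a minimum
connection count (5 for PPI, 4 for regulators by default).

Overlapping communities are found by clique agglomeration in the spirit of
EAGLE: maximal cliques of at least ``clique_size`` seed the communities, the
most-similar pair (|C1 n C2| / min sizes) is merged repeatedly, and the
dendrogram is cut where extended modularity EQ is maximal.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from omixlink.rrho import bh_adjust, hypergeom_tail

logger = logging.getLogger(__name__)

#: clique enumeration guard; the package targets desk-scale module networks
MAX_COMMUNITY_NODES = 2000


def edges_to_graph(edges: pd.DataFrame, directed: bool | None = None) -> nx.Graph:
    """Build a simple (di)graph from a two-column edge DataFrame."""
    if directed is None:
        directed = bool(edges.attrs.get("directed", False))
    g = nx.DiGraph() if directed else nx.Graph()
    g.add_edges_from(edges[["source", "target"]].itertuples(index=False, name=None))
    g.remove_edges_from(nx.selfloop_edges(g))
    return g


def restrict_to_expressed(
    edges: pd.DataFrame,
    expression: pd.DataFrame,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Keep nodes whose mean abundance exceeds ``threshold`` in >= 1 condition.

    ``expression`` has one row per feature (``feature_id``) and one column of
    mean abundance per condition. Nodes missing from the table count as not
    expressed; incident edges of removed nodes are dropped.
    """
    value_cols = [c for c in expression.columns if c != "feature_id"]
    expressed = set(
        expression.loc[
            (expression[value_cols] > threshold).any(axis=1), "feature_id"
        ]
    )
    nodes = set(edges["source"]) | set(edges["target"])
    missing = nodes - set(expression["feature_id"])
    if missing:
        logger.info("%d network nodes absent from expression table (dropped)",
                    len(missing))
    keep = edges["source"].isin(expressed) & edges["target"].isin(expressed)
    out = edges[keep].reset_index(drop=True)
    out.attrs["directed"] = edges.attrs.get("directed", False)
    if out.empty:
        warnings.warn("expression restriction removed every edge", stacklevel=2)
    return out


@dataclass
class ConnectorResult:
    """Per-candidate connector statistics and admission decisions."""

    table: pd.DataFrame  # node, degree, k_to_module, p, fdr, admitted
    module: set[str]
    min_connections: int
    fdr_threshold: float

    @property
    def admitted(self) -> set[str]:
        return set(self.table.loc[self.table["admitted"], "node"])


def connector_enrichment(
    edges: pd.DataFrame,
    module: set[str],
    min_connections: int = 5,
    fdr_threshold: float = 0.01,
    include_module_nodes: bool = False,
) -> ConnectorResult:
    """Nodes with significantly many connections into a module.

    Directed networks use out-edges (regulator -> target). Module members not
    present in the network are ignored (logged); the hypergeometric universe
    excludes the candidate node itself.
    """
    g = edges_to_graph(edges)
    directed = g.is_directed()
    nodes = set(g.nodes)
    module_in_net = module & nodes
    dropped = len(module) - len(module_in_net)
    if dropped:
        logger.info("%d module members absent from network ignored", dropped)
    if len(module) > len(nodes):
        raise ValueError("module larger than the network")
    n_nodes = len(nodes)

    rows = []
    for v in sorted(nodes):
        in_module = v in module_in_net
        if in_module and not include_module_nodes:
            continue
        neighbors = set(g.successors(v)) if directed else set(g.neighbors(v))
        d_v = len(neighbors)
        m_eff = len(module_in_net - {v})
        k = len(neighbors & (module_in_net - {v}))
        if d_v == 0 or m_eff == 0:
            p = 1.0
        else:
            p = hypergeom_tail(k, n_nodes - 1, m_eff, d_v)
        rows.append(
            {"node": v, "in_module": in_module, "degree": d_v,
             "k_to_module": k, "p": p}
        )
    table = pd.DataFrame(
        rows, columns=["node", "in_module", "degree", "k_to_module", "p"]
    )
    if len(table):
        table["fdr"] = bh_adjust(table["p"].to_numpy())
        table["admitted"] = (table["fdr"] < fdr_threshold) & (
            table["k_to_module"] >= min_connections
        )
    else:
        table["fdr"] = []
        table["admitted"] = []
    return ConnectorResult(
        table=table,
        module=module_in_net,
        min_connections=min_connections,
        fdr_threshold=fdr_threshold,
    )


def build_module_network(
    edges: pd.DataFrame,
    module: set[str],
    connectors: ConnectorResult,
    differential: pd.DataFrame | None = None,
    fc_threshold: float = 0.58,
    fdr_threshold: float = 0.15,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Induced subgraph on module members plus admitted connectors.

    Nodes are annotated up/down/equal from a differential table using the
    concordance-plot thresholds (log2FC beyond +-``fc_threshold`` at
    FDR < ``fdr_threshold``); nodes without a table entry are 'equal'.
    Returns (sub-edge-list, node annotation table).
    """
    g = edges_to_graph(edges)
    keep = (module & set(g.nodes)) | connectors.admitted
    sub = g.subgraph(keep)
    sub_edges = pd.DataFrame(sorted(sub.edges), columns=["source", "target"])
    sub_edges.attrs["directed"] = g.is_directed()

    ann_rows = []
    if differential is not None:
        table = differential.set_index("feature_id")
    for node in sorted(keep):
        status = "equal"
        if differential is not None and node in table.index:
            fc = float(table.loc[node, "log2fc"])
            fdr = float(table.loc[node, "fdr"])
            if fc > fc_threshold and fdr < fdr_threshold:
                status = "up"
            elif fc < -fc_threshold and fdr < fdr_threshold:
                status = "down"
        ann_rows.append(
            {
                "node": node,
                "role": "connector" if node in connectors.admitted else "module",
                "status": status,
            }
        )
    return sub_edges, pd.DataFrame(ann_rows)


@dataclass
class CommunitySet:
    communities: list[set[str]]
    clique_size: int
    complex_size: int
    eq: float


def _extended_modularity(
    g: nx.Graph, communities: list[set[str]]
) -> float:
    """Extended modularity EQ for (possibly overlapping) communities."""
    m = g.number_of_edges()
    if m == 0 or not communities:
        return 0.0
    membership: dict[str, int] = {}
    for c in communities:
        for v in c:
            membership[v] = membership.get(v, 0) + 1
    eq = 0.0
    two_m = 2.0 * m
    for c in communities:
        members = sorted(c)
        for i in members:
            ki = g.degree(i)
            oi = membership[i]
            for j in members:
                a_ij = 1.0 if g.has_edge(i, j) else 0.0
                eq += (a_ij - ki * g.degree(j) / two_m) / (oi * membership[j])
    return eq / two_m


def detect_communities(
    edges: pd.DataFrame, clique_size: int = 6, complex_size: int = 2
) -> CommunitySet:
    """Overlapping communities by maximal-clique agglomeration (EAGLE-style).

    Maximal cliques of size >= ``clique_size`` seed the communities; the pair
    with the largest similarity ``|C1 n C2| / min(|C1|, |C2|)`` is merged
    repeatedly and the resulting dendrogram is cut at the level with maximal
    extended modularity. Nodes only in smaller cliques ("subordinate") are
    then attached to the community with which they share most edges (ties
    attach to all tied communities). Communities below ``complex_size`` are
    discarded.
    """
    g = edges_to_graph(edges, directed=False)
    if g.number_of_nodes() > MAX_COMMUNITY_NODES:
        raise ValueError(
            f"graph has {g.number_of_nodes()} nodes; community detection is "
            f"guarded at {MAX_COMMUNITY_NODES}"
        )
    cliques = [set(c) for c in nx.find_cliques(g)]
    seeds = [c for c in cliques if len(c) >= clique_size]
    if not seeds:
        warnings.warn(
            f"no clique of size >= {clique_size}; no communities", stacklevel=2
        )
        return CommunitySet([], clique_size, complex_size, 0.0)

    # agglomerate, tracking EQ at every level of the dendrogram
    current = [set(c) for c in seeds]
    best = (
        _extended_modularity(g, current),
        [set(c) for c in current],
    )
    while len(current) > 1:
        pair = None
        best_sim = -1.0
        for i in range(len(current)):
            for j in range(i + 1, len(current)):
                sim = len(current[i] & current[j]) / min(
                    len(current[i]), len(current[j])
                )
                if sim > best_sim:
                    best_sim = sim
                    pair = (i, j)
        i, j = pair  # type: ignore[misc]
        merged = current[i] | current[j]
        current = [c for k, c in enumerate(current) if k not in (i, j)]
        current.append(merged)
        eq = _extended_modularity(g, current)
        if eq > best[0]:
            best = (eq, [set(c) for c in current])

    eq, communities = best
    covered = set().union(*communities)
    subordinate = sorted(set(g.nodes) - covered)
    for v in subordinate:
        shared = [len(set(g.neighbors(v)) & c) for c in communities]
        top = max(shared)
        if top == 0:
            continue
        for c, s in zip(communities, shared):
            if s == top:
                c.add(v)

    communities = [c for c in communities if len(c) >= complex_size]
    eq = _extended_modularity(g, communities)
    return CommunitySet(
        communities=sorted(communities, key=lambda c: (-len(c), sorted(c))),
        clique_size=clique_size,
        complex_size=complex_size,
        eq=eq,
    )
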