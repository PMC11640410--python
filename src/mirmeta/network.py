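"""Protein-interaction network construction and hub ranking.

Edges come from a STRING-style export (node_a, node_b, confidence score in
[0, 1]); edges below the confidence cutoff are discarded, duplicate and
reversed rows collapse to a single undirected edge (keeping the best score),
and hubs are ranked by degree with a deterministic symbol tie-break.
"""

from __future__ import annotations

from typing import Iterable

import networkx as nx
import pandas as pd


def build_network(
    edges: pd.DataFrame,
    min_score: float = 0.4,
    nodes: Iterable[str] | None = None,
) -> nx.Graph:
    """Undirected PPI graph from an edge list, keeping edges with
    score >= ``min_score``; ``nodes`` adds isolated query genes."""
    if not ((edges["score"] >= 0) & (edges["score"] <= 1)).all():
        raise ValueError("edge scores must lie in [0, 1]")
    g = nx.Graph()
    if nodes is not None:
        g.add_nodes_from(nodes)
    for a, b, score in edges[["node_a", "node_b", "score"]].itertuples(index=False):
        if a == b:
            continue  # self-loops carry no PPI information
        g.add_node(a)
        g.add_node(b)
        if score < min_score:
            continue
        if g.has_edge(a, b):
            g[a][b]["score"] = max(g[a][b]["score"], float(score))
        else:
            g.add_edge(a, b, score=float(score))
    return g


def rank_hubs(net: nx.Graph, top_n: int = 10, by: str = "degree") -> pd.DataFrame:
    """Top ``top_n`` genes by centrality (degree default, betweenness optional).

    Ties break by gene symbol, so the ranking is invariant to input order.
    Returns columns gene, degree, centrality, component.
    """
    if by == "degree":
        cent = dict(net.degree())
    elif by == "betweenness":
        cent = nx.betweenness_centrality(net)
    else:
        raise ValueError(f"unknown centrality '{by}'")
    comp_id = {}
    for i, comp in enumerate(
        sorted(nx.connected_components(net), key=lambda c: (-len(c), min(c)))
    ):
        for node in comp:
            comp_id[node] = i
    degree = dict(net.degree())
    ordered = sorted(net.nodes, key=lambda n: (-cent[n], str(n)))[:top_n]
    return pd.DataFrame(
        {
            "gene": ordered,
            "degree": [degree[n] for n in ordered],
            "centrality": [cent[n] for n in ordered],
            "component": [comp_id[n] for n in ordered],
        }
    )
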