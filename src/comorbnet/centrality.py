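"""Weighted centrality indices on the estimated comorbidity network.

Three node indices, following common practice in weighted psychometric-style
networks: strength (sum of absolute incident weights), closeness (inverse of
the summed shortest-path distance to all reachable nodes) and betweenness
(Brandes shortest-path counting with fractional splitting of tied geodesics,
endpoints excluded).  Paths use the distance transform d_ij = 1 / |w_ij|, so
stronger associations are shorter.  Absolute weights are used throughout:
distances must be positive, and a node whose only associations are negative
still has positive strength.  Closeness is unnormalized and undefined
(reported as missing, printed "-") for isolated nodes; for disconnected
graphs it is computed within each node's component.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .ising import IsingNetwork

__all__ = [
    "edge_distance",
    "to_distance_graph",
    "strength",
    "closeness",
    "betweenness",
    "centrality_table",
]


def edge_distance(w_ij: float) -> float:
    """Distance of an edge with weight w_ij: 1 / |w_ij| (w_ij must be non-zero).

    A zero weight is the absence of an edge, never a zero-length edge.
    """
    if w_ij == 0:
        raise ValueError("zero weight means no edge, not a zero-length edge")
    return 1.0 / abs(w_ij)


def to_distance_graph(net: IsingNetwork) -> nx.Graph:
    """Undirected graph with ``weight`` (signed) and ``distance`` attributes."""
    g = nx.Graph()
    g.add_nodes_from(net.labels)
    ii, jj = np.nonzero(np.triu(net.weights, k=1))
    for a, b in zip(ii, jj):
        w = float(net.weights[a, b])
        g.add_edge(net.labels[a], net.labels[b], weight=w,
                   distance=edge_distance(w))
    return g


def strength(net: IsingNetwork, i: str | int) -> float:
    """Sum of absolute weights of the node's incident edges (0 if isolated)."""
    idx = net.index(i)
    return float(np.abs(net.weights[idx]).sum())


def closeness(net: IsingNetwork, i: str | int,
              _graph: nx.Graph | None = None) -> float | None:
    """1 / (summed shortest-path distance to reachable nodes); None if isolated."""
    idx = net.index(i)
    label = net.labels[idx]
    g = _graph if _graph is not None else to_distance_graph(net)
    if g.degree(label) == 0:
        return None
    lengths = nx.single_source_dijkstra_path_length(g, label, weight="distance")
    total = sum(d for node, d in lengths.items() if node != label)
    return 1.0 / total


def betweenness(net: IsingNetwork, i: str | int,
                _bc: dict | None = None) -> float:
    """Raw (unnormalized) shortest-path betweenness of the node."""
    idx = net.index(i)
    if _bc is None:
        g = to_distance_graph(net)
        _bc = nx.betweenness_centrality(g, normalized=False, weight="distance")
    return float(_bc[net.labels[idx]])


def centrality_table(net: IsingNetwork) -> pd.DataFrame:
    """Per-disease strength/closeness/betweenness table.

    ``betweenness_int`` is the integer-rounded count as conventionally
    printed; ``closeness`` is NaN for isolated nodes.
    """
    g = to_distance_graph(net)
    bc = nx.betweenness_centrality(g, normalized=False, weight="distance")
    rows = []
    for label in net.labels:
        s = strength(net, label)
        c = closeness(net, label, _graph=g)
        b = float(bc[label])
        rows.append((label, s, np.nan if c is None else c, b, int(round(b))))
    return pd.DataFrame(rows, columns=["node", "strength", "closeness",
                                       "betweenness", "betweenness_int"])


def centrality_table_to_tsv(table: pd.DataFrame, path: str | Path) -> None:
    """Write the table with missing closeness rendered as '-'."""
    out = table.copy()
    out["closeness"] = out["closeness"].map(
        lambda v: "-" if pd.isna(v) else f"{v:.6g}")
    out.to_csv(path, sep="\t", index=False)
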