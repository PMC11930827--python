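"""Modularity and fast-greedy community detection on the comorbidity network.

Clustering operates on the positive subgraph of the estimated network
(negative edges describe under-co-occurrence and make the weighted null model
ill-defined, and comorbidity communities are positive groupings by
definition).  Modularity is evaluated exactly as

    Q = 1/(2m) Σ_ij (A_ij - γ k_i k_j / (2m)) δ(c_i, c_j)

with m the total edge weight, k_i the node strength and γ a resolution
parameter (1 by default).  The fast-greedy detector agglomerates from
singletons, always merging the community pair with the largest modularity
gain (ties broken by the lexicographically lowest id pair, for determinism),
records the full merge history, and cuts the dendrogram at the maximum-Q
point — the earliest such point, so zero-gain merges (e.g. absorbing isolated
nodes) are not performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ising import IsingNetwork

__all__ = [
    "WeightedGraph",
    "CommunityPartition",
    "positive_subgraph",
    "modularity",
    "fast_greedy",
]


@dataclass
class WeightedGraph:
    """Symmetric non-negative adjacency for clustering input."""

    labels: list[str]
    adjacency: np.ndarray
    dropped_negative: int = 0    # negative edges removed upstream

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=float)
        if not np.allclose(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if (a < 0).any():
            raise ValueError("adjacency weights must be non-negative")
        self.adjacency = a

    @property
    def p(self) -> int:
        return self.adjacency.shape[0]

    @property
    def total_weight(self) -> float:
        """m = half the adjacency sum."""
        return float(self.adjacency.sum() / 2.0)

    @property
    def strengths(self) -> np.ndarray:
        """k_i = Σ_j A_ij."""
        return self.adjacency.sum(axis=1)


def positive_subgraph(net: IsingNetwork) -> WeightedGraph:
    """Keep only positive edges; the count of dropped negative edges is kept
    on the returned graph for the run log."""
    w = net.weights
    n_neg = int((np.triu(w, k=1) < 0).sum())
    pos = np.where(w > 0, w, 0.0)
    return WeightedGraph(list(net.labels), pos, dropped_negative=n_neg)


def modularity(g: WeightedGraph, labels: np.ndarray | list,
               gamma_res: float = 1.0) -> float:
    """Exact modularity of a partition (labels cover every node)."""
    labels = np.asarray(labels)
    if labels.shape[0] != g.p:
        raise ValueError("labels must cover every node")
    a = g.adjacency
    if (a < 0).any():
        raise ValueError("modularity requires non-negative weights")
    two_m = a.sum()
    if two_m == 0:
        return 0.0
    k = g.strengths
    same = labels[:, None] == labels[None, :]
    q = (a[same].sum() - gamma_res * np.outer(k, k)[same].sum() / two_m) / two_m
    return float(q)


@dataclass
class CommunityPartition:
    """Node labels, modularity, resolution and the greedy merge history."""

    node_labels: list[str]
    membership: np.ndarray            # community id per node, 0..k-1
    q: float
    gamma_res: float
    merges: list[tuple[int, int, float]] = field(default_factory=list)
    dendrogram: str = ""

    @property
    def n_communities(self) -> int:
        return len(np.unique(self.membership))

    def communities(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for lbl, c in zip(self.node_labels, self.membership):
            out.setdefault(int(c), []).append(lbl)
        return out

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# Q={self.q:.10g}\tgamma_res={self.gamma_res:g}\n")
            pd.DataFrame({"node": self.node_labels,
                          "community_id": self.membership}).to_csv(
                fh, sep="\t", index=False)

    def to_graphml(self, path: str | Path, net: IsingNetwork) -> None:
        import networkx as nx
        g = nx.Graph(Q=float(self.q), gamma_res=float(self.gamma_res))
        member = dict(zip(self.node_labels, self.membership))
        for lbl in net.labels:
            g.add_node(lbl, community=int(member[lbl]))
        for _, row in net.edge_list().iterrows():
            g.add_edge(row["code_i"], row["code_j"], weight=float(row["weight"]))
        nx.write_graphml(g, path)


def fast_greedy(g: WeightedGraph, gamma_res: float = 1.0) -> CommunityPartition:
    """Agglomerative greedy modularity maximization (CNM-style).

    Starting from singletons, repeatedly merge the community pair with the
    largest ΔQ = E_ab/m - γ k_a k_b / (2 m²) until one community remains,
    then cut the merge path at its (earliest) maximum modularity.  With no
    edges, every node stays a singleton at Q = 0.
    """
    p = g.p
    m = g.total_weight
    if p == 0:
        return CommunityPartition([], np.array([], dtype=int), 0.0, gamma_res)
    membership = np.arange(p)
    if m == 0:
        return CommunityPartition(list(g.labels), membership, 0.0, gamma_res,
                                  dendrogram="(" + ",".join(g.labels) + ");")
    # community-aggregated between-weights and strengths
    e = g.adjacency.copy()
    np.fill_diagonal(e, 0.0)
    k = g.strengths.copy()
    alive = list(range(p))
    names: dict[int, str] = {i: g.labels[i] for i in range(p)}
    groups: dict[int, list[int]] = {i: [i] for i in range(p)}

    q = modularity(g, membership, gamma_res)
    q_path = [q]
    partitions = [membership.copy()]
    merges: list[tuple[int, int, float]] = []

    while len(alive) > 1:
        best = None
        best_dq = -np.inf
        for ai in range(len(alive)):
            for bi in range(ai + 1, len(alive)):
                a, b = alive[ai], alive[bi]
                dq = e[a, b] / m - gamma_res * k[a] * k[b] / (2.0 * m * m)
                if dq > best_dq + 1e-15 or (best is None):
                    best_dq = dq
                    best = (a, b)
        a, b = best  # a < b by construction of the scan order
        # merge b into a
        e[a, :] += e[b, :]
        e[:, a] += e[:, b]
        e[a, a] = 0.0
        e[b, :] = 0.0
        e[:, b] = 0.0
        k[a] += k[b]
        k[b] = 0.0
        groups[a].extend(groups[b])
        names[a] = f"({names[a]},{names[b]})"
        del groups[b], names[b]
        alive.remove(b)
        q += best_dq
        merges.append((a, b, q))
        part = np.empty(p, dtype=int)
        for cid, members in groups.items():
            part[members] = cid
        q_path.append(q)
        partitions.append(part)

    cut = int(np.argmax(np.round(np.asarray(q_path), 12)))
    final = partitions[cut]
    # renumber communities 0..k-1 in order of first appearance
    order: dict[int, int] = {}
    compact = np.empty(p, dtype=int)
    for idx, c in enumerate(final):
        if c not in order:
            order[c] = len(order)
        compact[idx] = order[c]
    q_final = modularity(g, compact, gamma_res)
    dendro = "(" + _replay_names(g.labels, merges, cut) + ");"
    return CommunityPartition(list(g.labels), compact, q_final, gamma_res,
                              merges=merges, dendrogram=dendro)


def _replay_names(labels, merges, cut) -> str:
    names = {i: lbl for i, lbl in enumerate(labels)}
    for a, b, _ in merges[:cut]:
        names[a] = f"({names[a]},{names[b]})"
        del names[b]
    return ",".join(names[i] for i in sorted(names))
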