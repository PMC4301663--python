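"""The gene correlation graph and its min-hop-min-weight completion.

Genes are nodes; a pair fitted with Pearson correlation r >= delta_r gets an
edge of weight r and derived distance d = 1 - r.  Requiring delta_r >= 0
guarantees all distances lie in [0, 1].  Because dropped pairs leave the
dissimilarity matrix partial, the graph is completed before classical MDS:
for every non-adjacent pair the completed cell is, among all connecting
paths with the minimum number of hops, the minimal product of edge
distances (the "most reliable" connection).  The completion only seeds the
initial embedding guess — the iterative MDS afterwards re-fits to the
original partial matrix — so a sum-of-distances objective is offered as a
config alternative.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "CompletedDistances",
    "DisconnectedGraphError",
    "build_graph",
    "giant_component",
    "mhmw_complete",
    "graph_to_frame",
    "write_graph_tsv",
    "read_graph_tsv",
]


class DisconnectedGraphError(ValueError):
    """Completion requires a connected graph; carries the component list."""

    def __init__(self, components):
        self.components = [sorted(c) for c in components]
        super().__init__(
            f"graph is disconnected ({len(self.components)} components, "
            f"sizes {[len(c) for c in self.components]}); "
            "restrict to the giant component first"
        )


@dataclass
class CompletedDistances:
    """Full symmetric dissimilarity matrix derived from the graph.

    ``dist`` holds path-derived dissimilarities (direct edges keep their own
    1 - r), ``hops`` the hop count of the defining path, and ``direct`` flags
    cells backed by an actual edge.
    """

    dist: pd.DataFrame
    hops: pd.DataFrame
    direct: pd.DataFrame

    @property
    def genes(self) -> list:
        return list(self.dist.index)

    def write_tsv(self, path) -> None:
        self.dist.to_csv(path, sep="\t", index_label="gene_id")

    @staticmethod
    def read_dist_tsv(path) -> pd.DataFrame:
        return pd.read_csv(path, sep="\t", index_col="gene_id")


def build_graph(fits, delta_r: float = 0.0, nodes=None) -> nx.Graph:
    """Threshold pair fits into the weighted gene correlation graph.

    Admits exactly the fits with pearson_r >= delta_r; edge attributes are
    ``weight`` (the correlation) and ``distance`` (1 - r).  ``nodes`` may
    supply the full gene set so genes without any admitted edge still appear
    as isolated nodes.
    """
    if not (0 <= delta_r < 1):
        raise ValueError("delta_r must be in [0, 1)")
    g = nx.Graph(delta_r=delta_r)
    if nodes is not None:
        g.add_nodes_from(nodes)
    for f in fits:
        g.add_node(f.gene_a)
        g.add_node(f.gene_b)
        if f.pearson_r >= delta_r:
            g.add_edge(
                f.gene_a,
                f.gene_b,
                weight=float(f.pearson_r),
                distance=float(1.0 - f.pearson_r),
            )
    return g


def giant_component(g: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest connected component.

    Ties are broken toward the component containing the smallest gene id.
    """
    if g.number_of_nodes() == 0:
        return g.copy()
    comps = sorted(
        nx.connected_components(g), key=lambda c: (-len(c), min(map(str, c)))
    )
    return g.subgraph(comps[0]).copy()


def mhmw_complete(g: nx.Graph, objective: str = "product") -> CompletedDistances:
    """Min-hop-min-weight completion of a connected correlation graph.

    For every node pair, among all paths with the minimum number of hops the
    completed cell holds the minimal product (default) or sum of the edge
    distances 1 - r along such a path.  Direct edges keep their own distance
    (the unique 1-hop path).  Runs one BFS + layered dynamic program per
    source, O(n * m) overall.
    """
    if objective not in ("product", "sum"):
        raise ValueError("objective must be 'product' or 'sum'")
    nodes = sorted(g.nodes, key=str)
    if not nodes:
        raise ValueError("empty graph")
    comps = list(nx.connected_components(g))
    if len(comps) > 1:
        raise DisconnectedGraphError(comps)

    idx = {v: i for i, v in enumerate(nodes)}
    adj = {
        v: [(u, float(d["distance"])) for u, d in g.adj[v].items()]
        for v in nodes
    }
    n = len(nodes)
    dist = np.zeros((n, n))
    hops = np.zeros((n, n), dtype=int)
    unit = 1.0 if objective == "product" else 0.0

    for s in nodes:
        si = idx[s]
        hop = {s: 0}
        best = {s: unit}
        queue = deque([s])
        while queue:
            u = queue.popleft()
            hu, bu = hop[u], best[u]
            for v, d in adj[u]:
                if v not in hop:
                    hop[v] = hu + 1
                    best[v] = np.inf
                    queue.append(v)
                if hop[v] == hu + 1:
                    cand = bu * d if objective == "product" else bu + d
                    if cand < best[v]:
                        best[v] = cand
            # u is final once popped: BFS order processes a full layer
            # before any node of the next one.
            dist[si, idx[u]] = best[u]
            hops[si, idx[u]] = hop[u]

    np.fill_diagonal(dist, 0.0)  # the empty path, not the empty product
    index = pd.Index(nodes, name="gene_id")
    direct = pd.DataFrame(hops == 1, index=index, columns=index)
    return CompletedDistances(
        dist=pd.DataFrame(dist, index=index, columns=index),
        hops=pd.DataFrame(hops, index=index, columns=index),
        direct=direct,
    )


def graph_to_frame(g: nx.Graph) -> pd.DataFrame:
    rows = [
        (a, b, d["weight"], d["distance"])
        for a, b, d in sorted(g.edges(data=True), key=lambda e: (str(e[0]), str(e[1])))
    ]
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "pearson_r", "distance"])


def write_graph_tsv(g: nx.Graph, path) -> None:
    graph_to_frame(g).to_csv(path, sep="\t", index=False)


def read_graph_tsv(path, delta_r: float = 0.0) -> nx.Graph:
    df = pd.read_csv(path, sep="\t")
    g = nx.Graph(delta_r=delta_r)
    for r in df.itertuples(index=False):
        g.add_edge(
            r.gene_a, r.gene_b, weight=float(r.pearson_r), distance=float(r.distance)
        )
    return g
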