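"""Nodal graph metrics on group consensus networks.

Four nodal metrics are computed on the group binary and weighted networks:
degree / strength (edge count / summed edge weight), betweenness centrality
(fraction of shortest paths between other node pairs traversing the node,
optionally log transformed because the raw values are heavily skewed),
clustering coefficient, and mean shortest path length.  Shortest paths are
hop counts on the binary consensus topology by default — path length is
defined by the lowest number of edges traversed even on the weighted
network, with an optional 1/weight distance mode for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .connectome import GroupNetwork

__all__ = [
    "NodalMetrics",
    "degree_strength",
    "betweenness",
    "clustering",
    "path_length",
    "nodal_metrics",
]


@dataclass(eq=False)
class NodalMetrics:
    region_ids: np.ndarray
    degree: np.ndarray
    strength: np.ndarray
    betweenness: np.ndarray
    log_betweenness: np.ndarray
    clustering: np.ndarray
    path_length: np.ndarray


def _graph(net: GroupNetwork, use_weights: bool = False) -> nx.Graph:
    A = np.asarray(net.binary)
    if A.shape[0] != A.shape[1] or not np.array_equal(A, A.T):
        raise ValueError("adjacency must be square and symmetric")
    G = nx.from_numpy_array(A)
    if use_weights:
        for i, j in G.edges:
            w = net.weighted[i, j]
            if w <= 0:
                raise ValueError("weighted mode requires positive edge weights")
            G[i][j]["dist"] = 1.0 / w
    return G


def _require_connected(G: nx.Graph) -> None:
    if G.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if not nx.is_connected(G):
        comps = [sorted(c) for c in nx.connected_components(G)]
        raise ValueError(
            f"graph is disconnected ({len(comps)} components; "
            f"smallest: {min(comps, key=len)})"
        )


def degree_strength(net: GroupNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Nodal degree (binary row sums) and strength (weighted row sums)."""
    return (
        np.asarray(net.binary).sum(axis=1),
        np.asarray(net.weighted).sum(axis=1),
    )


def betweenness(
    net: GroupNetwork, log_transform: bool = False, use_weights: bool = False
) -> np.ndarray:
    """Betweenness centrality: for node v, the sum over ordered pairs
    (s, t), s != t != v, of the fraction of shortest s-t paths through v,
    normalized by (N-1)(N-2).  With ``log_transform``, returns
    ln(b + eps) with eps = 1 / ((N-1)(N-2)) so zero-betweenness nodes stay
    finite.
    """
    G = _graph(net, use_weights=use_weights)
    _require_connected(G)
    n = G.number_of_nodes()
    bc = nx.betweenness_centrality(
        G, normalized=True, weight="dist" if use_weights else None
    )
    b = np.array([bc[i] for i in range(n)])
    if log_transform:
        eps = 1.0 / ((n - 1) * (n - 2))
        return np.log(b + eps)
    return b


def clustering(net: GroupNetwork) -> np.ndarray:
    """Clustering coefficient on the binary topology:
    c_v = 2 t_v / (k_v (k_v - 1)), zero for degree < 2."""
    G = _graph(net)
    cc = nx.clustering(G)
    return np.array([cc[i] for i in range(G.number_of_nodes())])


def path_length(net: GroupNetwork, use_weights: bool = False) -> np.ndarray:
    """Per-node mean shortest path length to all other nodes (hop counts by
    default; 1/weight distances with ``use_weights``)."""
    G = _graph(net, use_weights=use_weights)
    _require_connected(G)
    n = G.number_of_nodes()
    out = np.empty(n)
    for v in range(n):
        if use_weights:
            dist = nx.single_source_dijkstra_path_length(G, v, weight="dist")
        else:
            dist = nx.single_source_shortest_path_length(G, v)
        out[v] = sum(dist[u] for u in dist if u != v) / (n - 1)
    return out


def nodal_metrics(
    net: GroupNetwork, log_betweenness: bool = True, use_weights: bool = False
) -> NodalMetrics:
    """All four nodal metrics in one table."""
    deg, stren = degree_strength(net)
    b = betweenness(net, log_transform=False, use_weights=use_weights)
    n = len(deg)
    eps = 1.0 / ((n - 1) * (n - 2))
    return NodalMetrics(
        region_ids=np.asarray(net.region_ids),
        degree=deg,
        strength=stren,
        betweenness=b,
        log_betweenness=np.log(b + eps),
        clustering=clustering(net),
        path_length=path_length(net, use_weights=use_weights),
    )
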