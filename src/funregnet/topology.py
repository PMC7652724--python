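"""Topology metrics for the directed regulatory network.

Conventions (stated because several published variants exist):

* degree: a self-loop contributes 1 to Kin and 1 to Kout, so total degree
  sums to 2E;
* average degree: 2E/N truncated (not rounded) to one decimal;
* clustering coefficients: computed on the undirected simple projection
  with self-loops removed (nodes of projected degree < 2 get 0);
* closeness: harmonic centrality on the directed graph (well defined when
  some node pairs are unreachable);
* betweenness: all-pairs shortest paths on the directed graph;
* eigenvector centrality: on the undirected projection, normalized so the
  largest entry is 1;
* components: weak connectivity (direction ignored).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx

from funregnet.grn_store import RegulatoryNetwork

__all__ = [
    "DegreeProfile",
    "CentralityScores",
    "TopologySummary",
    "to_digraph",
    "degrees",
    "summarize",
    "clustering_coefficients",
    "centralities",
    "weak_components",
    "top_hubs",
    "average_degree",
    "hub_percentage",
]


@dataclass(frozen=True)
class DegreeProfile:
    kin: dict[str, int]
    kout: dict[str, int]

    def k(self, node: str) -> int:
        return self.kin.get(node, 0) + self.kout.get(node, 0)

    def total(self) -> int:
        return sum(self.kin.values()) + sum(self.kout.values())


@dataclass(frozen=True)
class CentralityScores:
    degree: dict[str, float]
    closeness: dict[str, float]
    betweenness: dict[str, float]
    eigenvector: dict[str, float]


@dataclass(frozen=True)
class TopologySummary:
    """The rows of the standard network-properties table."""

    n_nodes: int
    n_interactions: int
    n_auto_regulations: int
    n_positive: int
    n_negative: int
    n_unknown: int
    average_degree: float
    n_components: int
    giant_component_size: int
    max_out_degree: int
    max_out_node: str | None
    max_in_degree: int
    max_in_node: str | None
    average_clustering: float


def to_digraph(network: RegulatoryNetwork) -> nx.DiGraph:
    """networkx view of the network (edge attrs: weight, effect, tfbs_count)."""
    G = nx.DiGraph()
    G.add_nodes_from(network.nodes)
    for e in network.edges:
        G.add_edge(e.tf_id, e.tg_id, weight=e.weight, effect=e.effect,
                   tfbs_count=e.tfbs_count)
    return G


def _undirected_simple(G: nx.DiGraph) -> nx.Graph:
    """Undirected simple projection without self-loops."""
    U = nx.Graph()
    U.add_nodes_from(G.nodes)
    U.add_edges_from((u, v) for u, v in G.edges if u != v)
    return U


def degrees(network: RegulatoryNetwork) -> DegreeProfile:
    """Per-node in/out degree on the directed graph."""
    G = to_digraph(network)
    return DegreeProfile(kin=dict(G.in_degree()), kout=dict(G.out_degree()))


def truncate(x: float, decimals: int) -> float:
    """Truncate toward zero to a number of decimals (7.29 -> 7.2)."""
    f = 10**decimals
    return math.trunc(x * f) / f


def average_degree(n_nodes: int, n_edges: int) -> float:
    """Average total degree 2E/N, truncated to one decimal."""
    if n_nodes == 0:
        return 0.0
    return truncate(2 * n_edges / n_nodes, 1)


def hub_percentage(max_out_degree: int, n_nodes: int) -> int:
    """100 * Kout_max / N truncated to an integer percent."""
    if n_nodes == 0:
        return 0
    return math.trunc(100 * max_out_degree / n_nodes)


def summarize(network: RegulatoryNetwork) -> TopologySummary:
    """Compute the network-properties summary table."""
    G = to_digraph(network)
    n, e = G.number_of_nodes(), G.number_of_edges()
    tally = network.effect_tally()
    if n == 0:
        return TopologySummary(0, 0, 0, 0, 0, 0, 0.0, 0, 0, 0, None, 0, None, 0.0)
    comps = weak_components(network)
    kin, kout = dict(G.in_degree()), dict(G.out_degree())
    max_out_node = max(sorted(kout), key=lambda v: kout[v])
    max_in_node = max(sorted(kin), key=lambda v: kin[v])
    U = _undirected_simple(G)
    return TopologySummary(
        n_nodes=n,
        n_interactions=e,
        n_auto_regulations=network.n_auto_regulations,
        n_positive=tally["positive"],
        n_negative=tally["negative"],
        n_unknown=tally["unknown"],
        average_degree=average_degree(n, e),
        n_components=len(comps),
        giant_component_size=len(comps[0]) if comps else 0,
        max_out_degree=kout[max_out_node],
        max_out_node=max_out_node,
        max_in_degree=kin[max_in_node],
        max_in_node=max_in_node,
        average_clustering=nx.average_clustering(U) if U.number_of_nodes() else 0.0,
    )


def clustering_coefficients(network: RegulatoryNetwork) -> dict[str, float]:
    """Per-node clustering on the undirected simple projection (no self-loops)."""
    U = _undirected_simple(to_digraph(network))
    return nx.clustering(U)


def centralities(network: RegulatoryNetwork, max_iter: int = 1000) -> CentralityScores:
    """Degree, harmonic closeness, betweenness and eigenvector centralities."""
    G = to_digraph(network)
    n = G.number_of_nodes()
    Gs = G.copy()
    Gs.remove_edges_from(nx.selfloop_edges(Gs))
    degree = nx.degree_centrality(Gs) if n > 1 else {v: 0.0 for v in G}
    closeness = nx.harmonic_centrality(Gs)
    if n > 1:  # normalize harmonic closeness to [0, 1]
        closeness = {v: c / (n - 1) for v, c in closeness.items()}
    betweenness = nx.betweenness_centrality(Gs, normalized=False)
    U = _undirected_simple(G)
    if U.number_of_edges() == 0:
        eig = {v: 0.0 for v in G}
    else:
        eig = nx.eigenvector_centrality(U, max_iter=max_iter, tol=1e-10)
        m = max(eig.values())
        eig = {v: x / m for v, x in eig.items()}
    return CentralityScores(degree, closeness, betweenness, eig)


def weak_components(network: RegulatoryNetwork) -> list[set[str]]:
    """Weakly connected components, sorted descending by size."""
    G = to_digraph(network)
    comps = [set(c) for c in nx.weakly_connected_components(G)]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return comps


def top_hubs(network: RegulatoryNetwork, n: int = 10) -> list[tuple[str, int]]:
    """TFs ranked by out-degree, descending; ties broken lexicographically."""
    if n < 1:
        raise ValueError("n must be >= 1")
    G = to_digraph(network)
    kout = [(v, d) for v, d in G.out_degree() if d > 0]
    kout.sort(key=lambda t: (-t[1], t[0]))
    return kout[:n]
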