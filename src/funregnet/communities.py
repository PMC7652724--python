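"""Community detection and per-community term enrichment.

Communities are found with the Louvain two-phase modularity-maximization
algorithm (greedy local moves followed by graph aggregation, repeated until
modularity stops improving).  The directed network is symmetrized first:
edges are projected onto an undirected weighted graph with parallel arcs'
weights summed, since modularity as used here is defined for undirected
graphs.  Community ids are relabelled 0-based, largest community first, so
partitions are deterministic given a seed.

Term enrichment per community uses the one-sided hypergeometric upper-tail
test against the annotated-node universe, with Benjamini-Hochberg adjustment
across all (community, term) tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from funregnet.grn_store import RegulatoryNetwork
from funregnet.topology import to_digraph

__all__ = [
    "Partition",
    "EnrichmentResult",
    "louvain",
    "modularity",
    "community_sizes",
    "enrich_terms",
    "enrichment_matrix",
]


@dataclass(frozen=True)
class Partition:
    """A node -> community assignment (0-based contiguous ids) with its
    modularity Q."""

    assignment: dict[str, int]
    modularity: float

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values())) if self.assignment else 0

    def members(self, community: int) -> set[str]:
        return {v for v, c in self.assignment.items() if c == community}


@dataclass(frozen=True)
class EnrichmentResult:
    community: int
    term: str
    overlap: int
    community_size: int
    term_size: int
    universe_size: int
    p_value: float
    adjusted_p: float


def _symmetrize(network: RegulatoryNetwork) -> nx.Graph:
    """Undirected weighted projection; weights of antiparallel arcs summed,
    self-loops kept (they carry weight into the modularity null model)."""
    G = to_digraph(network)
    U = nx.Graph()
    U.add_nodes_from(G.nodes)
    for u, v, data in G.edges(data=True):
        w = data.get("weight", 1.0)
        if U.has_edge(u, v):
            U[u][v]["weight"] += w
        else:
            U.add_edge(u, v, weight=w)
    return U


def louvain(network: RegulatoryNetwork, seed: int = 0, resolution: float = 1.0) -> Partition:
    """Louvain community detection on the symmetrized network.

    The seed fixes the node-visit order of the local-move phase, making the
    partition reproducible.  Community ids are renumbered 0-based in
    decreasing size order (ties broken by smallest member id).
    """
    if not network.nodes:
        raise ValueError("cannot partition an empty network")
    U = _symmetrize(network)
    comms = nx.community.louvain_communities(
        U, weight="weight", resolution=resolution, seed=seed
    )
    comms = sorted(comms, key=lambda c: (-len(c), min(c)))
    assignment = {v: i for i, c in enumerate(comms) for v in c}
    q = nx.community.modularity(U, comms, weight="weight", resolution=resolution)
    return Partition(assignment, q)


def modularity(network: RegulatoryNetwork, partition: Partition | dict[str, int]) -> float:
    """Newman-Girvan modularity of a partition on the symmetrized network."""
    assignment = partition.assignment if isinstance(partition, Partition) else partition
    U = _symmetrize(network)
    uncovered = set(U.nodes) - assignment.keys()
    if uncovered:
        raise ValueError(f"partition does not cover nodes {sorted(uncovered)[:5]}")
    groups: dict[int, set[str]] = {}
    for v, c in assignment.items():
        if v in U:
            groups.setdefault(c, set()).add(v)
    return nx.community.modularity(U, list(groups.values()), weight="weight")


def community_sizes(partition: Partition) -> list[int]:
    """Community sizes in descending order; sums to the node count."""
    counts: dict[int, int] = {}
    for c in partition.assignment.values():
        counts[c] = counts.get(c, 0) + 1
    return sorted(counts.values(), reverse=True)


def enrich_terms(
    partition: Partition,
    annotations: dict[str, set[str]],
    universe: set[str] | None = None,
) -> list[EnrichmentResult]:
    """Hypergeometric upper-tail enrichment of terms in each community.

    ``annotations`` maps gene -> set of term ids.  The universe defaults to
    the annotated nodes of the partition.  For a community of size n
    containing k genes with a term of total size K in a universe of size N,
    p = P(X >= k) with X ~ Hypergeom(N, K, n).  BH adjustment is applied
    across every (community, term) test.
    """
    if universe is None:
        universe = {v for v in partition.assignment if v in annotations}
    if not universe:
        raise ValueError("empty annotation universe")
    N = len(universe)
    term_members: dict[str, set[str]] = {}
    for gene in universe:
        for term in annotations.get(gene, ()):
            term_members.setdefault(term, set()).add(gene)

    results: list[EnrichmentResult] = []
    raw: list[float] = []
    for comm in sorted(set(partition.assignment.values())):
        members = partition.members(comm) & universe
        n = len(members)
        if n == 0:
            continue
        for term in sorted(term_members):
            K = len(term_members[term])
            k = len(members & term_members[term])
            # P(X >= k); sf(k-1) is the upper tail including k
            p = float(hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
            p = min(p, 1.0)
            results.append(EnrichmentResult(comm, term, k, n, K, N, p, adjusted_p=1.0))
            raw.append(p)
    if not results:
        return []
    _, adj, _, _ = multipletests(raw, method="fdr_bh")
    return [
        EnrichmentResult(
            r.community, r.term, r.overlap, r.community_size, r.term_size,
            r.universe_size, r.p_value, float(a),
        )
        for r, a in zip(results, adj)
    ]


def enrichment_matrix(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Term x community matrix of -log10(adjusted p) (the heatmap data layer)."""
    if not results:
        return pd.DataFrame()
    df = pd.DataFrame(
        {
            "term": [r.term for r in results],
            "community": [r.community for r in results],
            "neglog10_adj_p": [-np.log10(max(r.adjusted_p, 1e-300)) for r in results],
        }
    )
    return df.pivot(index="term", columns="community", values="neglog10_adj_p").fillna(0.0)
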