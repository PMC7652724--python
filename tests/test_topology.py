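"""Topology metrics, checked against independent brute-force oracles.

The betweenness oracle counts shortest paths by explicit breadth-first
enumeration; the clustering oracle counts links among neighbours directly.
Both are run exhaustively over every labelled digraph on up to 4 nodes and
on a seeded random sample of 5- and 6-node digraphs.
"""

import itertools
from collections import deque

import pytest

from conftest import make_edges, make_network
from funregnet.grn_store import build_network
from funregnet.topology import (
    average_degree,
    centralities,
    clustering_coefficients,
    degrees,
    hub_percentage,
    summarize,
    top_hubs,
    weak_components,
)


def all_digraphs(n):
    """Every labelled simple digraph (no self-loops) on nodes 0..n-1."""
    arcs = [(str(a), str(b)) for a in range(n) for b in range(n) if a != b]
    for bits in range(2 ** len(arcs)):
        yield [arcs[i] for i in range(len(arcs)) if bits >> i & 1]


def brute_betweenness(nodes, arcs):
    """Betweenness by BFS shortest-path enumeration (unnormalized)."""
    adj = {v: [] for v in nodes}
    for a, b in arcs:
        adj[a].append(b)
    bc = {v: 0.0 for v in nodes}
    for s in nodes:
        # collect all shortest paths from s by BFS layers
        dist = {s: 0}
        paths = {s: [[s]]}
        queue = deque([s])
        while queue:
            u = queue.popleft()
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    paths[v] = [p + [v] for p in paths[u]]
                    queue.append(v)
                elif dist[v] == dist[u] + 1:
                    paths[v].extend(p + [v] for p in paths[u])
        for t, plist in paths.items():
            if t == s:
                continue
            for v in set(itertools.chain.from_iterable(p[1:-1] for p in plist)):
                frac = sum(1 for p in plist if v in p[1:-1]) / len(plist)
                bc[v] += frac
    return bc


def brute_clustering(nodes, arcs):
    """Clustering on the undirected simple projection by direct counting."""
    und = {frozenset(a) for a in arcs if a[0] != a[1]}
    neigh = {v: set() for v in nodes}
    for e in und:
        a, b = tuple(e)
        neigh[a].add(b)
        neigh[b].add(a)
    out = {}
    for v in nodes:
        k = len(neigh[v])
        if k < 2:
            out[v] = 0.0
            continue
        links = sum(
            1 for a, b in itertools.combinations(neigh[v], 2) if frozenset((a, b)) in und
        )
        out[v] = 2 * links / (k * (k - 1))
    return out


class TestDegrees:
    def test_basic_out_degrees(self):
        d = degrees(make_network([("a", "b"), ("a", "c")]))
        assert d.kout["a"] == 2 and d.kin["b"] == 1 and d.kin["c"] == 1

    def test_self_loop_counts_once_each_way(self):
        d = degrees(make_network([("a", "a")]))
        assert d.kin["a"] == 1 and d.kout["a"] == 1

    def test_total_degree_is_twice_edges(self, rng):
        pairs = {
            (str(rng.integers(50)), str(rng.integers(50))) for _ in range(120)
        }
        net = make_network(sorted(pairs))
        assert degrees(net).total() == 2 * len(net.edges)


class TestSummary:
    def test_average_degree_truncates_not_rounds(self):
        # 2*21184/5862 = 7.2276... and 2*16775/5528 = 6.0692...
        assert average_degree(5862, 21184) == 7.2
        assert average_degree(5528, 16775) == 6.0
        assert average_degree(10, 58) == 11.6  # exact value kept

    def test_hub_percentage_truncates(self):
        assert hub_percentage(2502, 5862) == 42
        assert hub_percentage(1619, 5528) == 29

    def test_empty_network_all_zero(self):
        s = summarize(build_network([]))
        assert s.n_nodes == 0 and s.n_interactions == 0 and s.average_degree == 0.0

    def test_summary_fields_consistent(self):
        net = make_network([("a", "b"), ("a", "c"), ("b", "c"), ("d", "d")])
        s = summarize(net)
        assert s.n_nodes == 4 and s.n_interactions == 4
        assert s.n_auto_regulations == 1
        assert s.max_out_degree == 2 and s.max_out_node == "a"
        assert s.giant_component_size == 3
        assert s.n_components == 2


class TestClustering:
    def test_triangle_all_one(self):
        cc = clustering_coefficients(make_network([("a", "b"), ("b", "c"), ("c", "a")]))
        assert all(v == 1.0 for v in cc.values())

    def test_star_center_zero(self):
        cc = clustering_coefficients(
            make_network([("s", "a"), ("s", "b"), ("s", "c"), ("s", "d")])
        )
        assert cc["s"] == 0.0

    def test_six_node_toy_matches_triangle_formula(self):
        pairs = [("a", "b"), ("b", "c"), ("c", "a"), ("c", "d"), ("d", "e"),
                 ("e", "c"), ("e", "f")]
        net = make_network(pairs)
        got = clustering_coefficients(net)
        want = brute_clustering(net.nodes, pairs)
        assert got == pytest.approx(want)


class TestCentralities:
    def test_directed_path_betweenness(self):
        c = centralities(make_network([("a", "b"), ("b", "c")]))
        assert c.betweenness["b"] == pytest.approx(1.0)
        assert c.betweenness["a"] == c.betweenness["c"] == 0.0

    def test_complete_graph_symmetry(self):
        pairs = [(a, b) for a in "abcd" for b in "abcd" if a != b]
        c = centralities(make_network(pairs))
        for scores in (c.degree, c.closeness, c.betweenness, c.eigenvector):
            assert len(set(round(v, 10) for v in scores.values())) == 1

    def test_eigenvector_normalized_to_unit_max(self):
        c = centralities(make_network([("a", "b"), ("b", "c"), ("c", "a"), ("c", "d")]))
        assert max(c.eigenvector.values()) == pytest.approx(1.0)

    def test_five_node_digraph_matches_brute_force(self):
        pairs = [("a", "b"), ("b", "c"), ("c", "d"), ("a", "c"), ("d", "e"),
                 ("e", "a"), ("b", "e")]
        net = make_network(pairs)
        got = centralities(net).betweenness
        want = brute_betweenness(net.nodes, pairs)
        assert got == pytest.approx(want)


class TestGraphOracles:
    def test_exhaustive_small_digraphs(self):
        """Betweenness and clustering match brute force on every labelled
        digraph with up to 4 nodes (2^12 graphs)."""
        for n in (2, 3, 4):
            for arcs in all_digraphs(n):
                if not arcs:
                    continue
                net = make_network(arcs)
                got_b = centralities(net).betweenness
                want_b = brute_betweenness(net.nodes, arcs)
                assert got_b == pytest.approx(want_b), arcs
                got_c = clustering_coefficients(net)
                want_c = brute_clustering(net.nodes, arcs)
                assert got_c == pytest.approx(want_c), arcs

    def test_random_five_and_six_node_digraphs(self, rng):
        """Seeded random sample of 5- and 6-node digraphs against the same
        oracles."""
        for _ in range(150):
            n = int(rng.integers(5, 7))
            arcs = sorted(
                {
                    (str(a), str(b))
                    for a, b in rng.integers(n, size=(12, 2))
                    if a != b
                }
            )
            if not arcs:
                continue
            net = make_network(arcs)
            assert centralities(net).betweenness == pytest.approx(
                brute_betweenness(net.nodes, arcs)
            )
            assert clustering_coefficients(net) == pytest.approx(
                brute_clustering(net.nodes, arcs)
            )


class TestComponentsAndHubs:
    def test_two_disjoint_edges(self):
        comps = weak_components(make_network([("a", "b"), ("c", "d")]))
        assert sorted(len(c) for c in comps) == [2, 2]

    def test_weakly_connected_single_giant(self):
        comps = weak_components(make_network([("a", "b"), ("c", "b"), ("c", "d")]))
        assert len(comps) == 1 and comps[0] == {"a", "b", "c", "d"}

    def test_component_sizes_partition_nodes(self, rng):
        pairs = sorted({(str(rng.integers(30)), str(rng.integers(30))) for _ in range(40)})
        net = make_network(pairs)
        comps = weak_components(net)
        assert sum(len(c) for c in comps) == len(net.nodes)
        assert set().union(*comps) == net.nodes

    def test_empty_network_no_components(self):
        assert weak_components(build_network([])) == []

    def test_hub_ranking_with_tie_break(self):
        net = make_network(
            [("a", x) for x in "vwxyz"] + [("c", x) for x in "vwxyz"] + [("b", x) for x in "xyz"]
        )
        ranking = top_hubs(net, 10)
        assert [t for t, _ in ranking] == ["a", "c", "b"]

    def test_n_larger_than_tf_count_returns_all(self):
        net = make_network([("a", "b")])
        assert top_hubs(net, 10) == [("a", 1)]
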