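"""Graph set algebra and topology statistics."""

import itertools

import igraph as ig
import networkx as nx
import numpy as np
import pytest

from conftest import make_graph
from gliomanet.graphops import (
    NetworkStats,
    compute_stats,
    difference_network,
    intersect_networks,
    isolated_nodes,
    top_hubs,
    union_networks,
)


def igraph_stats(g: nx.Graph) -> NetworkStats:
    """Independent reference for every stats field, via python-igraph."""
    nodes = sorted(g.nodes())
    index = {n: i for i, n in enumerate(nodes)}
    h = ig.Graph(
        n=len(nodes), edges=[(index[u], index[v]) for u, v in g.edges()]
    )
    if len(nodes) == 0:
        return NetworkStats(0, 0, 0.0, 0, 0, 0)
    local = h.transitivity_local_undirected(mode="zero")
    cc = float(np.mean(local)) if local else 0.0
    components = h.connected_components()
    diameter = 0
    for comp in components:
        if len(comp) > 1:
            diameter = max(diameter, h.subgraph(comp).diameter())
    return NetworkStats(
        n_nodes=h.vcount(),
        n_edges=h.ecount(),
        clustering_coefficient=cc,
        n_components=len(components),
        diameter=diameter,
        n_isolated=sum(1 for d in h.degree() if d == 0),
    )


class TestAlgebraExamples:
    def test_intersection_of_paths(self):
        g1 = make_graph([("A", "B"), ("B", "C")])
        g2 = make_graph([("B", "C"), ("C", "D")])
        out = intersect_networks([g1, g2])
        assert set(out.nodes()) == {"B", "C"}
        assert {frozenset(e) for e in out.edges()} == {frozenset(("B", "C"))}

    def test_intersection_idempotent_and_disjoint(self):
        g = make_graph([("A", "B")])
        same = intersect_networks([g, g])
        assert set(same.nodes()) == {"A", "B"} and same.number_of_edges() == 1
        empty = intersect_networks([g, make_graph([("X", "Y")])])
        assert empty.number_of_nodes() == 0

    def test_intersection_needs_two(self):
        with pytest.raises(ValueError):
            intersect_networks([make_graph([("A", "B")])])

    def test_union_counts(self):
        triangle = make_graph([("A", "B"), ("B", "C"), ("A", "C")])
        edge = make_graph([("D", "E")])
        out = union_networks([triangle, edge])
        assert out.number_of_nodes() == 5 and out.number_of_edges() == 4
        assert union_networks([triangle, triangle]).number_of_edges() == 3

    def test_union_score_conflict_max(self):
        a = make_graph([])
        a.add_edge("A", "B", score=0.91)
        b = make_graph([])
        b.add_edge("A", "B", score=0.95)
        assert union_networks([a, b]).edges["A", "B"]["score"] == pytest.approx(0.95)

    def test_difference_induced_subgraph(self):
        triangle = make_graph([("A", "B"), ("B", "C"), ("A", "C")])
        ref = make_graph([], isolated=["C"])
        out = difference_network(triangle, ref)
        assert set(out.nodes()) == {"A", "B"}
        assert out.number_of_edges() == 1

    def test_difference_identities(self):
        g = make_graph([("A", "B")], label="toy")
        assert difference_network(g, g).number_of_nodes() == 0
        unchanged = difference_network(g, make_graph([]))
        assert set(unchanged.nodes()) == set(g.nodes())
        assert unchanged.graph["label"] == "toy_unique"


class TestStatsClosedForms:
    def test_four_clique(self):
        g = make_graph(itertools.combinations("ABCD", 2))
        s = compute_stats(g)
        assert (s.clustering_coefficient, s.diameter, s.n_components, s.n_isolated) == (
            1.0, 1, 1, 0,
        )

    def test_path_of_four(self):
        s = compute_stats(make_graph([("A", "B"), ("B", "C"), ("C", "D")]))
        assert (s.clustering_coefficient, s.diameter, s.n_components) == (0.0, 3, 1)

    def test_triangle_plus_three_isolated(self):
        g = make_graph([("A", "B"), ("B", "C"), ("A", "C")], isolated=["X", "Y", "Z"])
        s = compute_stats(g)
        assert s.n_components == 4 and s.n_isolated == 3 and s.diameter == 1
        assert s.clustering_coefficient == pytest.approx(0.5)

    def test_star(self):
        g = make_graph([("H", f"L{i}") for i in range(9)])
        s = compute_stats(g)
        assert s.clustering_coefficient == 0.0 and s.diameter == 2

    def test_edgeless(self):
        s = compute_stats(make_graph([], isolated=list("ABC")))
        assert s.diameter == 0 and s.n_components == 3 == s.n_isolated

    def test_exclude_low_degree_flag(self):
        g = make_graph([("A", "B"), ("B", "C"), ("A", "C")], isolated=["X"])
        assert compute_stats(g, count_low_degree=False).clustering_coefficient == 1.0
        assert compute_stats(g).clustering_coefficient == pytest.approx(0.75)


class TestStatsAgainstIgraph:
    @pytest.mark.parametrize("seed", range(10))
    def test_random_graphs_match_reference(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 60))
        p = float(rng.uniform(0, 0.2))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31)))
        g = nx.relabel_nodes(g, {i: f"N{i}" for i in g.nodes()})
        ours = compute_stats(g)
        ref = igraph_stats(g)
        assert ours.n_nodes == ref.n_nodes
        assert ours.n_edges == ref.n_edges
        assert ours.clustering_coefficient == pytest.approx(ref.clustering_coefficient)
        assert ours.n_components == ref.n_components
        assert ours.diameter == ref.diameter
        assert ours.n_isolated == ref.n_isolated


class TestHubsAndIsolated:
    def test_star_center(self):
        g = make_graph([("H", f"L{i}") for i in range(9)])
        assert top_hubs(g, 1).ranked == (("H", 9),)

    def test_tie_broken_lexicographically(self):
        # two degree-2 nodes at the k boundary: the smaller id is included
        g = make_graph([("B", "X"), ("B", "Y"), ("A", "X"), ("A", "Y"), ("C", "X")])
        ranked = top_hubs(g, 3).ranked
        assert ranked[0] == ("X", 3)
        assert [n for n, _ in ranked[1:]] == ["A", "B"]

    def test_k_larger_than_graph(self):
        g = make_graph([("A", "B")])
        assert len(top_hubs(g, 10).ranked) == 2

    def test_ranking_is_stable(self):
        g = make_graph([("A", "B"), ("B", "C"), ("C", "A"), ("D", "A")])
        assert top_hubs(g, 4).ranked == top_hubs(g, 4).ranked

    def test_isolated_nodes(self):
        g = make_graph([("A", "B"), ("B", "C"), ("A", "C")], isolated=["X"])
        assert isolated_nodes(g).ids == {"X"}
        assert not isolated_nodes(make_graph(itertools.combinations("ABC", 2))).ids


def random_labelled_graph(rng, universe=40):
    n = int(rng.integers(2, 25))
    labels = rng.choice(universe, size=n, replace=False)
    g = nx.Graph()
    g.add_nodes_from(f"N{i}" for i in labels)
    nodes = sorted(g.nodes())
    for u, v in itertools.combinations(nodes, 2):
        if rng.random() < 0.15:
            g.add_edge(u, v)
    return g


class TestAlgebraIdentities:
    """Set-algebra laws on random graph triples over a shared label universe."""

    @pytest.mark.parametrize("seed", range(20))
    def test_identities(self, seed):
        rng = np.random.default_rng(seed)
        g1, g2, g3 = (random_labelled_graph(rng) for _ in range(3))
        inter = intersect_networks([g1, g2, g3])
        union = union_networks([g1, g2, g3])
        assert inter.number_of_nodes() <= min(g.number_of_nodes() for g in (g1, g2, g3))
        assert union.number_of_nodes() >= max(g.number_of_nodes() for g in (g1, g2, g3))
        # commutativity / associativity / idempotence on node+edge sets
        def key(g):
            return (set(g.nodes()), {frozenset(e) for e in g.edges()})

        assert key(intersect_networks([g2, g1, g3])) == key(inter)
        assert key(union_networks([g3, g2, g1])) == key(union)
        assert key(intersect_networks([inter, inter])) == key(inter)
        # difference partition: unique nodes and intersection nodes tile g1
        unique = difference_network(g1, inter)
        part_a = set(unique.nodes())
        part_b = set(g1.nodes()) & set(inter.nodes())
        assert part_a | part_b == set(g1.nodes())
        assert not part_a & part_b
        # difference never invents edges
        assert {frozenset(e) for e in unique.edges()} <= {
            frozenset(e) for e in g1.edges()
        }
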