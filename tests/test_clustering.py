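"""Cohesiveness scoring, greedy growth and overlapping cluster detection."""

import itertools

import networkx as nx
import pytest

from conftest import clique, make_graph
from gliomanet.clustering import (
    cluster_membership_of,
    cluster_network,
    cohesiveness,
    density,
    grow_cluster,
    overlap_score,
)


def local_moves(g, members, penalty):
    """Oracle: every single-node addition/removal reachable from ``members``."""
    members = set(members)
    moves = []
    boundary = {v for u in members for v in g.neighbors(u) if v not in members}
    for v in boundary:
        moves.append(members | {v})
    if len(members) > 1:
        for u in members:
            moves.append(members - {u})
    return [(m, cohesiveness(g, m, penalty)) for m in moves]


class TestCohesiveness:
    def test_isolated_triangle_is_perfect(self):
        g = make_graph(itertools.combinations("ABC", 2))
        assert cohesiveness(g, "ABC", penalty=0) == 1.0

    def test_two_of_three_triangle_nodes(self):
        g = make_graph(itertools.combinations("ABC", 2))
        # one internal edge, two boundary edges
        assert cohesiveness(g, "AB", penalty=0) == pytest.approx(1 / 3)

    def test_penalty_term(self):
        g = make_graph(itertools.combinations("ABC", 2))
        assert cohesiveness(g, "ABC", penalty=2) == pytest.approx(3 / (3 + 0 + 6))

    def test_weighted_edges_use_scores(self):
        g = nx.Graph()
        g.add_edge("A", "B", score=0.5)
        g.add_edge("B", "C", score=1.0)
        assert cohesiveness(g, "AB", penalty=0) == pytest.approx(0.5 / (0.5 + 1.0))

    def test_member_outside_graph(self):
        with pytest.raises(ValueError):
            cohesiveness(make_graph([("A", "B")]), {"A", "Z"})

    def test_empty_denominator(self):
        g = make_graph([], isolated=["A"])
        assert cohesiveness(g, {"A"}, penalty=0) == 0.0

    def test_internal_edge_never_decreases_f(self):
        # monotonicity of f in w_in on the same member set
        g = make_graph([("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")])
        before = cohesiveness(g, "ABCD", penalty=2)
        g.add_edge("A", "C")
        assert cohesiveness(g, "ABCD", penalty=2) >= before


class TestGrowCluster:
    def test_five_clique_fully_recovered(self):
        edges, nodes = clique("c", 5)
        g = make_graph(edges)
        grown = grow_cluster(g, nodes[0], penalty=2)
        assert grown.members == frozenset(nodes)
        assert grown.cohesiveness == pytest.approx(10 / 20)
        # exhaustive check: no single move beats the clique
        assert all(f <= grown.cohesiveness for _, f in local_moves(g, nodes, 2))

    def test_greedy_result_is_a_local_optimum(self):
        g = make_graph(
            [("A", "B"), ("B", "C"), ("C", "A"), ("C", "D"), ("D", "E"), ("E", "F")]
        )
        for seed in sorted(g.nodes()):
            grown = grow_cluster(g, seed, penalty=2)
            assert all(
                f <= grown.cohesiveness
                for _, f in local_moves(g, grown.members, 2)
            )

    def test_degree_zero_seed_stays_singleton(self):
        g = make_graph([("A", "B")], isolated=["X"])
        assert grow_cluster(g, "X").members == frozenset(["X"])

    def test_pendant_with_external_pull_not_added(self):
        # X touches the triangle once but leaks twice as much outward
        g = make_graph(
            list(itertools.combinations("ABC", 2)) + [("X", "A"), ("X", "D"), ("X", "E")]
        )
        grown = grow_cluster(g, "A", penalty=2)
        assert grown.members == frozenset("ABC")
        with_pendant = cohesiveness(g, set("ABCX"), penalty=2)
        assert with_pendant < grown.cohesiveness

    def test_absent_seed(self):
        with pytest.raises(ValueError):
            grow_cluster(make_graph([("A", "B")]), "Z")

    def test_deterministic(self):
        g = make_graph(clique("c", 6)[0] + [("c0", "x1"), ("x1", "x2")])
        assert grow_cluster(g, "c0").members == grow_cluster(g, "c0").members


class TestClusterNetwork:
    def test_two_cliques_and_outliers(self):
        e1, n1 = clique("a", 4)
        e2, n2 = clique("b", 4)
        g = make_graph(e1 + e2, isolated=["x", "y"])
        result = cluster_network(g)
        assert sorted(sorted(c.members) for c in result.clusters) == [
            sorted(n1), sorted(n2),
        ]
        assert result.roles["x"] == result.roles["y"] == "outlier"
        assert all(result.roles[n] == "cluster" for n in n1 + n2)

    def test_identical_candidates_merge(self):
        assert overlap_score("abcd", "abcd") == 1.0
        e1, n1 = clique("a", 5)
        g = make_graph(e1)
        result = cluster_network(g)
        assert len(result.clusters) == 1  # every grown duplicate collapses

    def test_shared_node_gets_overlap_role(self):
        e1, n1 = clique("a", 4)
        e2, n2 = clique("b", 4)
        g = make_graph(e1 + e2)
        g = nx.relabel_nodes(g, {"a0": "S", "b0": "S"})
        result = cluster_network(g)
        assert len(result.clusters) == 2
        assert result.roles["S"] == "overlap"
        assert result.roles["a1"] == "cluster"

    def test_filters_applied(self):
        # a path is too sparse: density < 0.5 for any grown candidate of size >= 4
        g = make_graph([("A", "B"), ("B", "C"), ("C", "D"), ("D", "E")])
        result = cluster_network(g, min_size=3, min_density=0.9)
        assert all(
            len(c.members) >= 3 and c.density >= 0.9 for c in result.clusters
        )

    def test_role_partition_is_exhaustive(self):
        e1, _ = clique("a", 5)
        e2, _ = clique("b", 4)
        g = make_graph(e1 + e2 + [("a0", "b0")], isolated=["z"])
        result = cluster_network(g)
        counts = {"cluster": 0, "overlap": 0, "outlier": 0}
        for role in result.roles.values():
            counts[role] += 1
        assert sum(counts.values()) == g.number_of_nodes()
        for node, role in result.roles.items():
            n_in = sum(node in c.members for c in result.clusters)
            assert (n_in == 0) == (role == "outlier")
            assert (n_in == 1) == (role == "cluster")
            assert (n_in >= 2) == (role == "overlap")

    def test_determinism(self):
        e1, _ = clique("a", 5)
        g = make_graph(e1 + [("a0", "p"), ("p", "q")])
        r1 = cluster_network(g)
        r2 = cluster_network(g)
        assert [c.members for c in r1.clusters] == [c.members for c in r2.clusters]
        assert r1.roles == r2.roles


class TestMembership:
    def test_membership_indices(self):
        e1, n1 = clique("a", 5)
        e2, n2 = clique("b", 4)
        g = make_graph(e1 + e2, isolated=["z"])
        g = nx.relabel_nodes(g, {"a0": "S", "b0": "S"})
        result = cluster_network(g)
        members = cluster_membership_of(result, ["S", "a1", "b1", "z"])
        assert members["S"] == [1, 2]  # clusters ranked by size: 5-clique first
        assert members["a1"] == [1]
        assert members["b1"] == [2]
        assert members["z"] == []


class TestPlantedRecoverySmall:
    @pytest.mark.parametrize("k,m", [(2, 4), (3, 5), (2, 8)])
    def test_disjoint_cliques_recovered_exactly(self, k, m):
        edges = []
        planted = []
        for c in range(k):
            e, nodes = clique(f"c{c}_", m)
            edges += e
            planted.append(frozenset(nodes))
        g = make_graph(edges, isolated=[f"iso{i}" for i in range(3)])
        result = cluster_network(g)
        assert sorted(c.members for c in result.clusters) == sorted(planted)
        for i in range(3):
            assert result.roles[f"iso{i}"] == "outlier"
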