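"""Graph set algebra and per-network topology statistics.

Intersection is node-AND-edge (merge semantics of common network tools):
a node or edge survives only if present in every input.  The difference
("unique") network subtracts a reference's *nodes* and keeps the induced
subgraph — the two semantics are deliberately different, matching how
disease-unique subnetworks are derived from a merged intersection.

Statistics conventions:

* mean local clustering includes degree<2 nodes as 0 (the common
  network-analyzer convention; excluding them is available via a flag),
* the diameter of a disconnected graph is the maximum over its components
  (finite pairs only), 0 for an edgeless graph,
* isolated nodes are degree-0 nodes and count as their own components.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import networkx as nx

from .core import GeneSet


@dataclass(frozen=True)
class NetworkStats:
    """The six summary fields of a per-network statistics row."""

    n_nodes: int
    n_edges: int
    clustering_coefficient: float
    n_components: int
    diameter: int
    n_isolated: int

    def __post_init__(self) -> None:
        if not self.n_isolated <= self.n_components <= self.n_nodes:
            raise ValueError(
                "inconsistent stats: need n_isolated <= n_components <= n_nodes"
            )
        if not 0.0 <= self.clustering_coefficient <= 1.0:
            raise ValueError("clustering coefficient outside [0, 1]")

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class HubList:
    """Degree-ranked top nodes of one network."""

    ranked: tuple[tuple[str, int], ...]
    id_space: str = "ensembl_gene"
    label: str = ""

    def ids(self) -> list[str]:
        return [gid for gid, _ in self.ranked]


def _require_multiple(networks: Sequence[nx.Graph], op: str) -> None:
    if len(networks) < 2:
        raise ValueError(f"{op} requires at least 2 networks, got {len(networks)}")


def intersect_networks(networks: Sequence[nx.Graph], label: str = "intersection") -> nx.Graph:
    """Node-and-edge intersection; attributes taken from the first input."""
    _require_multiple(networks, "intersect_networks")
    first = networks[0]
    common_nodes = set(first)
    for g in networks[1:]:
        common_nodes &= set(g)
    out = nx.Graph(label=label, id_space=first.graph.get("id_space", "ensembl_gene"))
    for n in sorted(common_nodes):
        out.add_node(n, **first.nodes[n])
    for u, v in sorted(first.edges(), key=lambda e: tuple(sorted(e))):
        if u in common_nodes and v in common_nodes and all(
            g.has_edge(u, v) for g in networks[1:]
        ):
            out.add_edge(u, v, **first.edges[u, v])
    return out


def union_networks(networks: Sequence[nx.Graph], label: str = "union") -> nx.Graph:
    """Node and edge union; score conflicts resolved by maximum."""
    _require_multiple(networks, "union_networks")
    out = nx.Graph(label=label, id_space=networks[0].graph.get("id_space", "ensembl_gene"))
    for g in networks:
        for n in sorted(g.nodes()):
            if n not in out:
                out.add_node(n, **g.nodes[n])
        for u, v in sorted(g.edges(), key=lambda e: tuple(sorted(e))):
            d = g.edges[u, v]
            if out.has_edge(u, v):
                old = out.edges[u, v].get("score")
                new = d.get("score")
                if new is not None and (old is None or new > old):
                    out.edges[u, v]["score"] = new
            else:
                out.add_edge(u, v, **d)
    return out


def difference_network(g: nx.Graph, reference: nx.Graph) -> nx.Graph:
    """Induced subgraph of ``g`` on nodes absent from ``reference``."""
    keep = set(g) - set(reference)
    out = nx.Graph(
        label=f"{g.graph.get('label', 'network')}_unique",
        id_space=g.graph.get("id_space", "ensembl_gene"),
    )
    for n in sorted(keep):
        out.add_node(n, **g.nodes[n])
    for u, v in sorted(g.edges(), key=lambda e: tuple(sorted(e))):
        if u in keep and v in keep:
            out.add_edge(u, v, **g.edges[u, v])
    return out


def compute_stats(g: nx.Graph, count_low_degree: bool = True) -> NetworkStats:
    """Six-field topology summary of one network.

    ``count_low_degree`` keeps degree<2 nodes (local clustering 0) in the
    clustering-coefficient mean; set False to average over eligible nodes
    only.
    """
    n_nodes = g.number_of_nodes()
    n_edges = g.number_of_edges()
    if n_nodes == 0:
        return NetworkStats(0, 0, 0.0, 0, 0, 0)
    local = nx.clustering(g)
    if count_low_degree:
        cc = sum(local.values()) / n_nodes
    else:
        eligible = [c for n, c in local.items() if g.degree(n) >= 2]
        cc = sum(eligible) / len(eligible) if eligible else 0.0
    components = list(nx.connected_components(g))
    diameter = 0
    for comp in components:
        if len(comp) > 1:
            sub = g.subgraph(comp)
            diameter = max(diameter, nx.diameter(sub))
    n_isolated = sum(1 for n in g if g.degree(n) == 0)
    return NetworkStats(
        n_nodes=n_nodes,
        n_edges=n_edges,
        clustering_coefficient=cc,
        n_components=len(components),
        diameter=diameter,
        n_isolated=n_isolated,
    )


def top_hubs(g: nx.Graph, k: int = 10) -> HubList:
    """The ``k`` highest-degree nodes; ties broken by lexicographic id."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    ranked = sorted(g.degree(), key=lambda item: (-item[1], item[0]))[:k]
    return HubList(
        ranked=tuple((str(n), int(d)) for n, d in ranked),
        id_space=g.graph.get("id_space", "ensembl_gene"),
        label=g.graph.get("label", ""),
    )


def isolated_nodes(g: nx.Graph) -> GeneSet:
    """All degree-0 node identifiers."""
    return GeneSet(
        frozenset(n for n in g if g.degree(n) == 0),
        g.graph.get("id_space", "ensembl_gene"),
    )
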