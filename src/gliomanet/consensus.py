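"""Cross-database and cross-disease consensus reporting.

Networks built from different interaction databases live in different
identifier spaces (official symbols vs Ensembl protein ids), so comparing
their hubs or merging their node sets first requires translation into a
common space — Ensembl gene ids by default, which proved the robust join
key; symbol-space comparison is supported for diagnostics but symbol
spelling drift across resources makes it unreliable as the primary key.
Identifiers that fail to map are always reported, never dropped silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import pandas as pd

from .annotations import IdMap
from .core import GeneSet
from .graphops import (
    HubList,
    compute_stats,
    intersect_networks,
    isolated_nodes,
    top_hubs,
    union_networks,
)

#: Column order of the per-network statistics table.
STATS_COLUMNS = (
    "Network",
    "Nodes",
    "Edges",
    "Clustering Coefficient",
    "Connected Components",
    "Network Diameter",
    "Isolated Nodes",
)


@dataclass
class ConsensusMatch:
    """Hub agreement between two networks after mapping to a common space."""

    matched: GeneSet
    unmapped_a: list[str]
    unmapped_b: list[str]

    @property
    def match_count(self) -> int:
        return len(self.matched)


@dataclass
class MergeReport:
    """Node-level merge of two networks keyed on a common identifier space."""

    intersecting_nodes: int
    union_nodes: int
    unconnected_in_intersection: int
    unmapped_a: list[str] = field(default_factory=list)
    unmapped_b: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.intersecting_nodes > self.union_nodes:
            raise ValueError("intersection larger than union")


def _to_space(
    ids: Sequence[str], space: str, idmap: IdMap | None, target: str
) -> tuple[dict[str, str], list[str]]:
    """Map a list of ids into ``target`` space; identity when already there."""
    if space == target:
        return {i: i for i in ids}, []
    if idmap is None:
        raise ValueError(
            f"no id map given but spaces differ ({space!r} vs {target!r})"
        )
    result = idmap.translate(GeneSet(frozenset(ids), space), target)
    return result.mapping, result.unmapped


def hub_consensus(
    hubs_a: HubList,
    hubs_b: HubList,
    idmap: IdMap | None = None,
    target: str = "ensembl_gene",
) -> ConsensusMatch:
    """Genes present in both hub lists after translation to ``target`` space."""
    if not hubs_a.ranked or not hubs_b.ranked:
        raise ValueError("hub lists must be nonempty")
    map_a, unmapped_a = _to_space(hubs_a.ids(), hubs_a.id_space, idmap, target)
    map_b, unmapped_b = _to_space(hubs_b.ids(), hubs_b.id_space, idmap, target)
    matched = frozenset(map_a.values()) & frozenset(map_b.values())
    return ConsensusMatch(
        matched=GeneSet(matched, target),
        unmapped_a=unmapped_a,
        unmapped_b=unmapped_b,
    )


def common_isolated(networks: Sequence[nx.Graph]) -> GeneSet:
    """Nodes isolated (degree 0) in every compared network.

    All networks must share one identifier space; map them before calling
    when comparing across databases.
    """
    if len(networks) < 2:
        raise ValueError("common_isolated requires at least 2 networks")
    spaces = {g.graph.get("id_space", "ensembl_gene") for g in networks}
    if len(spaces) > 1:
        raise ValueError(f"networks use different id spaces: {sorted(spaces)}")
    common = isolated_nodes(networks[0])
    for g in networks[1:]:
        common = common.intersection(isolated_nodes(g))
    return common


def cross_db_merge(
    g_a: nx.Graph,
    g_b: nx.Graph,
    idmap: IdMap | None = None,
    target: str = "ensembl_gene",
) -> MergeReport:
    """Merge two database-specific networks on a common identifier space.

    ``unconnected_in_intersection`` counts intersecting nodes incident to no
    edge present (after mapping) in both inputs — nodes the two databases
    agree exist but do not agree on any interaction for.
    """
    map_a, unmapped_a = _to_space(
        list(g_a.nodes()), g_a.graph.get("id_space", "ensembl_gene"), idmap, target
    )
    map_b, unmapped_b = _to_space(
        list(g_b.nodes()), g_b.graph.get("id_space", "ensembl_gene"), idmap, target
    )
    if not map_a or not map_b:
        raise ValueError("identifier mapping failed for an entire network")

    nodes_a = frozenset(map_a.values())
    nodes_b = frozenset(map_b.values())
    intersecting = nodes_a & nodes_b
    union = nodes_a | nodes_b

    def mapped_edges(g: nx.Graph, mapping: dict[str, str]) -> set[frozenset[str]]:
        out = set()
        for u, v in g.edges():
            mu, mv = mapping.get(u), mapping.get(v)
            if mu is not None and mv is not None and mu != mv:
                out.add(frozenset((mu, mv)))
        return out

    shared_edges = mapped_edges(g_a, map_a) & mapped_edges(g_b, map_b)
    touched = {n for edge in shared_edges for n in edge}
    unconnected = sum(1 for n in intersecting if n not in touched)

    return MergeReport(
        intersecting_nodes=len(intersecting),
        union_nodes=len(union),
        unconnected_in_intersection=unconnected,
        unmapped_a=unmapped_a,
        unmapped_b=unmapped_b,
    )


def compare_stats_table(
    networks: Sequence[nx.Graph], count_low_degree: bool = True
) -> pd.DataFrame:
    """Per-network statistics plus merged-intersection and merged-union rows."""
    rows = []
    for g in networks:
        stats = compute_stats(g, count_low_degree=count_low_degree)
        rows.append((g.graph.get("label", "network"), stats))
    if len(networks) >= 2:
        rows.append(
            ("merged intersection", compute_stats(intersect_networks(networks)))
        )
        rows.append(("merged union", compute_stats(union_networks(networks))))
    frame = pd.DataFrame(
        [
            {
                "Network": label,
                "Nodes": s.n_nodes,
                "Edges": s.n_edges,
                "Clustering Coefficient": round(s.clustering_coefficient, 4),
                "Connected Components": s.n_components,
                "Network Diameter": s.diameter,
                "Isolated Nodes": s.n_isolated,
            }
            for label, s in rows
        ],
        columns=list(STATS_COLUMNS),
    )
    return frame
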