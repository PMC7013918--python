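"""Cohesiveness-based greedy detection of overlapping protein complexes.

The score maximized during growth is the cohesiveness of a vertex set V,

    f(V) = w_in / (w_in + w_bound + p * |V|),

where ``w_in`` is the total weight of edges inside V, ``w_bound`` the total
weight of edges with exactly one endpoint in V, and ``p`` a per-member
penalty modelling unobserved interactions.  Edge weights are interaction
confidence scores when present and 1 otherwise, so unscored (e.g.
BioGRID-style) networks cluster on plain edge counts.

Growth is a deterministic greedy local search: from a singleton seed, the
single addition of an external neighbor or removal of a current member
that most increases f is applied until no move helps.  Grown candidates
whose pairwise overlap score

    omega(A, B) = |A ∩ B|^2 / (|A| * |B|)

exceeds a threshold are merged (union) to a fixpoint, and candidates that
are too small or too sparse are discarded.  Every node then has exactly one
role: ``cluster`` (member of one accepted cluster), ``overlap`` (member of
several) or ``outlier`` (member of none).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx

from .core import GeneSet

DEFAULT_PENALTY = 2.0
DEFAULT_MIN_SIZE = 3
DEFAULT_MIN_DENSITY = 0.5
DEFAULT_OVERLAP_MAX = 0.8


def _weight(g: nx.Graph, u, v) -> float:
    w = g.edges[u, v].get("score")
    return 1.0 if w is None else float(w)


@dataclass(frozen=True)
class Cluster:
    """An accepted candidate complex with its quality measures."""

    members: frozenset[str]
    cohesiveness: float
    density: float

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("cluster must have at least one member")
        if not 0.0 <= self.cohesiveness <= 1.0:
            raise ValueError("cohesiveness outside [0, 1]")
        if not 0.0 <= self.density <= 1.0:
            raise ValueError("density outside [0, 1]")


@dataclass
class ClusteringResult:
    """Clusters sorted by decreasing size, plus a role for every node."""

    clusters: list[Cluster]
    roles: dict[str, str]


def cohesiveness(g: nx.Graph, members: Iterable[str], penalty: float = DEFAULT_PENALTY) -> float:
    """f(V) = w_in / (w_in + w_bound + p|V|); 0 when the denominator is 0."""
    members = set(members)
    missing = members - set(g)
    if missing:
        raise ValueError(f"members not in graph: {sorted(missing)}")
    w_in = 0.0
    w_bound = 0.0
    for u in members:
        for v in g.neighbors(u):
            if v in members:
                if u < v:  # count internal edges once
                    w_in += _weight(g, u, v)
            else:
                w_bound += _weight(g, u, v)
    denom = w_in + w_bound + penalty * len(members)
    return 0.0 if denom == 0 else w_in / denom


def density(g: nx.Graph, members: Iterable[str]) -> float:
    """Unweighted internal edge density 2m/(n(n-1)); 0 for singletons."""
    members = set(members)
    n = len(members)
    if n < 2:
        return 0.0
    m = sum(1 for u in members for v in g.neighbors(u) if v in members and u < v)
    return 2.0 * m / (n * (n - 1))


def grow_cluster(g: nx.Graph, seed: str, penalty: float = DEFAULT_PENALTY) -> Cluster:
    """Greedy cohesiveness maximization from a singleton seed.

    At each step every external neighbor (addition) and every current
    member (removal, unless it would empty the set) is evaluated; the move
    with the largest strict increase in f is applied, smallest node id
    first on ties.  Deterministic by construction.
    """
    if seed not in g:
        raise ValueError(f"seed {seed!r} not in graph")

    members: set[str] = {seed}
    strength = {n: sum(_weight(g, n, v) for v in g.neighbors(n)) for n in g}

    def inward(node: str) -> float:
        """Weight from ``node`` to current members (excluding itself)."""
        return sum(
            _weight(g, node, v) for v in g.neighbors(node) if v in members and v != node
        )

    w_in = 0.0
    w_bound = strength[seed]

    def f(wi: float, wb: float, size: int) -> float:
        denom = wi + wb + penalty * size
        return 0.0 if denom == 0 else wi / denom

    current = f(w_in, w_bound, 1)
    while True:
        best: tuple[float, int, str] | None = None  # (f, kind, node); kind 0=add 1=remove
        boundary = sorted(
            {v for u in members for v in g.neighbors(u) if v not in members}
        )
        # tie-break: higher f, then additions before removals, then lowest id
        for v in boundary:
            win_v = inward(v)
            cand = f(
                w_in + win_v,
                w_bound + strength[v] - 2 * win_v,
                len(members) + 1,
            )
            if best is None or cand > best[0] or (
                cand == best[0] and (0, v) < (best[1], best[2])
            ):
                best = (cand, 0, v)
        if len(members) > 1:
            for u in sorted(members):
                win_u = inward(u)
                cand = f(
                    w_in - win_u,
                    w_bound + 2 * win_u - strength[u],
                    len(members) - 1,
                )
                if best is None or cand > best[0] or (
                    cand == best[0] and (1, u) < (best[1], best[2])
                ):
                    best = (cand, 1, u)
        if best is None or best[0] <= current:
            break
        current, kind, node = best
        win_node = inward(node)
        if kind == 0:
            members.add(node)
            w_in += win_node
            w_bound += strength[node] - 2 * win_node
        else:
            members.remove(node)
            w_in -= win_node
            w_bound += 2 * win_node - strength[node]

    return Cluster(
        members=frozenset(members),
        cohesiveness=cohesiveness(g, members, penalty),
        density=density(g, members),
    )


def overlap_score(a: Iterable[str], b: Iterable[str]) -> float:
    """omega(A, B) = |A∩B|^2 / (|A||B|)."""
    a, b = set(a), set(b)
    if not a or not b:
        return 0.0
    inter = len(a & b)
    return inter * inter / (len(a) * len(b))


def _merge_overlapping(
    candidates: list[frozenset[str]], overlap_max: float
) -> list[frozenset[str]]:
    """Union-merge candidate pairs with omega > overlap_max, to fixpoint."""
    merged = [set(c) for c in candidates]
    changed = True
    while changed:
        changed = False
        out: list[set[str]] = []
        for cand in merged:
            target = None
            for existing in out:
                if overlap_score(existing, cand) > overlap_max:
                    target = existing
                    break
            if target is not None:
                target |= cand
                changed = True
            else:
                out.append(cand)
        merged = out
    # drop exact duplicates, keep deterministic order
    seen: set[frozenset[str]] = set()
    result = []
    for cand in merged:
        frozen = frozenset(cand)
        if frozen not in seen:
            seen.add(frozen)
            result.append(frozen)
    return result


def cluster_network(
    g: nx.Graph,
    penalty: float = DEFAULT_PENALTY,
    min_size: int = DEFAULT_MIN_SIZE,
    min_density: float = DEFAULT_MIN_DENSITY,
    overlap_max: float = DEFAULT_OVERLAP_MAX,
) -> ClusteringResult:
    """Detect overlapping clusters over the whole network.

    Seeds are processed in decreasing degree order (ties by id); a node
    already covered by a grown candidate is not used as a new seed.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    if not 0.0 <= min_density <= 1.0:
        raise ValueError("min_density outside [0, 1]")
    if not 0.0 <= overlap_max <= 1.0:
        raise ValueError("overlap_max outside [0, 1]")

    order = sorted(g.nodes(), key=lambda n: (-g.degree(n), n))
    covered: set[str] = set()
    candidates: list[frozenset[str]] = []
    for seed in order:
        if seed in covered:
            continue
        grown = grow_cluster(g, seed, penalty)
        candidates.append(grown.members)
        covered |= grown.members

    merged = _merge_overlapping(candidates, overlap_max)

    accepted = []
    for members in merged:
        dens = density(g, members)
        if len(members) >= min_size and dens >= min_density:
            accepted.append(
                Cluster(
                    members=members,
                    cohesiveness=cohesiveness(g, members, penalty),
                    density=dens,
                )
            )
    accepted.sort(key=lambda c: (-len(c.members), min(c.members)))

    counts: dict[str, int] = {n: 0 for n in g}
    for cluster in accepted:
        for n in cluster.members:
            counts[n] += 1
    roles = {
        n: ("outlier" if c == 0 else "cluster" if c == 1 else "overlap")
        for n, c in counts.items()
    }
    return ClusteringResult(clusters=accepted, roles=roles)


def cluster_membership_of(
    result: ClusteringResult, genes: GeneSet | Iterable[str]
) -> dict[str, list[int]]:
    """1-based cluster indices (size-ranked) containing each queried gene."""
    ids = genes.ids if isinstance(genes, GeneSet) else set(genes)
    membership: dict[str, list[int]] = {}
    for gid in sorted(ids):
        membership[gid] = [
            i + 1 for i, cluster in enumerate(result.clusters) if gid in cluster.members
        ]
    return membership


def write_clusters_tsv(result: ClusteringResult, path) -> None:
    """One cluster per line: index, size, cohesiveness, density, members."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("cluster\tsize\tcohesiveness\tdensity\tmembers\n")
        for i, cluster in enumerate(result.clusters, start=1):
            members = "\t".join(sorted(cluster.members))
            fh.write(
                f"{i}\t{len(cluster.members)}\t{cluster.cohesiveness:.4f}\t"
                f"{cluster.density:.4f}\t{members}\n"
            )


def write_roles_tsv(result: ClusteringResult, path) -> None:
    """Node-attribute table: node, role, cluster indices (semicolon-joined)."""
    index_of = cluster_membership_of(result, list(result.roles))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("node\trole\tclusters\n")
        for node in sorted(result.roles):
            idx = ";".join(str(i) for i in index_of[node])
            fh.write(f"{node}\t{result.roles[node]}\t{idx}\n")
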