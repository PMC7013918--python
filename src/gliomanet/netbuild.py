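"""Interaction-table parsing and first-order PPI network construction.

Two table dialects are supported:

* ``biogrid_tab`` — tab-separated with identifier, official-symbol,
  organism (NCBI taxonomy integer) and experimental-system columns; no
  confidence score, so filtering on this dialect is taxonomy-only.
* ``string_links`` — whitespace-separated ``protein1 protein2
  combined_score`` with integer scores on the native 0–1000 scale, rescaled
  here to [0, 1]; the organism is a file-level property (taxon applied to
  both endpoints of every record).

A first-order network keeps only interactions with at least one endpoint in
the seed set (after score and taxonomy predicates), so every edge touches a
seed.  Seeds with no surviving interaction remain in the graph as isolated
nodes — their isolation is a finding, not a parsing accident.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import networkx as nx

from .core import GeneSet

BIOGRID_COLUMNS = (
    "ID Interactor A",
    "ID Interactor B",
    "Official Symbol Interactor A",
    "Official Symbol Interactor B",
    "Organism Interactor A",
    "Organism Interactor B",
    "Experimental System",
)

STRING_COLUMNS = ("protein1", "protein2", "combined_score")

HUMAN_TAXON = 9606

#: A STRING "90% confidence" filter is combined_score >= 900 on the native
#: integer scale, i.e. 0.9 after rescaling.
DEFAULT_MIN_SCORE = 0.9


@dataclass
class InteractionRecord:
    """One physical/functional interaction between two gene products."""

    id_a: str
    id_b: str
    taxon_a: int
    taxon_b: int
    score: float | None = None
    evidence: str | None = None
    symbol_a: str | None = None
    symbol_b: str | None = None

    def __post_init__(self) -> None:
        if not self.id_a or not self.id_b:
            raise ValueError("interaction endpoints must be non-empty identifiers")
        if self.score is not None and not 0.0 <= self.score <= 1.0:
            raise ValueError(f"interaction score {self.score} outside [0, 1]")


def _parse_biogrid_tab(path) -> list[InteractionRecord]:
    records: list[InteractionRecord] = []
    with open(path, encoding="utf-8") as fh:
        header_line = fh.readline().rstrip("\n")
        header = [h.lstrip("#").strip() for h in header_line.split("\t")]
        positions = {}
        for col in BIOGRID_COLUMNS:
            if col not in header:
                raise ValueError(f"biogrid_tab file lacks column {col!r}")
            positions[col] = header.index(col)
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < len(header):
                raise ValueError(f"line {lineno}: expected {len(header)} fields")
            try:
                taxon_a = int(fields[positions["Organism Interactor A"]])
                taxon_b = int(fields[positions["Organism Interactor B"]])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-integer organism id") from exc
            records.append(
                InteractionRecord(
                    id_a=fields[positions["ID Interactor A"]],
                    id_b=fields[positions["ID Interactor B"]],
                    taxon_a=taxon_a,
                    taxon_b=taxon_b,
                    score=None,
                    evidence=fields[positions["Experimental System"]],
                    symbol_a=fields[positions["Official Symbol Interactor A"]],
                    symbol_b=fields[positions["Official Symbol Interactor B"]],
                )
            )
    return records


def _parse_string_links(path, organism: int) -> list[InteractionRecord]:
    records: list[InteractionRecord] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if header[:3] != list(STRING_COLUMNS):
            raise ValueError(
                f"string_links file must start with columns {STRING_COLUMNS}, got {header[:3]}"
            )
        for lineno, line in enumerate(fh, start=2):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: expected 3 whitespace-separated fields")
            try:
                raw = int(fields[2])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-integer combined_score") from exc
            if not 0 <= raw <= 1000:
                raise ValueError(f"line {lineno}: combined_score {raw} outside 0-1000")
            records.append(
                InteractionRecord(
                    id_a=fields[0],
                    id_b=fields[1],
                    taxon_a=organism,
                    taxon_b=organism,
                    score=raw / 1000.0,
                )
            )
    return records


def parse_interactions(path, dialect: str, organism: int = HUMAN_TAXON) -> list[InteractionRecord]:
    """Parse an interaction table in the named dialect."""
    if dialect == "biogrid_tab":
        return _parse_biogrid_tab(path)
    if dialect == "string_links":
        return _parse_string_links(path, organism)
    raise ValueError(f"unknown interaction dialect {dialect!r}")


def build_first_order_network(
    seeds: GeneSet,
    records: Sequence[InteractionRecord],
    min_score: float | None = None,
    taxon: int | None = None,
    evidence: Callable[[str | None], bool] | None = None,
    label: str = "network",
) -> nx.Graph:
    """Build the graph of seeds plus their direct interactors.

    A record survives iff its score passes ``min_score`` (records without a
    score fail a score filter), both endpoints match ``taxon`` when given,
    the optional evidence predicate accepts it, and at least one endpoint is
    a seed.  Self-loops are dropped; duplicate edges keep the maximum score.
    Every seed appears as a node even when none of its records survive.
    """
    if not seeds.ids:
        raise ValueError("seed set is empty")
    if min_score is not None and not 0.0 <= min_score <= 1.0:
        raise ValueError(f"min_score {min_score} outside [0, 1]")

    g = nx.Graph(label=label, id_space=seeds.id_space)
    for seed in sorted(seeds.ids):
        g.add_node(seed, is_seed=True)

    for rec in records:
        if min_score is not None and (rec.score is None or rec.score < min_score):
            continue
        if taxon is not None and not (rec.taxon_a == taxon and rec.taxon_b == taxon):
            continue
        if evidence is not None and not evidence(rec.evidence):
            continue
        if rec.id_a not in seeds.ids and rec.id_b not in seeds.ids:
            continue
        if rec.id_a == rec.id_b:
            continue
        for node, symbol, node_taxon in (
            (rec.id_a, rec.symbol_a, rec.taxon_a),
            (rec.id_b, rec.symbol_b, rec.taxon_b),
        ):
            if node not in g:
                g.add_node(node, is_seed=node in seeds.ids)
            if symbol:
                g.nodes[node]["symbol"] = symbol
            g.nodes[node]["taxon"] = node_taxon
        if g.has_edge(rec.id_a, rec.id_b):
            old = g.edges[rec.id_a, rec.id_b].get("score")
            new = rec.score
            if new is not None and (old is None or new > old):
                g.edges[rec.id_a, rec.id_b]["score"] = new
                if rec.evidence is not None:
                    g.edges[rec.id_a, rec.id_b]["evidence"] = rec.evidence
        else:
            attrs = {}
            if rec.score is not None:
                attrs["score"] = rec.score
            if rec.evidence is not None:
                attrs["evidence"] = rec.evidence
            g.add_edge(rec.id_a, rec.id_b, **attrs)
    return g


# ---------------------------------------------------------------------- I/O

def write_graphml(g: nx.Graph, path) -> None:
    """GraphML export with node and edge attributes preserved."""
    nx.write_graphml(g, path, named_key_ids=True)


def read_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)


def write_sif(g: nx.Graph, path, relation: str = "pp") -> None:
    """Simple-interaction-format export, symbol-labelled when available."""
    def name(n):
        return g.nodes[n].get("symbol", n)

    with open(path, "w", encoding="utf-8") as fh:
        for u, v in sorted(g.edges(), key=lambda e: tuple(sorted(e))):
            a, b = sorted((name(u), name(v)))
            fh.write(f"{a}\t{relation}\t{b}\n")
        for n in sorted(g.nodes()):
            if g.degree(n) == 0:
                fh.write(f"{name(n)}\n")


def write_edgelist_tsv(g: nx.Graph, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id_a\tid_b\tscore\tevidence\n")
        for u, v in sorted(g.edges(), key=lambda e: tuple(sorted(e))):
            a, b = sorted((u, v))
            d = g.edges[u, v]
            score = "" if d.get("score") is None else f"{d['score']:.3f}"
            fh.write(f"{a}\t{b}\t{score}\t{d.get('evidence', '')}\n")
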