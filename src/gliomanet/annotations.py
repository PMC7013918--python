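"""GO annotations and multi-source gene identifier mapping.

Two concerns live here because they share the same failure mode: identifiers
that do not line up between resources.  :class:`AnnotationTable` stores
direct gene-to-term annotations (no ontology-graph propagation — enrichment
downstream tests exactly what is annotated, nothing inherited).
:class:`IdMap` stores cross-reference rows between Ensembl gene / Ensembl
protein / Entrez / symbol spaces, keeps per-row provenance so that merged
maps resolve conflicts by source precedence, and always reports identifiers
it could not map instead of dropping them.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .core import ID_SPACES, GeneSet, normalize_symbol

logger = logging.getLogger(__name__)

_GO_ACCESSION_RE = re.compile(r"^GO:\d{7}$")
GO_NAMESPACES = ("biological_process", "molecular_function", "cellular_component")


@dataclass(frozen=True)
class GoTerm:
    """A Gene Ontology term: accession, human-readable name, namespace."""

    accession: str
    name: str
    namespace: str = "biological_process"

    def __post_init__(self) -> None:
        if not _GO_ACCESSION_RE.match(self.accession):
            raise ValueError(f"malformed GO accession: {self.accession!r}")
        if not self.name:
            raise ValueError(f"GO term {self.accession} has an empty name")
        if self.namespace not in GO_NAMESPACES:
            raise ValueError(f"unknown GO namespace: {self.namespace!r}")


class AnnotationTable:
    """Direct gene-to-GO annotations with term metadata.

    Entries are unique ``(gene_id, accession)`` pairs; re-adding an existing
    pair is a no-op (annotation deduplication happens here, by construction).
    """

    def __init__(self) -> None:
        self.terms: dict[str, GoTerm] = {}
        self.entries: set[tuple[str, str]] = set()
        self._genes_by_term: dict[str, set[str]] = {}
        self._terms_by_gene: dict[str, set[str]] = {}

    def add_term(self, term: GoTerm) -> None:
        self.terms[term.accession] = term
        self._genes_by_term.setdefault(term.accession, set())

    def annotate(self, gene_id: str, accession: str) -> None:
        if accession not in self.terms:
            raise KeyError(f"unknown GO accession {accession!r}; add its term first")
        self.entries.add((gene_id, accession))
        self._genes_by_term.setdefault(accession, set()).add(gene_id)
        self._terms_by_gene.setdefault(gene_id, set()).add(accession)

    def genes_for_term(self, accession: str) -> frozenset[str]:
        return frozenset(self._genes_by_term.get(accession, ()))

    def terms_for_gene(self, gene_id: str) -> frozenset[str]:
        return frozenset(self._terms_by_gene.get(gene_id, ()))

    def annotated_genes(self) -> frozenset[str]:
        return frozenset(self._terms_by_gene)

    def genes_with_keyword(self, keyword: str) -> frozenset[str]:
        """All genes annotated to >=1 term whose name contains ``keyword``
        (case-insensitive substring)."""
        if not keyword:
            raise ValueError("empty keyword would match every term")
        needle = keyword.lower()
        hits: set[str] = set()
        for accession, term in self.terms.items():
            if needle in term.name.lower():
                hits |= self._genes_by_term.get(accession, set())
        return frozenset(hits)

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_tsv_pair(cls, gene2term_path, term_meta_path) -> "AnnotationTable":
        """Load from a (gene_id, accession) TSV plus a term-metadata TSV
        with columns accession, name, namespace."""
        table = cls()
        meta = pd.read_csv(term_meta_path, sep="\t", dtype=str, keep_default_na=False)
        for col in ("accession", "name", "namespace"):
            if col not in meta.columns:
                raise ValueError(f"term metadata file lacks column {col!r}")
        for row in meta.itertuples(index=False):
            table.add_term(GoTerm(row.accession, row.name, row.namespace))
        pairs = pd.read_csv(gene2term_path, sep="\t", dtype=str, keep_default_na=False)
        for col in ("gene_id", "accession"):
            if col not in pairs.columns:
                raise ValueError(f"gene2term file lacks column {col!r}")
        for row in pairs.itertuples(index=False):
            table.annotate(row.gene_id, row.accession)
        return table

    @classmethod
    def from_gmt(cls, path) -> "AnnotationTable":
        """Load GMT-style lines: ``accession<TAB>name<TAB>gene1<TAB>gene2…``.

        The namespace is not representable in GMT and defaults to
        biological_process.
        """
        table = cls()
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(f"GMT line {lineno}: expected >=3 tab-separated fields")
                accession, name, *genes = fields
                table.add_term(GoTerm(accession, name))
                for gene in genes:
                    if gene:
                        table.annotate(gene, accession)
        return table

    def to_tsv_pair(self, gene2term_path, term_meta_path) -> None:
        with open(term_meta_path, "w", encoding="utf-8") as fh:
            fh.write("accession\tname\tnamespace\n")
            for accession in sorted(self.terms):
                term = self.terms[accession]
                fh.write(f"{term.accession}\t{term.name}\t{term.namespace}\n")
        with open(gene2term_path, "w", encoding="utf-8") as fh:
            fh.write("gene_id\taccession\n")
            for gene_id, accession in sorted(self.entries):
                fh.write(f"{gene_id}\t{accession}\n")


# ---------------------------------------------------------------------------
# Identifier mapping
# ---------------------------------------------------------------------------

_MISSING = ""

IDMAP_COLUMNS = ("ensembl_gene", "ensembl_protein", "entrez", "symbol")


@dataclass
class MappingResult:
    """Outcome of translating a gene set into another identifier space."""

    mapping: dict[str, str]
    unmapped: list[str]
    ambiguous: dict[str, list[str]]
    target_space: str

    @property
    def mapped(self) -> GeneSet:
        return GeneSet(frozenset(self.mapping.values()), self.target_space)


class IdMap:
    """Cross-reference table between gene identifier spaces.

    Each row holds up to four identifiers for one gene plus a provenance
    label and a precedence rank (lower rank wins; manual patches get rank
    -1).  Lookups normalize symbols to uppercase, restrict to the
    highest-precedence rows that resolve, and break remaining ties by the
    lexicographically smallest target, logging the ambiguity.
    """

    def __init__(self) -> None:
        self.rows: list[dict] = []
        self._index: dict[str, dict[str, list[int]]] = {s: {} for s in IDMAP_COLUMNS}
        self.conflicts: list[dict] = []

    def __len__(self) -> int:
        return len(self.rows)

    @staticmethod
    def _norm(space: str, value: str) -> str:
        value = str(value).strip()
        return normalize_symbol(value) if space == "symbol" else value

    def add_row(
        self,
        ensembl_gene: str = _MISSING,
        ensembl_protein: str = _MISSING,
        entrez: str = _MISSING,
        symbol: str = _MISSING,
        provenance: str = "unspecified",
        rank: int = 0,
    ) -> None:
        row = {
            "ensembl_gene": self._norm("ensembl_gene", ensembl_gene),
            "ensembl_protein": self._norm("ensembl_protein", ensembl_protein),
            "entrez": self._norm("entrez", entrez),
            "symbol": self._norm("symbol", symbol) if symbol else _MISSING,
            "provenance": provenance,
            "rank": rank,
        }
        if not any(row[c] for c in IDMAP_COLUMNS):
            raise ValueError("idmap row with every identifier missing")
        idx = len(self.rows)
        self.rows.append(row)
        for space in IDMAP_COLUMNS:
            value = row[space]
            if value:
                self._index[space].setdefault(value, []).append(idx)

    @classmethod
    def from_tsv(cls, path, provenance: str | None = None, rank: int = 0) -> "IdMap":
        """Read a TSV with columns ensembl_gene_id, ensembl_protein_id,
        entrez_id, symbol (blank cell = missing identifier)."""
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        colmap = {
            "ensembl_gene_id": "ensembl_gene",
            "ensembl_protein_id": "ensembl_protein",
            "entrez_id": "entrez",
            "symbol": "symbol",
        }
        missing = [c for c in colmap if c not in frame.columns]
        if missing:
            raise ValueError(f"idmap file lacks columns: {missing}")
        idmap = cls()
        label = provenance if provenance is not None else str(path)
        for row in frame.itertuples(index=False):
            idmap.add_row(
                ensembl_gene=getattr(row, "ensembl_gene_id"),
                ensembl_protein=getattr(row, "ensembl_protein_id"),
                entrez=getattr(row, "entrez_id"),
                symbol=getattr(row, "symbol"),
                provenance=label,
                rank=rank,
            )
        return idmap

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("ensembl_gene_id\tensembl_protein_id\tentrez_id\tsymbol\n")
            for row in self.rows:
                fh.write(
                    f"{row['ensembl_gene']}\t{row['ensembl_protein']}\t"
                    f"{row['entrez']}\t{row['symbol']}\n"
                )

    def _record_conflicts(self) -> None:
        """Log source ids that resolve to multiple distinct targets."""
        for space in IDMAP_COLUMNS:
            for key, indices in self._index[space].items():
                if len(indices) < 2:
                    continue
                for target in IDMAP_COLUMNS:
                    if target == space:
                        continue
                    targets = {self.rows[i][target] for i in indices if self.rows[i][target]}
                    if len(targets) > 1:
                        self.conflicts.append(
                            {"space": space, "id": key, "target_space": target,
                             "targets": sorted(targets)}
                        )
                        logger.info(
                            "idmap conflict: %s %s maps to multiple %s values %s",
                            space, key, target, sorted(targets),
                        )

    # --------------------------------------------------------------- lookup

    def resolve(self, source: str, value: str, target: str) -> tuple[str | None, list[str]]:
        """Resolve one identifier; returns (target id or None, all candidates)."""
        key = self._norm(source, value)
        candidates: dict[str, int] = {}
        for idx in self._index[source].get(key, ()):
            row = self.rows[idx]
            tgt = row[target]
            if tgt:
                best = candidates.get(tgt)
                if best is None or row["rank"] < best:
                    candidates[tgt] = row["rank"]
        if not candidates:
            return None, []
        min_rank = min(candidates.values())
        preferred = sorted(t for t, r in candidates.items() if r == min_rank)
        return preferred[0], preferred

    def translate(self, genes: GeneSet, target: str) -> MappingResult:
        if target not in ID_SPACES:
            raise ValueError(f"unknown target id_space {target!r}")
        if genes.id_space == target:
            raise ValueError(f"source and target id_space are both {target!r}")
        mapping: dict[str, str] = {}
        unmapped: list[str] = []
        ambiguous: dict[str, list[str]] = {}
        for gid in sorted(genes.ids):
            chosen, candidates = self.resolve(genes.id_space, gid, target)
            if chosen is None:
                unmapped.append(gid)
            else:
                mapping[gid] = chosen
                if len(candidates) > 1:
                    ambiguous[gid] = candidates
                    logger.warning(
                        "ambiguous mapping %s -> %s (chose %s of %s)",
                        gid, target, chosen, candidates,
                    )
        return MappingResult(mapping, unmapped, ambiguous, target)


def map_ids(genes: GeneSet, idmap: IdMap, target: str) -> tuple[GeneSet, list[str]]:
    """Map a gene set into ``target`` space.

    Returns the mapped set and the list of input identifiers with no
    resolution — callers must handle the unmapped list explicitly; nothing
    is ever silently dropped.
    """
    result = idmap.translate(genes, target)
    return result.mapped, result.unmapped


def merge_idmaps(maps: Sequence[IdMap]) -> IdMap:
    """Union of several maps; earlier maps take precedence on conflict.

    A conflict is a source identifier that resolves to different targets in
    different input maps; the first-listed map wins and the conflict is
    recorded on the merged map's ``conflicts`` list.
    """
    if not maps:
        raise ValueError("merge_idmaps requires at least one map")
    merged = IdMap()
    for rank, source_map in enumerate(maps):
        for row in source_map.rows:
            merged.add_row(
                ensembl_gene=row["ensembl_gene"],
                ensembl_protein=row["ensembl_protein"],
                entrez=row["entrez"],
                symbol=row["symbol"],
                provenance=row["provenance"],
                rank=rank if row["rank"] >= 0 else row["rank"],
            )
    merged._record_conflicts()
    return merged


def manual_patch(idmap: IdMap, patches: Iterable[dict]) -> IdMap:
    """Return a new map with manually curated rows at highest precedence.

    Each patch is a dict with any subset of the identifier columns; rows are
    tagged with provenance "manual" and rank -1 so they win every lookup.
    """
    patched = IdMap()
    for i, patch in enumerate(patches):
        unknown = set(patch) - set(IDMAP_COLUMNS)
        if unknown:
            raise ValueError(f"patch row {i}: unknown fields {sorted(unknown)}")
        if not any(patch.get(c) for c in IDMAP_COLUMNS):
            raise ValueError(f"patch row {i}: every identifier missing")
        patched.add_row(
            ensembl_gene=patch.get("ensembl_gene", _MISSING),
            ensembl_protein=patch.get("ensembl_protein", _MISSING),
            entrez=patch.get("entrez", _MISSING),
            symbol=patch.get("symbol", _MISSING),
            provenance="manual",
            rank=-1,
        )
    for row in idmap.rows:
        patched.add_row(
            ensembl_gene=row["ensembl_gene"],
            ensembl_protein=row["ensembl_protein"],
            entrez=row["entrez"],
            symbol=row["symbol"],
            provenance=row["provenance"],
            rank=row["rank"] if row["rank"] >= 0 else 0,
        )
    patched._record_conflicts()
    return patched
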