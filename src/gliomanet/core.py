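"""Shared primitive types used across the pipeline.

The pipeline moves gene sets between four identifier spaces (Ensembl gene,
Ensembl protein, Entrez, HGNC-style symbol).  A :class:`GeneSet` is a frozen
set of identifiers tagged with the space they live in, so that downstream
operations can refuse to mix spaces silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

#: Recognized identifier spaces, in the order used for mapping preference.
ID_SPACES = ("ensembl_gene", "ensembl_protein", "entrez", "symbol")


def normalize_symbol(symbol: str) -> str:
    """Uppercase and trim a gene symbol.

    Symbol spellings vary between databases and export tools; comparisons
    are therefore always done on the uppercased, whitespace-stripped form.
    """
    return symbol.strip().upper()


@dataclass(frozen=True)
class GeneSet:
    """An immutable set of gene identifiers in a single identifier space."""

    ids: frozenset[str]
    id_space: str = "ensembl_gene"

    def __post_init__(self) -> None:
        if self.id_space not in ID_SPACES:
            raise ValueError(
                f"unknown id_space {self.id_space!r}; expected one of {ID_SPACES}"
            )
        object.__setattr__(self, "ids", frozenset(self.ids))

    @classmethod
    def from_iterable(cls, ids: Iterable[str], id_space: str = "ensembl_gene") -> "GeneSet":
        return cls(ids=frozenset(ids), id_space=id_space)

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.ids))

    def __contains__(self, gene_id: object) -> bool:
        return gene_id in self.ids

    def _require_same_space(self, other: "GeneSet") -> None:
        if self.id_space != other.id_space:
            raise ValueError(
                f"id_space mismatch: {self.id_space!r} vs {other.id_space!r}"
            )

    def union(self, other: "GeneSet") -> "GeneSet":
        self._require_same_space(other)
        return GeneSet(self.ids | other.ids, self.id_space)

    def intersection(self, other: "GeneSet") -> "GeneSet":
        self._require_same_space(other)
        return GeneSet(self.ids & other.ids, self.id_space)

    def difference(self, other: "GeneSet") -> "GeneSet":
        self._require_same_space(other)
        return GeneSet(self.ids - other.ids, self.id_space)

    def issubset(self, other: "GeneSet") -> bool:
        self._require_same_space(other)
        return self.ids <= other.ids


def write_gene_list(genes: GeneSet, path) -> None:
    """Write one identifier per line, sorted, newline-terminated."""
    with open(path, "w", encoding="utf-8") as fh:
        for gid in sorted(genes.ids):
            fh.write(f"{gid}\n")


def write_gene_table(genes: GeneSet, symbols: dict[str, str], path) -> None:
    """Write a two-column TSV (identifier, symbol); missing symbols blank."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tgene_symbol\n")
        for gid in sorted(genes.ids):
            fh.write(f"{gid}\t{symbols.get(gid, '')}\n")
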