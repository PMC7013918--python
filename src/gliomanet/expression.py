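"""Expression-table parsing and seed-gene filtering.

Disease-specific seed gene lists are extracted from Expression Atlas–style
TSV tables (one FPKM column per condition) by an absolute expression cutoff,
optionally narrowed by a GO-keyword filter ("proliferation" by default), or
from differential-expression tables by p-value / log2 fold-change /
direction filters.  All boundary conventions are explicit:

* FPKM cutoff removes values strictly below the threshold, so a value equal
  to the cutoff is kept (default cutoff 3.0 FPKM; the equivalent bound on
  the TPM scale is 10).
* DEG filtering keeps rows with p-value strictly below ``p_max`` and
  log2 fold-change >= ``lfc_min`` — upregulated genes only.
* A missing expression cell means "not observed" and never passes a cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .annotations import AnnotationTable
from .core import GeneSet

#: Equivalent cutoff on the transcripts-per-million scale, kept as metadata
#: for tables normalized in TPM rather than FPKM.
TPM_CUTOFF_EQUIVALENT = 10.0

DEFAULT_FPKM_CUTOFF = 3.0


@dataclass
class ExpressionRecord:
    """Per-gene expression levels (FPKM), one value per condition.

    ``values`` maps condition name -> level; ``None`` marks a missing cell.
    """

    gene_id: str
    gene_symbol: str
    values: dict[str, float | None]


@dataclass
class DEGRecord:
    """One row of a differential-expression result table."""

    gene_id: str
    gene_symbol: str
    log2_fold_change: float
    p_value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(
                f"gene {self.gene_id}: p-value {self.p_value} outside [0, 1]"
            )


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def parse_expression_table(
    path,
    id_col: str = "Gene ID",
    symbol_col: str = "Gene Name",
    id_space: str = "ensembl_gene",
) -> list[ExpressionRecord]:
    """Parse a per-condition FPKM table.

    Every column other than the identifier and symbol columns is treated as
    a condition.  Blank cells become ``None`` (missing, not zero).  Negative
    values and duplicated gene identifiers are errors.
    """
    frame = _read_tsv(path)
    for col in (id_col, symbol_col):
        if col not in frame.columns:
            raise ValueError(f"expression table lacks required column {col!r}")
    conditions = [c for c in frame.columns if c not in (id_col, symbol_col)]
    if not conditions:
        raise ValueError("expression table has no condition columns")

    ids = frame[id_col].tolist()
    dupes = sorted({g for g in ids if ids.count(g) > 1}) if len(set(ids)) < len(ids) else []
    if dupes:
        raise ValueError(f"duplicated gene ids in expression table: {dupes}")

    records: list[ExpressionRecord] = []
    for rownum, (_, row) in enumerate(frame.iterrows(), start=2):
        values: dict[str, float | None] = {}
        for cond in conditions:
            cell = str(row[cond]).strip()
            if cell == "" or cell.upper() in ("NA", "NAN"):
                values[cond] = None
                continue
            try:
                level = float(cell)
            except ValueError as exc:
                raise ValueError(
                    f"row {rownum}, column {cond!r}: non-numeric value {cell!r}"
                ) from exc
            if math.isnan(level):
                values[cond] = None
                continue
            if level < 0:
                raise ValueError(
                    f"row {rownum}, column {cond!r}: negative expression {level}"
                )
            values[cond] = level
        records.append(
            ExpressionRecord(
                gene_id=str(row[id_col]).strip(),
                gene_symbol=str(row[symbol_col]).strip(),
                values=values,
            )
        )
    return records


def parse_deg_table(
    path,
    id_col: str = "Gene ID",
    symbol_col: str = "Gene Name",
    lfc_col: str = "log2foldchange",
    p_col: str = "pvalue",
) -> list[DEGRecord]:
    """Parse a differential-expression table (identifier, symbol, log2FC, p)."""
    frame = _read_tsv(path)
    for col in (id_col, symbol_col, lfc_col, p_col):
        if col not in frame.columns:
            raise ValueError(f"DEG table lacks required column {col!r}")
    records = []
    for rownum, (_, row) in enumerate(frame.iterrows(), start=2):
        try:
            lfc = float(row[lfc_col])
            p = float(row[p_col])
        except ValueError as exc:
            raise ValueError(f"row {rownum}: non-numeric fold-change or p-value") from exc
        records.append(
            DEGRecord(
                gene_id=str(row[id_col]).strip(),
                gene_symbol=str(row[symbol_col]).strip(),
                log2_fold_change=lfc,
                p_value=p,
            )
        )
    return records


def filter_by_cutoff(
    records: list[ExpressionRecord],
    condition: str,
    cutoff: float = DEFAULT_FPKM_CUTOFF,
    id_space: str = "ensembl_gene",
) -> GeneSet:
    """Seed genes for one condition: expression >= cutoff.

    Values strictly below the cutoff are removed, so a gene at exactly the
    cutoff survives.  Missing values never pass.
    """
    if cutoff < 0:
        raise ValueError(f"cutoff must be non-negative, got {cutoff}")
    if records and not any(condition in r.values for r in records):
        raise KeyError(f"unknown condition {condition!r}")
    kept = {
        r.gene_id
        for r in records
        if r.values.get(condition) is not None and r.values[condition] >= cutoff
    }
    return GeneSet(frozenset(kept), id_space)


def filter_upregulated(
    records: list[DEGRecord],
    p_max: float = 0.05,
    lfc_min: float = 1.0,
    id_space: str = "symbol",
) -> GeneSet:
    """Upregulated significant genes: p < p_max and log2FC >= lfc_min."""
    if not (math.isfinite(p_max) and math.isfinite(lfc_min)):
        raise ValueError("thresholds must be finite")
    kept = {
        r.gene_id
        for r in records
        if r.p_value < p_max and r.log2_fold_change >= lfc_min
    }
    return GeneSet(frozenset(kept), id_space)


def filter_by_go_keyword(
    genes: GeneSet,
    annotations: AnnotationTable,
    keyword: str = "proliferation",
) -> GeneSet:
    """Keep genes annotated to >=1 GO term whose name contains ``keyword``.

    Matching is a case-insensitive substring test on term names — the filter
    follows a word, not a GO accession.
    """
    matching = annotations.genes_with_keyword(keyword)
    return GeneSet(genes.ids & matching, genes.id_space)


def symbol_index(records: list[ExpressionRecord]) -> dict[str, str]:
    """Gene id -> symbol lookup for report writing."""
    return {r.gene_id: r.gene_symbol for r in records}
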