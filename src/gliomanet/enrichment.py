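"""GO over-representation testing.

For each term the study set is treated as a draw of ``n`` genes from a
background of ``N``, of which ``K`` carry the term; the p-value is the
upper tail of the hypergeometric distribution,

    p = sum_{i=k}^{min(n,K)} C(K,i) C(N-K, n-i) / C(N,n),

i.e. the probability of seeing at least the observed ``k`` annotated study
genes by chance.  Only over-representation is tested (one-sided), only
direct annotations count (no ontology-graph propagation), and q-values come
from Benjamini–Hochberg FDR adjustment across all tested terms.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

import networkx as nx

from .annotations import AnnotationTable, GoTerm
from .core import GeneSet


@dataclass(frozen=True)
class EnrichmentRow:
    """One term's 2x2 urn counts and significance."""

    term: GoTerm
    k: int
    n: int
    K: int
    N: int
    p_value: float
    q_value: float
    significant: bool

    def __post_init__(self) -> None:
        _validate_counts(self.k, self.n, self.K, self.N)
        for name, val in (("p_value", self.p_value), ("q_value", self.q_value)):
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} {val} outside [0, 1]")


def _validate_counts(k: int, n: int, K: int, N: int) -> None:
    if N < 0 or not (0 <= K <= N) or not (0 <= n <= N):
        raise ValueError(f"invalid urn counts: n={n}, K={K}, N={N}")
    if not 0 <= k <= min(n, K):
        raise ValueError(f"invalid count k={k} for n={n}, K={K}, N={N}")


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    _validate_counts(k, n, K, N)
    if k == 0:
        return 1.0
    # sf(k-1) is the upper tail including k; scipy computes it stably.
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(
    study: GeneSet,
    background: GeneSet,
    annotations: AnnotationTable,
    alpha: float = 0.05,
) -> list[EnrichmentRow]:
    """Test every annotated term for over-representation in the study set.

    Terms with no annotated gene in the background are skipped.  Rows are
    sorted by ascending p-value, ties by accession, and carry BH q-values
    over all tested terms; ``significant`` flags q <= alpha.
    """
    if not study.ids or not background.ids:
        raise ValueError("study and background sets must be nonempty")
    if not study.ids <= background.ids:
        extra = sorted(study.ids - background.ids)[:5]
        raise ValueError(f"study set is not contained in background (e.g. {extra})")

    n = len(study.ids)
    N = len(background.ids)
    tested: list[tuple[GoTerm, int, int]] = []
    for accession in sorted(annotations.terms):
        annotated = annotations.genes_for_term(accession) & background.ids
        K = len(annotated)
        if K == 0:
            continue
        k = len(annotated & study.ids)
        tested.append((annotations.terms[accession], k, K))
    if not tested:
        return []

    pvalues = [hypergeom_upper_tail(k, n, K, N) for _, k, K in tested]
    _, qvalues, _, _ = multipletests(pvalues, method="fdr_bh")

    rows = [
        EnrichmentRow(
            term=term,
            k=k,
            n=n,
            K=K,
            N=N,
            p_value=p,
            q_value=float(q),
            significant=bool(q <= alpha),
        )
        for (term, k, K), p, q in zip(tested, pvalues, qvalues)
    ]
    rows.sort(key=lambda r: (r.p_value, r.term.accession))
    return rows


def term_node_count(network: nx.Graph, term: GoTerm, annotations: AnnotationTable) -> int:
    """How many network nodes are annotated to the term."""
    return len(annotations.genes_for_term(term.accession) & set(network.nodes()))


def write_enrichment_tsv(rows: list[EnrichmentRow], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("accession\tname\tnamespace\tk\tn\tK\tN\tp_value\tq_value\tsignificant\n")
        for r in rows:
            fh.write(
                f"{r.term.accession}\t{r.term.name}\t{r.term.namespace}\t"
                f"{r.k}\t{r.n}\t{r.K}\t{r.N}\t{r.p_value:.6g}\t{r.q_value:.6g}\t"
                f"{'yes' if r.significant else 'no'}\n"
            )
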