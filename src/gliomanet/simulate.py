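"""Synthetic pipeline inputs with planted, recoverable structure.

The generator emits every input the pipeline consumes — an expression table
with one FPKM column per disease condition, interaction tables in both
supported dialects, a gene–GO annotation table, two identifier maps with
controlled missingness, and a symbol-keyed differential-expression table —
together with a :class:`SyntheticTruth` record of what was planted:

* disease-shared and disease-unique over-expressed genes (log-normal FPKM,
  background centred well below the cutoff of 3, over-expressed genes drawn
  from a shifted distribution so that >=95% exceed it);
* protein complexes as cliques among shared seed genes, with confidence
  scores >= 0.9 so they survive a STRING-style 90% filter;
* hub genes wired to many background partners;
* seeds that appear in *no* interaction record of either dialect and must
  therefore surface as isolated nodes common to every disease network;
* noise edges with mostly sub-0.9 Beta-distributed scores, a fraction of
  them carrying a non-human taxon to exercise taxonomy filtering;
* one GO term enriched among the disease-unique genes, plus a
  "proliferation"-named term annotating every seed (the keyword filter's
  target) and generic filler terms;
* an identifier map missing ~20% of Ensembl gene ids, a second map that
  closes the gap, and exactly one gene unmappable to Ensembl anywhere.

Everything is drawn from one seeded NumPy generator, so a config reproduces
its outputs byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .annotations import AnnotationTable, GoTerm, IdMap
from .core import GeneSet

PROLIFERATION_TERM = GoTerm("GO:0008283", "cell population proliferation")
ENRICHED_TERM = GoTerm("GO:0099999", "planted enriched process (synthetic)")
FILLER_TERMS = (
    GoTerm("GO:0006915", "apoptotic process"),
    GoTerm("GO:0007165", "signal transduction"),
    GoTerm("GO:0007155", "cell adhesion"),
    GoTerm("GO:0006955", "immune response"),
)
EVIDENCE_SYSTEMS = ("Two-hybrid", "Affinity Capture-MS", "Co-fractionation")


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic universe, with study-scale defaults."""

    n_genes: int = 400
    n_diseases: int = 3
    shared_overexpressed: int = 30
    unique_overexpressed: int = 12
    #: log-normal parameters: background (mu, sigma) and over-expressed mu.
    fpkm_mu: float = -1.0
    fpkm_sigma: float = 0.6
    fpkm_mu_hi: float = 3.0
    #: (size, count) pairs of planted cliques among shared seed genes.
    planted_complexes: tuple[tuple[int, int], ...] = ((5, 2), (6, 1))
    planted_hubs: int = 10
    hub_degree: int = 30
    planted_isolated_seeds: int = 3
    #: per-pair probability of a spurious interaction.
    noise_edge_prob: float = 0.004
    #: Beta(a, b) parameters of noise-edge confidence scores.
    score_beta: tuple[float, float] = (2.0, 6.0)
    contaminant_taxon_fraction: float = 0.05
    contaminant_taxon: int = 10090
    taxon: int = 9606
    #: fraction of disease-unique genes / other genes carrying the enriched term.
    enriched_term_study_fraction: float = 0.9
    enriched_term_background_fraction: float = 0.05
    idmap_missing_fraction: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        complex_genes = sum(size * count for size, count in self.planted_complexes)
        planted = complex_genes + self.planted_hubs + self.planted_isolated_seeds
        if planted > self.shared_overexpressed:
            raise ValueError(
                f"planted structure needs {planted} shared genes but only "
                f"{self.shared_overexpressed} are configured"
            )
        needed = self.shared_overexpressed + self.n_diseases * self.unique_overexpressed
        if needed + self.hub_degree > self.n_genes:
            raise ValueError("n_genes too small for the configured planted structure")
        for name in (
            "noise_edge_prob",
            "contaminant_taxon_fraction",
            "enriched_term_study_fraction",
            "enriched_term_background_fraction",
            "idmap_missing_fraction",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if min(s for s, _ in self.planted_complexes) < 3:
            raise ValueError("planted complexes must have size >= 3")


@dataclass
class SyntheticTruth:
    """The planted structure against which pipeline recovery is scored."""

    conditions: list[str]
    seeds_by_disease: dict[str, list[str]]
    shared_genes: list[str]
    unique_by_disease: dict[str, list[str]]
    complexes: list[list[str]]
    hub_genes: list[str]
    always_isolated: list[str]
    enriched_term_accession: str
    proliferation_term_accession: str
    unmappable_gene: str

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


def _ensg(i: int) -> str:
    return f"ENSG{i:011d}"


def _ensp(i: int) -> str:
    return f"ENSP{i:011d}"


def _entrez(i: int) -> str:
    return str(10000 + i)


def _symbol(i: int) -> str:
    return f"GENE{i:04d}"


@dataclass
class _Edge:
    a: int
    b: int
    score: float  # [0, 1]
    taxon_a: int
    taxon_b: int
    evidence: str
    kind: str  # complex | hub | anchor | noise


@dataclass
class SyntheticDataset:
    """In-memory generated inputs plus the truth; ``write`` renders files."""

    config: GeneratorConfig
    truth: SyntheticTruth
    expression: list[tuple[str, str, list[float]]]
    deg_rows: list[tuple[str, str, float, float]]
    edges: list[_Edge]
    annotations: AnnotationTable
    idmap_primary: IdMap
    idmap_secondary: IdMap

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "expression": outdir / "expression.tsv",
            "deg": outdir / "deg_table.tsv",
            "biogrid": outdir / "interactions_biogrid.tsv",
            "string": outdir / "string_links.txt",
            "annotations_genes": outdir / "annotations_gene2term.tsv",
            "annotations_terms": outdir / "annotations_terms.tsv",
            "annotations_gmt": outdir / "annotations.gmt",
            "idmap_primary": outdir / "idmap_biomart.tsv",
            "idmap_secondary": outdir / "idmap_secondary.tsv",
            "truth": outdir / "truth.json",
        }
        with open(paths["expression"], "w", encoding="utf-8") as fh:
            fh.write("Gene ID\tGene Name\t" + "\t".join(self.truth.conditions) + "\n")
            for gid, symbol, values in self.expression:
                vals = "\t".join(f"{v:.4f}" for v in values)
                fh.write(f"{gid}\t{symbol}\t{vals}\n")
        with open(paths["deg"], "w", encoding="utf-8") as fh:
            fh.write("Gene ID\tGene Name\tlog2foldchange\tpvalue\n")
            for gid, symbol, lfc, p in self.deg_rows:
                fh.write(f"{gid}\t{symbol}\t{lfc:.4f}\t{p:.6g}\n")
        with open(paths["biogrid"], "w", encoding="utf-8") as fh:
            fh.write(
                "#ID Interactor A\tID Interactor B\t"
                "Official Symbol Interactor A\tOfficial Symbol Interactor B\t"
                "Organism Interactor A\tOrganism Interactor B\tExperimental System\n"
            )
            for e in sorted(self.edges, key=lambda e: (e.a, e.b)):
                fh.write(
                    f"{_entrez(e.a)}\t{_entrez(e.b)}\t{_symbol(e.a)}\t{_symbol(e.b)}\t"
                    f"{e.taxon_a}\t{e.taxon_b}\t{e.evidence}\n"
                )
        with open(paths["string"], "w", encoding="utf-8") as fh:
            fh.write("protein1 protein2 combined_score\n")
            for e in sorted(self.edges, key=lambda e: (e.a, e.b)):
                fh.write(f"{_ensp(e.a)} {_ensp(e.b)} {round(e.score * 1000)}\n")
        self.annotations.to_tsv_pair(
            paths["annotations_genes"], paths["annotations_terms"]
        )
        with open(paths["annotations_gmt"], "w", encoding="utf-8") as fh:
            for accession in sorted(self.annotations.terms):
                term = self.annotations.terms[accession]
                genes = sorted(self.annotations.genes_for_term(accession))
                fh.write("\t".join([accession, term.name] + genes) + "\n")
        self.idmap_primary.to_tsv(paths["idmap_primary"])
        self.idmap_secondary.to_tsv(paths["idmap_secondary"])
        self.truth.to_json(paths["truth"])
        return paths


def generate(config: GeneratorConfig | None = None, outdir=None) -> SyntheticDataset:
    """Generate the full synthetic universe; write files when ``outdir`` given."""
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    conditions = [f"disease_{d + 1}" for d in range(config.n_diseases)]

    # ---- gene role assignment -------------------------------------------
    perm = rng.permutation(n)
    cursor = 0
    shared = list(perm[cursor : cursor + config.shared_overexpressed])
    cursor += config.shared_overexpressed
    unique: dict[str, list[int]] = {}
    for cond in conditions:
        unique[cond] = list(perm[cursor : cursor + config.unique_overexpressed])
        cursor += config.unique_overexpressed
    background = list(perm[cursor:])

    pos = 0
    complexes: list[list[int]] = []
    for size, count in config.planted_complexes:
        for _ in range(count):
            complexes.append(shared[pos : pos + size])
            pos += size
    hubs = shared[pos : pos + config.planted_hubs]
    pos += config.planted_hubs
    isolated = shared[pos : pos + config.planted_isolated_seeds]
    pos += config.planted_isolated_seeds

    seeds_by_disease = {cond: sorted(shared + unique[cond]) for cond in conditions}
    all_seeds = sorted({g for s in seeds_by_disease.values() for g in s})
    unique_union = sorted({g for u in unique.values() for g in u})

    # ---- expression values ----------------------------------------------
    values = rng.lognormal(config.fpkm_mu, config.fpkm_sigma, size=(n, len(conditions)))
    for d, cond in enumerate(conditions):
        idx = np.array(seeds_by_disease[cond])
        values[idx, d] = rng.lognormal(config.fpkm_mu_hi, config.fpkm_sigma, size=len(idx))
    expression = [
        (_ensg(i), _symbol(i), [float(values[i, d]) for d in range(len(conditions))])
        for i in range(n)
    ]

    # ---- DEG table for the first condition (symbol-keyed) ---------------
    deg_rows = []
    first_seeds = set(seeds_by_disease[conditions[0]])
    for i in range(n):
        if i in first_seeds:
            lfc = float(rng.uniform(1.5, 4.0))
            p = float(10.0 ** rng.uniform(-6, -2))
        else:
            lfc = float(rng.normal(0.0, 0.5))
            p = float(rng.uniform(0.0, 1.0))
        deg_rows.append((_symbol(i), _symbol(i), lfc, p))

    # ---- interactions ----------------------------------------------------
    forbidden = set(isolated)  # appear in no record of any dialect
    edges: list[_Edge] = []
    seen_pairs: set[tuple[int, int]] = set()

    def add_edge(a: int, b: int, score: float, kind: str,
                 taxon_a: int | None = None, taxon_b: int | None = None) -> bool:
        if a == b or a in forbidden or b in forbidden:
            return False
        key = (min(a, b), max(a, b))
        if key in seen_pairs:
            return False
        seen_pairs.add(key)
        edges.append(
            _Edge(
                a=key[0],
                b=key[1],
                score=float(score),
                taxon_a=config.taxon if taxon_a is None else taxon_a,
                taxon_b=config.taxon if taxon_b is None else taxon_b,
                evidence=str(rng.choice(EVIDENCE_SYSTEMS)),
                kind=kind,
            )
        )
        return True

    for members in complexes:
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                add_edge(a, b, rng.uniform(0.9, 1.0), "complex")

    bg_pool = np.array(background)
    for hub in hubs:
        partners = rng.choice(bg_pool, size=config.hub_degree, replace=False)
        for partner in partners:
            add_edge(hub, int(partner), rng.uniform(0.9, 1.0), "hub")

    # every non-isolated seed gets >=2 high-confidence anchor interactions,
    # so that planted-isolated seeds are the only seeds isolated everywhere
    covered = {e.a for e in edges} | {e.b for e in edges}
    for seed_gene in all_seeds:
        if seed_gene in forbidden or seed_gene in covered:
            continue
        partners = rng.choice(bg_pool, size=2, replace=False)
        for partner in partners:
            add_edge(seed_gene, int(partner), rng.uniform(0.9, 1.0), "anchor")

    n_pairs = n * (n - 1) // 2
    n_noise = int(rng.binomial(n_pairs, config.noise_edge_prob))
    placed = 0
    while placed < n_noise:
        a, b = (int(x) for x in rng.integers(0, n, size=2))
        contaminated = rng.random() < config.contaminant_taxon_fraction
        taxon = config.contaminant_taxon if contaminated else config.taxon
        if add_edge(a, b, rng.beta(*config.score_beta), "noise", taxon, taxon):
            placed += 1

    # ---- annotations -----------------------------------------------------
    table = AnnotationTable()
    for term in (PROLIFERATION_TERM, ENRICHED_TERM) + FILLER_TERMS:
        table.add_term(term)
    for g in all_seeds:
        table.annotate(_ensg(g), PROLIFERATION_TERM.accession)
    non_seeds = [i for i in range(n) if i not in set(all_seeds)]
    prolif_extra = rng.choice(np.array(non_seeds), size=max(1, len(non_seeds) // 20),
                              replace=False)
    for g in prolif_extra:
        table.annotate(_ensg(int(g)), PROLIFERATION_TERM.accession)

    n_hi = int(round(config.enriched_term_study_fraction * len(unique_union)))
    enriched_hi = rng.choice(np.array(unique_union), size=n_hi, replace=False)
    rest = [i for i in range(n) if i not in set(unique_union)]
    n_lo = int(round(config.enriched_term_background_fraction * len(rest)))
    enriched_lo = rng.choice(np.array(rest), size=n_lo, replace=False)
    for g in list(enriched_hi) + list(enriched_lo):
        table.annotate(_ensg(int(g)), ENRICHED_TERM.accession)

    for term in FILLER_TERMS:
        carriers = rng.choice(n, size=n // 10, replace=False)
        for g in carriers:
            table.annotate(_ensg(int(g)), term.accession)

    # ---- identifier maps -------------------------------------------------
    n_missing = int(round(config.idmap_missing_fraction * n))
    missing = set(int(g) for g in rng.choice(n, size=n_missing, replace=False))
    unmappable_candidates = sorted(set(background) & missing) or sorted(background)
    unmappable = unmappable_candidates[0]
    missing.add(unmappable)

    primary = IdMap()
    for i in range(n):
        primary.add_row(
            ensembl_gene="" if i in missing else _ensg(i),
            ensembl_protein=_ensp(i),
            entrez=_entrez(i),
            symbol=_symbol(i),
            provenance="biomart",
        )
    secondary = IdMap()
    for i in sorted(missing):
        if i == unmappable:
            continue
        secondary.add_row(
            ensembl_gene=_ensg(i),
            ensembl_protein=_ensp(i),
            entrez=_entrez(i),
            symbol=_symbol(i),
            provenance="gprofiler",
        )

    truth = SyntheticTruth(
        conditions=conditions,
        seeds_by_disease={c: [_ensg(g) for g in seeds_by_disease[c]] for c in conditions},
        shared_genes=[_ensg(g) for g in sorted(shared)],
        unique_by_disease={c: [_ensg(g) for g in sorted(unique[c])] for c in conditions},
        complexes=[sorted(_ensg(g) for g in members) for members in complexes],
        hub_genes=[_ensg(g) for g in sorted(hubs)],
        always_isolated=[_ensg(g) for g in sorted(isolated)],
        enriched_term_accession=ENRICHED_TERM.accession,
        proliferation_term_accession=PROLIFERATION_TERM.accession,
        unmappable_gene=_ensg(unmappable),
    )

    dataset = SyntheticDataset(
        config=config,
        truth=truth,
        expression=expression,
        deg_rows=deg_rows,
        edges=edges,
        annotations=table,
        idmap_primary=primary,
        idmap_secondary=secondary,
    )
    if outdir is not None:
        dataset.write(outdir)
    return dataset


# ---------------------------------------------------------------------------
# Recovery scoring
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    """How well the pipeline recovered the planted structure."""

    complex_jaccard: dict[str, list[float]]
    mean_complex_jaccard: float
    hub_recovery: dict[str, float]
    min_hub_recovery: float
    isolated_exact: bool
    recovered_isolated: dict[str, list[str]]
    difference_purity: dict[str, float]
    min_difference_purity: float
    enriched_term_rank: dict[str, int | None]
    best_enriched_rank: int | None

    def as_dict(self) -> dict:
        return asdict(self)


def _jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def score_recovery(truth: SyntheticTruth, result) -> RecoveryReport:
    """Score a :class:`~gliomanet.pipeline.PipelineResult` against the truth.

    Network node sets are translated to Ensembl gene space with the
    pipeline's merged identifier map before comparison; identifiers that do
    not map count against recovery rather than being excused.
    """
    idmap = result.idmap

    def to_ensg(ids: Sequence[str], space: str) -> dict[str, str]:
        if space == "ensembl_gene":
            return {i: i for i in ids}
        mapping, _ = _translate(idmap, ids, space)
        return mapping

    def _translate(idmap, ids, space):
        res = idmap.translate(GeneSet(frozenset(ids), space), "ensembl_gene")
        return res.mapping, res.unmapped

    hub_truth = set(truth.hub_genes)
    hub_recovery: dict[str, float] = {}
    for key, hubs in result.hubs.items():
        mapping = to_ensg(hubs.ids(), hubs.id_space)
        recovered = {mapping.get(h) for h in hubs.ids()} & hub_truth
        hub_recovery["/".join(key)] = len(recovered) / len(hub_truth)

    recovered_isolated: dict[str, list[str]] = {}
    isolated_exact = True
    for db, genes in result.common_isolated_by_db.items():
        mapping = to_ensg(sorted(genes.ids), genes.id_space)
        mapped = sorted(mapping.get(g, g) for g in genes.ids)
        recovered_isolated[db] = mapped
        if set(mapped) != set(truth.always_isolated):
            isolated_exact = False

    # a unique-network node is "pure" if it is a truth-unique gene or a
    # neighbor of one in the parent disease network (its exclusivity is
    # already established by surviving the intersection subtraction)
    purity: dict[str, float] = {}
    for key, g in result.unique.items():
        db, cond = key
        parent = result.networks[key]
        unique_truth = set(truth.unique_by_disease[cond])
        space = g.graph.get("id_space", "ensembl_gene")
        mapping = to_ensg(list(parent.nodes()), space)
        if g.number_of_nodes() == 0:
            purity["/".join(key)] = 1.0
            continue
        pure = 0
        for node in g.nodes():
            ensg = mapping.get(node)
            if ensg in unique_truth:
                pure += 1
                continue
            if any(
                mapping.get(nb) in unique_truth for nb in parent.neighbors(node)
            ):
                pure += 1
        purity["/".join(key)] = pure / g.number_of_nodes()

    complex_truth = [set(members) for members in truth.complexes]
    complex_jaccard: dict[str, list[float]] = {}
    for key, clustering in result.clusterings.items():
        db, cond = key
        g = result.networks[key]
        space = g.graph.get("id_space", "ensembl_gene")
        cluster_sets = []
        for cluster in clustering.clusters:
            mapping = to_ensg(sorted(cluster.members), space)
            cluster_sets.append({mapping.get(m, m) for m in cluster.members})
        scores = []
        for planted in complex_truth:
            best = max((_jaccard(planted, c) for c in cluster_sets), default=0.0)
            scores.append(best)
        complex_jaccard["/".join(key)] = scores

    all_scores = [s for scores in complex_jaccard.values() for s in scores]
    mean_cj = sum(all_scores) / len(all_scores) if all_scores else 0.0

    # the keyword-filter term is enriched by selection (every seed carries
    # it), so the planted term's rank is computed among the other terms
    enriched_rank: dict[str, int | None] = {}
    for key, rows in result.enrichments.items():
        rank = None
        position = 0
        for row in rows:
            if row.term.accession == truth.proliferation_term_accession:
                continue
            position += 1
            if row.term.accession == truth.enriched_term_accession:
                rank = position
                break
        enriched_rank["/".join(key)] = rank
    ranks = [r for r in enriched_rank.values() if r is not None]

    return RecoveryReport(
        complex_jaccard=complex_jaccard,
        mean_complex_jaccard=mean_cj,
        hub_recovery=hub_recovery,
        min_hub_recovery=min(hub_recovery.values()) if hub_recovery else 0.0,
        isolated_exact=isolated_exact,
        recovered_isolated=recovered_isolated,
        difference_purity=purity,
        min_difference_purity=min(purity.values()) if purity else 0.0,
        enriched_term_rank=enriched_rank,
        best_enriched_rank=min(ranks) if ranks else None,
    )
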