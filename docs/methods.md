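# Methods

## Problem setting

Given per-condition gene expression tables and bulk interaction databases,
the pipeline builds one PPI network per disease condition and per database
dialect, compares the networks algebraically, and characterises the parts
unique to each condition. Nothing in the pipeline queries a live service;
all inputs are plain-text tables, so a run is a pure function of its input
files and parameters.

## Seed selection

Seeds are genes considered "expressed and relevant" in a condition.

* **Expression cutoff** — a gene passes if its FPKM value in the chosen
  condition is ≥ `cutoff` (default 3.0). The convention is removal of
  values *strictly below* the cutoff, so a gene at exactly the threshold
  survives. The equivalent bound on the TPM scale (10) is recorded as
  metadata (`TPM_CUTOFF_EQUIVALENT`) for tables normalised differently.
  Missing cells mean "not observed" and never pass any cutoff, including a
  cutoff of 0 — absence of evidence must not create seeds. When a table
  carries several condition columns the caller must name the condition; no
  cross-condition summary is implied.
* **DEG filtering** — for differential-expression tables the filter is
  `p < 0.05` (strict, the convention of count-model DE tools) and
  `log2FC ≥ 1` (boundary kept), upregulated genes only. Both thresholds
  are parameters.
* **GO keyword** — a gene survives if annotated to at least one GO term
  whose *name* contains the keyword as a case-insensitive substring
  (default `proliferation`). The filter follows a word, not an accession,
  because curated pipelines of this kind select on the concept; all terms
  whose names contain the word contribute.

Duplicate gene ids in an expression table are an error rather than being
deduplicated silently; identifier-level deduplication belongs to the
id-mapping layer, where provenance can be recorded.

## Identifier mapping

An `IdMap` holds rows of up to four identifiers (Ensembl gene, Ensembl
protein, Entrez, symbol) plus a provenance label and a precedence rank.
Symbols are normalised to trimmed uppercase on ingest because symbol
spelling varies across databases and export tools. Lookups restrict to the
highest-precedence rows that resolve (manual patches, rank −1, always win;
otherwise the order in which maps were merged), then break residual ties by
the lexicographically smallest target. Every ambiguous resolution and every
merge conflict is logged; every unresolved identifier is returned in an
explicit `unmapped` list — nothing is dropped silently, because mapping
loss is itself a result (it changes node counts downstream).

The GO annotation store keeps *direct* annotations only. Ancestor
propagation over the GO graph is deliberately not modelled: enrichment
then tests exactly what the annotation input states, and a caller who wants
propagated annotations can materialise them upstream.

## Network construction

First-order construction: a record survives if it passes the score
predicate (records without a score fail an explicit `min_score` filter —
so score filtering is only meaningful for the scored dialect), both
endpoints match the taxonomy filter when one is set (the strict reading of
"human-only"), and at least one endpoint is a seed. The graph is simple and
undirected; self-loops are dropped; duplicate edges keep the maximum score
(scores are confidences — the best evidence prevails). Every seed is a
node even when none of its records survive: downstream, seeds isolated in
*every* network are reported as a cross-network finding, which is only
expressible if isolation is preserved here.

Dialects: the BioGRID-like tab format carries per-record organism columns
and no score; the STRING-links format carries integer 0–1000 combined
scores (rescaled by /1000; the 90% confidence level is ≥ 0.9) and a
file-level organism. First-neighbour expansion is the chosen semantics
because sub-100-gene seed lists produce thousand-node networks only when
direct interactors are included.

## Graph algebra and statistics

Intersection is node-AND-edge (the merge semantics of common network
tools); union takes node and edge unions with max-score conflict
resolution. The difference ("unique") network subtracts the reference's
*node set* and keeps the induced subgraph — deliberately node-wise, since
subtype-unique biology is framed in terms of unique nodes.

Statistics conventions: the mean local clustering coefficient includes
degree<2 nodes as zeros (the common network-analyzer convention; a flag
excludes them), the diameter of a disconnected graph is the maximum over
components (0 for an edgeless graph), and isolated nodes are degree-0
nodes. Hub ranking is by degree descending with lexicographic id
tie-break — deterministic, byte-stable across runs.

## Cohesiveness clustering

The cluster score is `f(V) = w_in / (w_in + w_bound + p·|V|)` with `w_in`
the total weight inside `V`, `w_bound` the weight crossing the boundary and
`p` a per-member penalty (default 2) modelling unobserved interactions.
Edge weights are confidence scores where present, 1 otherwise, so the
unscored dialect clusters on edge counts. Growth is a deterministic greedy
local search from a singleton seed: the single addition of a boundary
vertex or removal of a member with the largest strict increase in `f` is
applied until no move helps (ties: additions before removals, then lowest
id). Seeds are processed in decreasing degree order, skipping nodes
already covered by a grown candidate. Candidates with pairwise overlap
`ω(A,B) = |A∩B|²/(|A|·|B|)` above 0.8 are union-merged to a fixpoint;
survivors need ≥ 3 members and density ≥ 0.5. Roles: a node in exactly one
accepted cluster is `cluster`, in several `overlap`, in none `outlier`.

Two consequences worth knowing. On noise-free planted graphs (disjoint
cliques plus isolated nodes) the procedure recovers each clique exactly
for p = 2. In unweighted graphs, however, a degree-1 noise pendant
attached to a clique *increases* `f` whenever the cluster has any boundary
weight, so pendants are absorbed; enough of them can push a candidate
below the density filter. Score-weighted networks suppress this because
noise edges carry low weight. This is inherent to the objective, not a
defect of the search.

## Enrichment

Per term the p-value is the upper hypergeometric tail
`P(X ≥ k)` for `X ~ Hypergeom(N, K, n)` — only over-representation is
tested. q-values are Benjamini–Hochberg over all tested terms (terms with
no annotated background gene are skipped). The default background for
pipeline runs is every gene of the relevant database input plus all seeds,
mapped to Ensembl gene space; a caller can substitute the whole annotation
table. Output ordering is p ascending with accession tie-break, so tables
are byte-reproducible.

## Synthetic universe

The generator emulates the *shapes* of the real inputs, at desk scale
(400 genes, 3 conditions by default), with planted truth:

* **Expression** — log-normal FPKM: background `lognormal(−1.0, 0.6)`
  (practically never above the cutoff of 3), over-expressed genes
  `lognormal(3.0, 0.6)` (≥ 99% above it; the contract demands ≥ 95%).
  Each condition over-expresses 30 shared genes plus 12 of its own.
* **Planted structure** — among the shared genes: three clique complexes
  (sizes 5, 5, 6) with confidence scores ≥ 0.9; ten hubs wired to 30
  background partners each (scores ≥ 0.9); three seeds that appear in *no*
  interaction record of either dialect. Every other seed receives two
  high-confidence anchor interactions so that the planted trio are the
  only seeds isolated everywhere. Noise edges appear with per-pair
  probability 0.004 and Beta(2, 6) scores (mostly < 0.9); 5% of them carry
  a mouse taxon (10090) to exercise taxonomy filtering.
* **Annotations** — a "cell population proliferation" term on every seed
  (the keyword filter's target) plus 5% of background genes; a planted
  enriched term on 90% of disease-unique genes and 5% of the rest; four
  generic filler terms on random 10% slices.
* **Identifier maps** — the primary map lacks the Ensembl gene id for 20%
  of genes; a secondary map closes the gap except for exactly one
  background gene, which remains unmappable anywhere (the realistic
  "no Ensembl id at all" case). The DEG table is symbol-keyed so that the
  unmappable gene is reachable from real inputs.
* **Dialects** — both interaction files serialise the *same* underlying
  planted interactome (entrez/symbol identifiers and taxon columns in the
  BioGRID-like file; Ensembl protein identifiers and integer scores in the
  STRING-like file). Database-snapshot divergence is deliberately not
  emulated: recovery scoring needs a common ground truth, and snapshot
  drift is exactly the quantity the original tables cannot pin down.

All draws come from one seeded NumPy generator; outputs are byte-identical
under a fixed seed.

What passing recovery tests on this universe shows: the pipeline's
filtering, mapping, construction, algebra, clustering and enrichment
machinery compose correctly and recover planted structure through both
dialects. What it does not show: performance on real interactomes' degree
distributions, annotation bias, or symbol-spelling chaos beyond simple
case drift.

## Recovery scoring

`score_recovery` translates every network into Ensembl gene space with the
pipeline's merged map (unmapped identifiers count against recovery) and
reports: best-match Jaccard per planted complex and network; the fraction
of planted hubs inside each network's top-10; whether the set of nodes
isolated in every network of a database equals the planted trio exactly;
difference-network purity — the fraction of unique-network nodes that are
truth-unique genes or neighbours of one in the parent disease network
(their exclusivity is already established by surviving the intersection
subtraction); and the rank of the planted enriched term in each unique
network's enrichment. The rank is computed among terms *excluding* the
keyword-filter term: every seed carries that term by construction of seed
selection, so its enrichment reflects selection bias, not discovered
signal — masking the selection term is the standard correction.

## Numerical and determinism choices

Hypergeometric tails come from `scipy.stats.hypergeom.sf` (log-space
stable); the unit suite cross-checks exhaustive enumeration for all urns
with N ≤ 12. Network statistics are cross-checked against python-igraph.
Everywhere an order matters — node insertion, seed processing, cluster
indexing, report rows — sorting makes it deterministic, and a complete run
from a fixed generator seed reproduces artifacts byte-for-byte (manifest
timestamps aside).

## Known limitations

* No GO-graph propagation, no depletion tests, no GSEA-style rank tests.
* No directed or signed interactions, no PSI-MI XML, no live database
  clients; Cytoscape-style layout/visualisation is out of scope (GraphML
  and SIF exports serve external viewers).
* Centralities beyond degree are not computed; hubs are degree hubs.
* The clustering is a faithful-in-spirit re-implementation of greedy
  cohesiveness maximisation, not a bit-exact clone of any particular app;
  with unweighted inputs it inherits the pendant-absorption behaviour
  described above.
* Problem sizes in tests and the acceptance script (hundreds of genes,
  thousands of edges) are chosen so the full suite runs in well under half
  an hour on one CPU; the algorithms themselves have no such limits.
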