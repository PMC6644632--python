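# Methods

## Statistical model

Enrichment of a query gene list in a term is tested with the one-sided
hypergeometric (equivalently, one-sided Fisher) test.  With a universe of
`N` assayed genes, a term covering `K` of them and a query of `n` genes, the
observed overlap `k` is referred to the upper tail of
`Hypergeom(N, K, n)`; `k = 0` returns exactly 1.  Only over-representation
is tested: depletion of a term in a gene list is rarely an interpretable
annotation signal and no depletion analysis is exposed.

Three choices fully determine the test, and all three are explicit, logged
inputs rather than hidden defaults:

* **Universe** (`resolve_universe`): `resource_union` (default policy — the
  union of all genes annotated by the selected resources), `user_list` (an
  explicit assayed-gene list, e.g. all genes expressed in the tissue), or
  `query_union`.  Query genes outside the universe are dropped with a
  warning, never silently counted; the chosen mode is recorded in run
  provenance.
* **Term-size filter**: terms are intersected with the universe before
  sizing; terms with fewer than 5 or more than 500 universe genes are
  excluded by default (conventional ORA bounds — very small terms cannot
  reach useful significance, very large ones are uninformative) and every
  exclusion is tallied in a skip report.
* **Pooling scope**: all terms from all selected resources are corrected
  together per query (Benjamini–Hochberg step-up; Bonferroni available as a
  hook).  A `global` mode pools across queries x terms for multi-list
  heatmaps.  Per-query pooling is the default because each gene list is an
  independent analysis; the pool is what "adding one more resource" should
  widen.

### A note on pooled BH q-values

BH q-values are not pointwise monotone in the pool size as a mathematical
fact: if the added resource's p-values cluster below a term's p-value, the
term's rank can improve faster than the pool grows and its q-value can
*decrease*.  In the sparse-overlap regime of realistic enrichment analyses
(universes of thousands of genes, queries of tens, most term overlaps zero)
the monotone "pooling can only be more conservative" behaviour holds
replicate-for-replicate, and the acceptance suite asserts it under exactly
those conditions; the pathological direction requires query densities far
above anything a background-corrected analysis produces.

### Discreteness and null calibration

The hypergeometric statistic is discrete, so the attainable test level is
below any nominal `alpha`: at universe 2,000, term size 50, query size 30,
the largest achievable level at or below 0.05 is `P(X >= 3) ~ 0.037`.  The
null-calibration check therefore compares the empirical `p <= 0.05` rate
against binomial bounds around this *exact attainable* level (computed from
the discrete null), plus a one-sided guarantee that the rate never exceeds
the nominal 0.05.  Centering the band on the nominal level would reject any
correct implementation of a discrete test.

## Reporting

Heatmap cells are `min(-log10 q, cap)` with `cap = 10` by default; `q = 0`
maps to the cap.  Rows are terms significant at `q <= 0.05` (default) in at
least one query, ordered by best q with lexicographic tie-breaks so output
is byte-deterministic.  Figures always ship with a numeric TSV twin; no
number exists only in a picture.  The colour scale is linear from 0 to the
cap; the colormap is cosmetic and configurable.

## Resource overlap and reduction

Overlap between two terms is the fraction of shared genes.  The default
metric is the overlap coefficient `|A∩B| / min(|A|,|B|)` — a subset counts
as 100% shared, which matches how one-to-one mappings between a fine-grained
and a coarse-grained resource behave; Jaccard and the asymmetric directional
fraction `|A∩B| / |A|` are selectable, and pairwise operations under the
directional metric take the larger direction so "either containment"
qualifies.  Overlaps are computed on raw term gene sets, not
universe-intersected ones: similarity between resources is a property of
the resources, not of any particular experiment.

The overlap graph evaluates every unordered term pair (optionally only
cross-resource pairs), never compares a term to itself, and displays only
terms incident to at least one passing edge.

Reduction is a **greedy** pass, not optimal set selection: terms are visited
largest-first (ties by resource name then term name, so the outcome is
independent of input order) and a term is dropped the moment it overlaps an
already-kept term at or above the threshold, recording the absorber.  The
kept set provably contains no pair at or above the threshold — the
brute-force check is part of the test suite — and the visit order is stated
in the report so any reduction is auditable.  Raising the threshold never
decreases the kept count.

## Networks and expansion

Edge lists and SIF files merge into one undirected graph.  Per-edge
provenance keeps every contributing source; the stored score is the maximum
across sources (scores are reliabilities, and the best evidence for an edge
is what filtering should act on).  Confidence filtering keeps edges with
`score >= min_score`; unscored edges are kept by default (dropping them is a
flag) because many curated resources publish no scores.  Self-loops are
stored but excluded from degree and neighbor logic — "number of
interactions" as a centrality reads as distinct partners.

Neighbor expansion is multi-source BFS to a hop budget, then the induced
subgraph on seeds plus added genes.  Connector expansion considers every
seed pair lacking a direct edge and admits all non-seed interior nodes of
all tied shortest paths between them, provided the path has at most
`max_intermediates` interior nodes (default 1 — common-neighbor
connectors).  Admitting *all* tied paths makes the result deterministic and
traversal-order independent.  "Efficiently connecting" genes is not a
standard term; the shortest-path-with-budget reading is this package's
definition, named in the result's `method` field so exports are
self-describing.  An optional weighted mode uses `-log(score)` edge costs
(multiplicative reliabilities); exact Steiner trees and diffusion scoring
are out of scope.

## Synthetic data

The fixture generator stands in for licensed resources that cannot be
redistributed.  Its key property is that planted structure is **constructed,
not sampled**: a planted overlap pair is built by allocating exactly
`fraction * min(size_a, size_b)` shared genes (an error, naming the nearest
feasible fraction, if that is not an integer), every other pair is exactly
disjoint, and a term may take part in at most one planted pair so the truth
table is exact.  Planted enrichment draws `effect * n_query` query genes
from the target term and the rest from the universe excluding it.  All
randomness flows through one seeded generator; a seed reproduces every
emitted byte.

Default study conditions — 2,000-gene universe, 50-gene terms, 30-gene
queries, effect 0.8, 200 replicates for power and calibration runs — are
the regime of a typical transcriptomics gene list against a mid-sized
annotation resource.  The generator does **not** emulate heavy-tailed term
sizes, ontology DAG structure, inter-term correlation of real resources, or
gene-symbol aliasing; passing tests demonstrate the mechanics are correct
under known truth, not that any particular real resource behaves this way.

## Numerical and I/O choices

* Tail probabilities come from `scipy.stats.hypergeom.sf`; the test suite
  checks them against exact big-integer enumeration (relative tolerance
  1e-12 up to universes of 60) and against one-sided Fisher.
* BH is the standard step-up with cumulative-minimum monotone enforcement,
  output aligned to input order; it is cross-checked against an independent
  re-implementation and against statsmodels.
* Gene identifiers are opaque, case-sensitive strings (an uppercase
  normalisation flag exists, off by default); namespace mapping
  (Entrez/symbol/Ensembl) is the caller's responsibility.
* GMT: field 2 is always a description; a strict flag rejects lines whose
  description duplicates a member gene.  Written GMT sorts gene columns, so
  serialisation is byte-stable and round-trips exactly.
* Edge-list parsing: with no declared score column, a numeric third column
  is a score and a non-numeric middle column triggers SIF (`gene relation
  gene`) interpretation — this disambiguates `A B 0.9` from `A pp B`
  without flags.  SIF export writes each unordered edge once, smaller
  symbol first, with a companion edge-attribute TSV carrying scores and
  sources past SIF's three-column limit.
* Pipeline runs always write a provenance JSON (versions, SHA-256 of every
  input, all thresholds, counts at every filter step); deterministic stages
  re-run bit-identically from a saved config.

## Known limitations

Only the hypergeometric ORA statistic is implemented (no ranked/GSEA-style
or topology-aware testing); reduction is greedy, not optimal; semantic
(ontology-graph) term similarity is out of scope; statistical significance
of network overlaps is not assessed.  P-values from annotation are
descriptive: iterating between discovery and annotation invites overfitting
and is deliberately unsupported.
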