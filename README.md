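# termnet

Gene-centric knowledge integration for interpreting gene lists from
high-throughput experiments.  `termnet` pools over-representation analysis
across multiple geneset resources under a **single** false-discovery
correction, quantifies and reduces redundancy between resources, and expands
query gene lists through merged interaction networks — exporting results in
formats that downstream tools (Cytoscape, spreadsheets) consume directly.

## Who it is for

Anyone holding a list of prioritized genes — differentially expressed,
mutated, co-methylated — who wants to know which functions, pathways or
disease modules the list is enriched for, across *several* annotation
resources at once, without the multiple-testing bookkeeping falling through
the cracks, and which un-listed genes tie the list together in interaction
networks.

## The statistics

**Enrichment.**  For a query of $n$ genes drawn from a background universe of
$N$ assayed genes and a term annotating $K$ universe genes, the overlap under
the null is $X \sim \mathrm{Hypergeom}(N, K, n)$ and the one-sided
over-representation p-value at observed overlap $k$ is

$$p = P(X \ge k) \;=\; \sum_{i=k}^{\min(K,n)} \frac{\binom{K}{i}\binom{N-K}{n-i}}{\binom{N}{n}}.$$

All terms from all selected resources enter **one** p-value pool and one
Benjamini–Hochberg step-up correction is applied across the pool ("include
one more resource" widens the correction instead of spawning an uncorrected
parallel analysis).  Heatmaps report $\min(-\log_{10} q,\ 10)$.

**Redundancy.**  Resource similarity is measured as the fraction of shared
genes; the default metric is the overlap coefficient
$|A \cap B| / \min(|A|, |B|)$ (a subset scores 100%), with Jaccard and
directional fractions selectable.  Thresholded overlap graphs expose the
structure; a greedy largest-first pass reduces a union of resources to a
subset in which no kept pair overlaps at or above the threshold.

**Networks.**  Interaction resources merge into one undirected graph with
per-edge provenance (max confidence score, contributing sources).  Query
lists expand either by all neighbors within $k$ hops, or by *connector*
genes — non-seed genes on shortest paths (at most a budgeted number of
intermediates) between seed pairs, surfacing hubs that interact with the
hits without being hits themselves.

## Worked example

Generate a synthetic two-resource workspace with a planted signal and run
the pooled analysis (the `termnet.synthetic` module builds resources whose
overlaps and enrichment are known by construction):

```python
from termnet.synthetic import (FixtureSpec, PlantedOverlap, gene_symbols,
                               make_geneset_fixture, make_query_fixture)
from termnet.resources import write_gmt

spec = FixtureSpec(n_terms=(12, 8), term_size_range=(20, 40), universe_size=2000,
                   planted_overlaps=[PlantedOverlap((0, 0), (1, 0), 1.0)], seed=7)
(go_like, pathways), _ = make_geneset_fixture(spec)
write_gmt(go_like, "go_like.gmt"); write_gmt(pathways, "pathways.gmt")
universe = gene_symbols(2000)
open("universe.txt", "w").write("\n".join(universe) + "\n")
query, _ = make_query_fixture(go_like, ["resource1_T003"], effect=0.8,
                              n_query=30, seed=1, universe=universe)
open("degs.txt", "w").write("\n".join(sorted(query)) + "\n")
```

```sh
termnet enrich --gmt go_like.gmt --gmt pathways.gmt \
               --genes degs.txt --universe universe.txt --out enrichment.tsv
```

```
[enrich] 1 quer(ies), 20 pooled terms, universe 2000
[enrich] wrote enrichment.tsv
```

Top of `enrichment.tsv` (sorted by q):

```
          term resource  n_overlap  n_term            p            q  neg_log10_q_capped
resource1_T003  go_like         24      34 3.211934e-42 6.423869e-41                10.0
resource1_T001  go_like          0      39 1.000000e+00 1.000000e+00                 0.0
```

The planted term is recovered: 24 of the 30 query genes fall in its 34
universe genes, the hypergeometric tail is ~3e-42, and the BH q-value —
corrected across all 20 pooled terms from *both* resources — stays
decisive.  Its capped heatmap score is 10.0 (the display ceiling); null
terms sit at p = q = 1, score 0.0.

Other subcommands: `termnet overlap` (thresholded term-overlap graph TSV),
`termnet reduce` (minimally redundant merged GMT), `termnet expand`
(neighbor/connector subnetwork as SIF + node attributes), `termnet run`
(YAML-config pipeline with provenance JSON).  Everything is equally usable
as a library (`import termnet`).

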