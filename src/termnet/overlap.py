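"""Quantitative overlap between terms within and across geneset resources.

Curated resources are highly redundant: the same biological process is often
annotated as a GO term, a pathway, and several disease genesets with nearly
identical membership.  Testing all of them inflates the multiple-testing
burden without adding information, making pooled false-discovery adjustment
overly conservative.  This module measures that redundancy — the fraction of
shared genes between term pairs — builds thresholded overlap graphs for
inspection, and greedily reduces a union of resources to a subset in which no
kept pair overlaps above a chosen threshold.

Overlap metrics (for gene sets ``a``, ``b``):

``min_denominator`` (default)
    Overlap coefficient ``|a ∩ b| / min(|a|, |b|)`` — a subset scores 1.0,
    matching the "100% of genes shared" reading of one-to-one term mappings.
``jaccard``
    ``|a ∩ b| / |a ∪ b|``.
``directional``
    ``|a ∩ b| / |a|`` — asymmetric; pairwise operations evaluate both
    directions and an edge qualifies if either direction passes.

Overlaps are computed on raw term gene sets, not universe-intersected ones:
resource similarity is a property of the resources themselves, independent of
any particular experiment's background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence, Union

import networkx as nx
import pandas as pd

from .resources import GeneSet, GeneSetResource

__all__ = [
    "Metric",
    "overlap_fraction",
    "TermOverlapGraph",
    "overlap_graph",
    "cross_resource_mapping",
    "ReductionReport",
    "reduce_redundancy",
    "overlap_table",
]

Metric = Literal["min_denominator", "jaccard", "directional"]


def _genes(x: Union[GeneSet, Iterable[str]]) -> frozenset[str]:
    return x.genes if isinstance(x, GeneSet) else frozenset(x)


def overlap_fraction(
    a: Union[GeneSet, Iterable[str]],
    b: Union[GeneSet, Iterable[str]],
    metric: Metric = "min_denominator",
) -> float:
    """Fraction of shared genes between two sets under the chosen metric.

    ``directional`` is ``|a ∩ b| / |a|`` (asymmetric: swap arguments for the
    other direction).  Empty sets are a domain error.
    """
    ga, gb = _genes(a), _genes(b)
    if not ga or not gb:
        raise ValueError("overlap_fraction requires non-empty gene sets")
    shared = len(ga & gb)
    if metric == "min_denominator":
        return shared / min(len(ga), len(gb))
    if metric == "jaccard":
        return shared / len(ga | gb)
    if metric == "directional":
        return shared / len(ga)
    raise ValueError(f"unknown metric {metric!r}")


def _pair_fraction(a: GeneSet, b: GeneSet, metric: Metric) -> float:
    """Symmetric per-pair fraction; for the directional metric this is the
    maximum over both directions (either containment direction qualifies)."""
    if metric == "directional":
        return max(
            overlap_fraction(a, b, "directional"), overlap_fraction(b, a, "directional")
        )
    return overlap_fraction(a, b, metric)


@dataclass
class TermOverlapGraph:
    """Thresholded term-overlap graph: terms as nodes, edges weighted by
    shared-gene fraction.

    Self-comparison is excluded; only terms incident to at least one edge at
    or above the construction threshold appear as nodes.  Backed by an
    undirected :class:`networkx.Graph` whose nodes are ``(resource, name)``
    pairs with ``size`` attributes and whose edges carry ``fraction`` and
    ``shared`` counts.
    """

    graph: nx.Graph
    threshold: float
    metric: Metric

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_set(self) -> set[frozenset[tuple[str, str]]]:
        return {frozenset((u, v)) for u, v in self.graph.edges}


def _all_terms(resources: Sequence[GeneSetResource]) -> list[GeneSet]:
    return [gs for res in resources for gs in res]


def overlap_graph(
    resources: Sequence[GeneSetResource],
    threshold: float,
    metric: Metric = "min_denominator",
    cross_only: bool = False,
) -> TermOverlapGraph:
    """Evaluate all unordered term pairs and keep those with overlap fraction
    at or above ``threshold``.

    ``cross_only=True`` restricts the comparison to pairs drawn from
    different resources (the between-resource mode); by default both
    within- and between-resource pairs are evaluated, always ignoring
    self-overlap.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0, 1]")
    if not resources:
        raise ValueError("at least one resource is required")
    terms = _all_terms(resources)
    g = nx.Graph()
    for i in range(len(terms)):
        for j in range(i + 1, len(terms)):
            a, b = terms[i], terms[j]
            if cross_only and a.resource == b.resource:
                continue
            frac = _pair_fraction(a, b, metric)
            if frac >= threshold:
                for t in (a, b):
                    g.add_node(t.key, size=t.size)
                g.add_edge(a.key, b.key, fraction=frac, shared=len(a.genes & b.genes))
    return TermOverlapGraph(graph=g, threshold=threshold, metric=metric)


def cross_resource_mapping(
    r1: GeneSetResource,
    r2: GeneSetResource,
    threshold: float,
    metric: Metric = "min_denominator",
) -> tuple[list[tuple[str, str, float]], dict[str, int]]:
    """All cross-resource term pairs with overlap >= ``threshold``, plus
    summary counts of distinct mapped terms on each side.

    Mappings may be many-to-many; the summary reports how many distinct
    terms of each resource participate in at least one passing pair.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0, 1]")
    pairs: list[tuple[str, str, float]] = []
    for a in r1:
        for b in r2:
            frac = _pair_fraction(a, b, metric)
            if frac >= threshold:
                pairs.append((a.name, b.name, frac))
    summary = {
        "n_pairs": len(pairs),
        "n_terms_r1": len({p[0] for p in pairs}),
        "n_terms_r2": len({p[1] for p in pairs}),
    }
    return pairs, summary


@dataclass
class ReductionReport:
    """Outcome of greedy redundancy reduction.

    ``kept`` and the absorbed terms in ``dropped`` partition the input;
    no pair within ``kept`` overlaps at or above ``threshold``.
    """

    kept: list[GeneSet]
    dropped: list[tuple[GeneSet, GeneSet, float]]  # (term, absorbed_by, fraction)
    threshold: float
    metric: Metric
    priority: str

    @property
    def n_kept(self) -> int:
        return len(self.kept)

    @property
    def n_dropped(self) -> int:
        return len(self.dropped)

    def to_resource(self, name: str = "reduced") -> GeneSetResource:
        """Kept terms as a single resource; name collisions across source
        resources are disambiguated with a ``resource:`` prefix."""
        names = [gs.name for gs in self.kept]
        dup = {n for n in names if names.count(n) > 1}
        sets = [
            GeneSet(
                f"{gs.resource}:{gs.name}" if gs.name in dup else gs.name,
                gs.description,
                gs.genes,
                resource=name,
            )
            for gs in self.kept
        ]
        return GeneSetResource(name, sets)


def reduce_redundancy(
    resources: Sequence[GeneSetResource],
    threshold: float,
    metric: Metric = "min_denominator",
    priority: Literal["larger_first", "resource_order"] = "larger_first",
) -> ReductionReport:
    """Greedily select a minimally redundant subset of all terms.

    Terms are visited in priority order — ``larger_first``: descending gene
    count, ties broken by resource name then term name, so the outcome does
    not depend on the order resources were supplied in; ``resource_order``:
    file order within resource, resources in the given order.  A term is
    dropped when its overlap with any
    already-kept term reaches ``threshold``, and the report records which
    kept term absorbed it.  Greedy rather than optimal set selection: the
    visit order is stated in the report so results are auditable.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    terms = _all_terms(resources)
    if priority == "larger_first":
        terms = sorted(terms, key=lambda t: (-t.size, t.resource, t.name))
    elif priority != "resource_order":
        raise ValueError(f"unknown priority {priority!r}")
    kept: list[GeneSet] = []
    dropped: list[tuple[GeneSet, GeneSet, float]] = []
    for t in terms:
        absorbed_by = None
        best = 0.0
        for k in kept:
            frac = _pair_fraction(t, k, metric)
            if frac >= threshold and frac > best:
                absorbed_by, best = k, frac
        if absorbed_by is None:
            kept.append(t)
        else:
            dropped.append((t, absorbed_by, best))
    return ReductionReport(
        kept=kept, dropped=dropped, threshold=threshold, metric=metric, priority=priority
    )


def overlap_table(g: TermOverlapGraph) -> pd.DataFrame:
    """Overlap-graph edges as the exportable TSV schema (Cytoscape-ready)."""
    rows = []
    for (r1, t1), (r2, t2), data in g.graph.edges(data=True):
        rows.append(
            {
                "term1": t1,
                "resource1": r1,
                "size1": g.graph.nodes[(r1, t1)]["size"],
                "term2": t2,
                "resource2": r2,
                "size2": g.graph.nodes[(r2, t2)]["size"],
                "shared": data["shared"],
                "fraction": data["fraction"],
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "term1",
            "resource1",
            "size1",
            "term2",
            "resource2",
            "size2",
            "shared",
            "fraction",
        ],
    )
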