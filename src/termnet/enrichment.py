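"""Pooled over-representation analysis across multiple geneset resources.

The statistical model is the one-sided hypergeometric (Fisher) test: given a
background universe of ``N`` assayed genes, a term annotating ``K`` of them
and a query list of ``n`` genes, the number of query genes inside the term
under the null of random draws is ``X ~ Hypergeometric(N, K, n)`` and the
over-representation p-value is the upper tail ``P(X >= k)`` at the observed
overlap ``k``.

The distinguishing feature of this module is *pooling*: all terms from every
selected resource are tested together and a single false-discovery correction
(Benjamini–Hochberg by default) is applied over the pooled p-value vector, so
adding a resource to a query widens the correction instead of spawning an
uncorrected parallel analysis.  Per-query pooling is the default; a global
mode pools across queries x terms for multi-list heatmaps.

Three quantities fully determine each test and are stored on every result so
that any reported p-value can be recomputed from its own row: the overlap
count, the term size within the universe, the query size, and the universe
size.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .resources import GeneSet, GeneSetResource

__all__ = [
    "EnrichmentQuery",
    "EnrichmentResult",
    "EnrichmentMatrix",
    "hypergeom_p",
    "bh_adjust",
    "bonferroni_adjust",
    "term_enrichment",
    "enrichment_matrix",
    "resolve_universe",
    "neg_log10_capped",
    "results_table",
    "DEFAULT_MIN_TERM_SIZE",
    "DEFAULT_MAX_TERM_SIZE",
    "DEFAULT_CAP",
    "DEFAULT_Q_THRESHOLD",
]

DEFAULT_MIN_TERM_SIZE = 5
DEFAULT_MAX_TERM_SIZE = 500
DEFAULT_CAP = 10.0
DEFAULT_Q_THRESHOLD = 0.05


@dataclass(frozen=True)
class EnrichmentQuery:
    """A named query gene list together with its background universe.

    ``genes`` must be a subset of ``universe``; use :meth:`from_genes` to
    apply the mandatory intersection step (genes absent from the universe are
    dropped with a warning, never silently counted).
    """

    name: str
    genes: frozenset[str]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        if not isinstance(self.genes, frozenset):
            object.__setattr__(self, "genes", frozenset(self.genes))
        if not isinstance(self.universe, frozenset):
            object.__setattr__(self, "universe", frozenset(self.universe))
        if not self.genes:
            raise ValueError(f"query {self.name!r} is empty after universe intersection")
        if not self.genes <= self.universe:
            raise ValueError(
                f"query {self.name!r} contains genes outside the universe; "
                "use EnrichmentQuery.from_genes to intersect first"
            )

    @classmethod
    def from_genes(
        cls, name: str, genes: Iterable[str], universe: Iterable[str]
    ) -> "EnrichmentQuery":
        genes = frozenset(genes)
        universe = frozenset(universe)
        kept = genes & universe
        dropped = genes - universe
        if dropped:
            warnings.warn(
                f"query {name!r}: {len(dropped)} gene(s) absent from universe "
                f"dropped: {', '.join(sorted(dropped)[:10])}"
                + ("..." if len(dropped) > 10 else ""),
                stacklevel=2,
            )
        if not kept:
            raise ValueError(f"query {name!r} has no genes in the universe")
        return cls(name, kept, universe)


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-term test result; the four counts reproduce ``p_value`` exactly."""

    term: str
    resource: str
    query: str
    n_overlap: int
    n_term_in_universe: int
    n_query: int
    n_universe: int
    overlap_genes: tuple[str, ...]
    p_value: float
    q_value: float = math.nan
    neg_log10_q_capped: float = math.nan


def hypergeom_p(n_overlap: int, n_term: int, n_query: int, n_universe: int) -> float:
    """Upper-tail hypergeometric p-value ``P(X >= n_overlap)``.

    ``X ~ Hypergeometric(N=n_universe, K=n_term, n=n_query)`` — the overlap
    between a random ``n_query``-subset of the universe and a fixed term of
    ``n_term`` universe genes.  Returns exactly 1.0 at zero overlap.
    """
    for label, v in (
        ("n_overlap", n_overlap),
        ("n_term", n_term),
        ("n_query", n_query),
        ("n_universe", n_universe),
    ):
        if int(v) != v or v < 0:
            raise ValueError(f"{label} must be a non-negative integer, got {v!r}")
    if n_universe < 1:
        raise ValueError("n_universe must be >= 1")
    if n_term > n_universe or n_query > n_universe:
        raise ValueError("term and query sizes cannot exceed the universe size")
    if n_overlap > min(n_term, n_query):
        raise ValueError("n_overlap cannot exceed min(n_term, n_query)")
    if n_overlap == 0:
        return 1.0
    # sf(k-1) = P(X >= k)
    return float(stats.hypergeom.sf(n_overlap - 1, n_universe, n_term, n_query))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in the input order.

    Standard procedure: sort ascending, scale p_(i) by m/i, enforce
    monotonicity by a cumulative minimum from the largest rank down, clip to
    1, unsort.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def bonferroni_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Bonferroni adjustment (alternative FDR-hook; controls FWER)."""
    p = np.asarray(p_values, dtype=float)
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(p * p.size, 1.0)


_ADJUSTERS = {"bh": bh_adjust, "bonferroni": bonferroni_adjust}


def neg_log10_capped(q: float, cap: float = DEFAULT_CAP) -> float:
    """``min(-log10(q), cap)``; q = 0 maps to the cap."""
    if q < 0 or q > 1:
        raise ValueError("q must lie in [0, 1]")
    if q == 0.0:
        return float(cap)
    return max(0.0, float(min(-math.log10(q), cap)))


@dataclass
class SkipReport:
    """Terms excluded by the size filter, counted per reason."""

    too_small: int = 0
    too_large: int = 0
    min_term_size: int = DEFAULT_MIN_TERM_SIZE
    max_term_size: int = DEFAULT_MAX_TERM_SIZE
    skipped_terms: list[tuple[str, str, int]] = field(default_factory=list)

    @property
    def total(self) -> int:
        return self.too_small + self.too_large


def _tested_terms(
    resources: Sequence[GeneSetResource],
    universe: frozenset[str],
    min_term_size: int,
    max_term_size: int,
) -> tuple[list[tuple[GeneSet, frozenset[str]]], SkipReport]:
    """Intersect every term with the universe and apply the size filter."""
    skip = SkipReport(min_term_size=min_term_size, max_term_size=max_term_size)
    kept: list[tuple[GeneSet, frozenset[str]]] = []
    for res in resources:
        for gs in res:
            in_univ = gs.genes & universe
            if len(in_univ) < min_term_size:
                skip.too_small += 1
                skip.skipped_terms.append((res.name, gs.name, len(in_univ)))
            elif len(in_univ) > max_term_size:
                skip.too_large += 1
                skip.skipped_terms.append((res.name, gs.name, len(in_univ)))
            else:
                kept.append((gs, in_univ))
    return kept, skip


def term_enrichment(
    query: EnrichmentQuery,
    resources: Sequence[GeneSetResource],
    min_term_size: int = DEFAULT_MIN_TERM_SIZE,
    max_term_size: int = DEFAULT_MAX_TERM_SIZE,
    method: Literal["bh", "bonferroni"] = "bh",
    cap: float = DEFAULT_CAP,
) -> tuple[list[EnrichmentResult], SkipReport]:
    """Test one query against the pooled terms of all given resources.

    Every term from every resource enters a single p-value pool and one
    multiple-testing correction is applied across the pool, so false
    discovery is controlled over everything tested, not per resource.

    Term gene sets are intersected with the query's universe before sizing
    and testing; terms falling outside ``[min_term_size, max_term_size]``
    after intersection are excluded and tallied in the returned
    :class:`SkipReport`.
    """
    if not resources:
        raise ValueError("at least one resource is required")
    terms, skip = _tested_terms(resources, query.universe, min_term_size, max_term_size)
    if not terms:
        raise ValueError(
            f"all {skip.total} terms filtered out by size bounds "
            f"[{min_term_size}, {max_term_size}] after universe intersection"
        )
    n_universe = len(query.universe)
    n_query = len(query.genes)
    results: list[EnrichmentResult] = []
    pvals: list[float] = []
    for gs, in_univ in terms:
        overlap = in_univ & query.genes
        p = hypergeom_p(len(overlap), len(in_univ), n_query, n_universe)
        pvals.append(p)
        results.append(
            EnrichmentResult(
                term=gs.name,
                resource=gs.resource,
                query=query.name,
                n_overlap=len(overlap),
                n_term_in_universe=len(in_univ),
                n_query=n_query,
                n_universe=n_universe,
                overlap_genes=tuple(sorted(overlap)),
                p_value=p,
            )
        )
    qvals = _ADJUSTERS[method](pvals)
    results = [
        EnrichmentResult(
            **{
                **r.__dict__,
                "q_value": float(qv),
                "neg_log10_q_capped": neg_log10_capped(float(qv), cap),
            }
        )
        for r, qv in zip(results, qvals)
    ]
    return results, skip


@dataclass
class EnrichmentMatrix:
    """Terms x queries matrix of capped ``-log10(q)`` values for heatmaps.

    ``values`` rows are term names ordered by best q (ties lexicographic),
    restricted to terms significant at ``q_threshold`` in at least one query.
    ``empty`` flags the no-significant-terms case — a warning object, not an
    error.
    """

    values: pd.DataFrame
    q_values: pd.DataFrame
    design: Optional[pd.DataFrame] = None
    cap: float = DEFAULT_CAP
    q_threshold: float = DEFAULT_Q_THRESHOLD
    term_resources: dict[str, str] = field(default_factory=dict)

    @property
    def empty(self) -> bool:
        return self.values.shape[0] == 0


def enrichment_matrix(
    queries: Sequence[EnrichmentQuery],
    resources: Sequence[GeneSetResource],
    cap: float = DEFAULT_CAP,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    pool: Literal["per_query", "global"] = "per_query",
    min_term_size: int = DEFAULT_MIN_TERM_SIZE,
    max_term_size: int = DEFAULT_MAX_TERM_SIZE,
    method: Literal["bh", "bonferroni"] = "bh",
    design: Optional[pd.DataFrame] = None,
) -> EnrichmentMatrix:
    """Build the heatmap matrix of capped ``-log10(q)`` for several queries.

    ``pool`` chooses the FDR scope: ``per_query`` corrects each query's
    pooled term vector separately (the default — resources combine, columns
    stay independent analyses); ``global`` applies one correction across the
    full queries x terms grid.
    """
    if not queries:
        raise ValueError("at least one query is required")
    per_query: dict[str, list[EnrichmentResult]] = {}
    for query in queries:
        results, _ = term_enrichment(
            query,
            resources,
            min_term_size=min_term_size,
            max_term_size=max_term_size,
            method=method,
            cap=cap,
        )
        per_query[query.name] = results
    if pool == "global":
        flat = [r for results in per_query.values() for r in results]
        qvals = _ADJUSTERS[method]([r.p_value for r in flat])
        it = iter(qvals)
        per_query = {
            name: [
                EnrichmentResult(
                    **{
                        **r.__dict__,
                        "q_value": float(next(it)),
                    }
                )
                for r in results
            ]
            for name, results in per_query.items()
        }
        per_query = {
            name: [
                EnrichmentResult(
                    **{
                        **r.__dict__,
                        "neg_log10_q_capped": neg_log10_capped(r.q_value, cap),
                    }
                )
                for r in results
            ]
            for name, results in per_query.items()
        }
    elif pool != "per_query":
        raise ValueError(f"unknown pooling scope {pool!r}")

    query_names = [q.name for q in queries]
    term_names = [r.term for r in next(iter(per_query.values()))]
    term_resources = {r.term: r.resource for r in next(iter(per_query.values()))}
    qmat = pd.DataFrame(
        {name: [r.q_value for r in per_query[name]] for name in query_names},
        index=term_names,
    )
    best_q = qmat.min(axis=1)
    keep = best_q[best_q <= q_threshold]
    ordered = keep.to_frame("q").reset_index(names="term")
    ordered = ordered.sort_values(["q", "term"], kind="stable")
    rows = ordered["term"].tolist()
    if not rows:
        warnings.warn("no term passes the q threshold; matrix is empty", stacklevel=2)
    vmat = qmat.loc[rows].map(lambda q: neg_log10_capped(q, cap))
    return EnrichmentMatrix(
        values=vmat,
        q_values=qmat.loc[rows],
        design=design,
        cap=cap,
        q_threshold=q_threshold,
        term_resources={t: term_resources[t] for t in rows},
    )


def resolve_universe(
    mode: Literal["resource_union", "user_list", "query_union"],
    resources: Sequence[GeneSetResource] = (),
    user_genes: Optional[Iterable[str]] = None,
    query_gene_lists: Sequence[Iterable[str]] = (),
) -> frozenset[str]:
    """Resolve the background gene universe — "the total number of genes that
    were assayed" — under one of three policies.

    ``resource_union`` (default policy): union of all genes across the
    selected resources.  ``user_list``: an explicit assayed-gene list, e.g.
    all protein-coding genes expressed in the tissue of interest.
    ``query_union``: union of the query lists themselves (a last-resort
    background that renders single-query tests powerless; provided for
    completeness).
    """
    if mode == "resource_union":
        out: set[str] = set()
        for res in resources:
            out |= res.universe
    elif mode == "user_list":
        if user_genes is None:
            raise ValueError("user_list mode requires user_genes")
        out = set(user_genes)
    elif mode == "query_union":
        out = set()
        for genes in query_gene_lists:
            out |= set(genes)
    else:
        raise ValueError(f"unknown universe mode {mode!r}")
    if not out:
        raise ValueError(f"universe resolved under mode {mode!r} is empty")
    return frozenset(out)


def results_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Flatten results to the exportable TSV schema."""
    return pd.DataFrame(
        [
            {
                "term": r.term,
                "resource": r.resource,
                "query": r.query,
                "n_overlap": r.n_overlap,
                "n_term": r.n_term_in_universe,
                "n_query": r.n_query,
                "n_universe": r.n_universe,
                "overlap_genes": ",".join(r.overlap_genes),
                "p": r.p_value,
                "q": r.q_value,
                "neg_log10_q_capped": r.neg_log10_q_capped,
            }
            for r in results
        ]
    )
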