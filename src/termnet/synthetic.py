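"""Synthetic geneset resources, networks and query lists with known truth.

Curated annotation resources generally cannot be redistributed, so the test
surface of this package is built on constructed stand-ins: resources whose
pairwise term overlaps are *planted exactly* (built by allocating shared
genes, not by sampling until a target is hit) and query lists whose
enrichment signal is controlled by a single ``effect`` parameter — the
fraction of the query drawn from the planted term(s).

All randomness flows through one :class:`numpy.random.Generator` seeded from
``FixtureSpec.seed``; a fixed seed reproduces every emitted file byte for
byte.  Truth tables (planted overlap fractions, planted query memberships)
accompany each fixture so tests can assert against construction rather than
re-deriving expectations.

What these fixtures deliberately do not emulate: the heavy-tailed term-size
distributions, ontology DAG structure and gene-multiplicity patterns of real
resources.  They exercise the *mechanics* (counting, pooling, thresholds,
graph traversal) under fully known conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .resources import EdgeRecord, GeneSet, GeneSetResource

__all__ = [
    "FixtureSpec",
    "PlantedOverlap",
    "make_geneset_fixture",
    "make_query_fixture",
    "make_network_fixture",
    "gene_symbols",
]


def gene_symbols(n: int, prefix: str = "G") -> list[str]:
    """Deterministic synthetic gene symbols G00001, G00002, ..."""
    width = max(5, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


@dataclass(frozen=True)
class PlantedOverlap:
    """A planted overlap between two terms, addressed as (resource index,
    term index) pairs, with a target overlap-coefficient fraction."""

    term_a: tuple[int, int]
    term_b: tuple[int, int]
    fraction: float


@dataclass
class FixtureSpec:
    """Blueprint for a family of synthetic geneset resources.

    ``n_terms`` holds one entry per resource.  Planted overlaps must be
    exactly representable: ``fraction * min(size_a, size_b)`` must be an
    integer (overlap-coefficient metric), and a term may take part in at
    most one planted pair so unplanted pairs stay exactly disjoint.
    """

    n_terms: Sequence[int] = (20,)
    term_size_range: tuple[int, int] = (10, 50)
    universe_size: int = 2000
    planted_overlaps: Sequence[PlantedOverlap] = ()
    seed: int = 0
    resource_prefix: str = "resource"


def _term_sizes(spec: FixtureSpec, rng: np.random.Generator) -> list[list[int]]:
    lo, hi = spec.term_size_range
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid term size range {spec.term_size_range}")
    return [
        [int(rng.integers(lo, hi + 1)) for _ in range(n)] for n in spec.n_terms
    ]


def make_geneset_fixture(
    spec: FixtureSpec,
) -> tuple[list[GeneSetResource], pd.DataFrame]:
    """Construct resources with exactly planted pairwise overlaps.

    Returns the resources plus a truth table with one row per planted pair
    (resource/term coordinates, sizes, shared count, achieved fraction).
    Terms not involved in a planted pair are built from fresh universe genes
    and are therefore pairwise disjoint.

    Raises ``ValueError`` when a planted fraction is not representable with
    an integer intersection, suggesting the nearest feasible value.
    """
    rng = np.random.default_rng(spec.seed)
    sizes = _term_sizes(spec, rng)
    seen: set[tuple[int, int]] = set()
    for po in spec.planted_overlaps:
        for coord in (po.term_a, po.term_b):
            r, t = coord
            if not (0 <= r < len(spec.n_terms)) or not (0 <= t < spec.n_terms[r]):
                raise ValueError(f"planted overlap references missing term {coord}")
            if coord in seen:
                raise ValueError(
                    f"term {coord} appears in more than one planted pair; "
                    "each term may be planted at most once"
                )
            seen.add(coord)
        if not (0.0 < po.fraction <= 1.0):
            raise ValueError(f"planted fraction must lie in (0, 1], got {po.fraction}")

    # validate representability before allocating anything
    shared_counts: dict[tuple[tuple[int, int], tuple[int, int]], int] = {}
    for po in spec.planted_overlaps:
        sa = sizes[po.term_a[0]][po.term_a[1]]
        sb = sizes[po.term_b[0]][po.term_b[1]]
        target = po.fraction * min(sa, sb)
        shared = round(target)
        if abs(target - shared) > 1e-9:
            feasible = shared / min(sa, sb)
            raise ValueError(
                f"planted fraction {po.fraction} infeasible for sizes ({sa}, {sb}): "
                f"{target:.3f} shared genes is not an integer; "
                f"nearest feasible fraction is {feasible:.6f}"
            )
        if shared < 1:
            raise ValueError(
                f"planted fraction {po.fraction} yields zero shared genes for "
                f"sizes ({sa}, {sb})"
            )
        shared_counts[(po.term_a, po.term_b)] = shared

    total_needed = sum(s for row in sizes for s in row)
    if total_needed > spec.universe_size:
        raise ValueError(
            f"universe of {spec.universe_size} genes too small: "
            f"{total_needed} distinct genes required"
        )
    pool = iter(gene_symbols(spec.universe_size))

    genes: dict[tuple[int, int], set[str]] = {}
    for r, row in enumerate(sizes):
        for t, size in enumerate(row):
            genes[(r, t)] = {next(pool) for _ in range(size)}
    # overwrite the planted partner's genes so the intersection is exact
    truth_rows = []
    for po in spec.planted_overlaps:
        a, b = po.term_a, po.term_b
        shared = shared_counts[(a, b)]
        shared_genes = set(sorted(genes[a])[:shared])
        own_b = sorted(genes[b] - genes[a])
        genes[b] = shared_genes | set(own_b[: sizes[b[0]][b[1]] - shared])
        achieved = shared / min(len(genes[a]), len(genes[b]))
        truth_rows.append(
            {
                "resource_a": a[0],
                "term_a": a[1],
                "resource_b": b[0],
                "term_b": b[1],
                "size_a": len(genes[a]),
                "size_b": len(genes[b]),
                "shared": shared,
                "fraction": achieved,
            }
        )

    resources = []
    for r, n in enumerate(spec.n_terms):
        name = f"{spec.resource_prefix}{r + 1}"
        sets = [
            GeneSet(f"{name}_T{t + 1:03d}", f"synthetic term {t + 1}", frozenset(genes[(r, t)]), resource=name)
            for t in range(n)
        ]
        resources.append(GeneSetResource(name, sets))
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "resource_a",
            "term_a",
            "resource_b",
            "term_b",
            "size_a",
            "size_b",
            "shared",
            "fraction",
        ],
    )
    return resources, truth


def make_query_fixture(
    resource: GeneSetResource,
    enriched_terms: Sequence[str],
    effect: float,
    n_query: int,
    seed: int,
    universe: Optional[Sequence[str]] = None,
) -> tuple[set[str], dict]:
    """Draw a query gene list with a planted enrichment signal.

    ``round(effect * n_query)`` genes are sampled without replacement from
    the union of the named terms; the remainder is sampled uniformly from
    the universe minus those terms (so background genes never dilute into
    the signal pool).  ``effect=0`` (or an empty term list) yields a pure
    null query.  Returns the query plus a truth record of the draw.
    """
    if not (0.0 <= effect <= 1.0):
        raise ValueError("effect must lie in [0, 1]")
    if n_query < 1:
        raise ValueError("n_query must be >= 1")
    rng = np.random.default_rng(seed)
    univ = sorted(universe) if universe is not None else sorted(resource.universe)
    signal_pool = sorted(set().union(*(resource[t].genes for t in enriched_terms))) if enriched_terms else []
    n_signal = round(effect * n_query) if enriched_terms else 0
    if n_signal > len(signal_pool):
        raise ValueError(
            f"cannot draw {n_signal} signal genes from a pool of {len(signal_pool)}"
        )
    background_pool = sorted(set(univ) - set(signal_pool))
    n_background = n_query - n_signal
    if n_background > len(background_pool):
        raise ValueError(
            f"cannot draw {n_background} background genes from a pool of "
            f"{len(background_pool)}"
        )
    signal = set(rng.choice(signal_pool, size=n_signal, replace=False)) if n_signal else set()
    background = (
        set(rng.choice(background_pool, size=n_background, replace=False))
        if n_background
        else set()
    )
    query = signal | background
    truth = {
        "enriched_terms": list(enriched_terms),
        "effect": effect,
        "n_query": n_query,
        "n_signal": n_signal,
        "signal_genes": sorted(signal),
        "background_genes": sorted(background),
        "seed": seed,
    }
    return query, truth


def make_network_fixture(
    model: Literal["path", "star", "random"],
    n_nodes: int,
    edge_prob: float = 0.05,
    seed: int = 0,
    scored: bool = False,
    source: str = "synthetic_net",
    node_names: Optional[Sequence[str]] = None,
) -> list[EdgeRecord]:
    """Generate an edge-record list with simple, fully known topology.

    ``path``: N1-N2-...-Nn chain.  ``star``: N1 as hub.  ``random``:
    Erdős–Rényi G(n, p) drawn from the seeded generator.  With
    ``scored=True`` each edge gets a confidence uniform in [0.5, 1).
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    rng = np.random.default_rng(seed)
    names = list(node_names) if node_names is not None else gene_symbols(n_nodes, prefix="N")
    if len(names) != n_nodes:
        raise ValueError("node_names length must equal n_nodes")
    pairs: list[tuple[str, str]] = []
    if model == "path":
        pairs = [(names[i], names[i + 1]) for i in range(n_nodes - 1)]
    elif model == "star":
        pairs = [(names[0], names[i]) for i in range(1, n_nodes)]
    elif model == "random":
        for i in range(n_nodes):
            for j in range(i + 1, n_nodes):
                if rng.random() < edge_prob:
                    pairs.append((names[i], names[j]))
    else:
        raise ValueError(f"unknown network model {model!r}")
    return [
        EdgeRecord(
            a,
            b,
            score=float(np.round(0.5 + 0.5 * rng.random(), 6)) if scored else None,
            source=source,
        )
        for a, b in pairs
    ]


def write_truth_table(truth: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a fixture truth table as TSV."""
    truth.to_csv(path, sep="\t", index=False)
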