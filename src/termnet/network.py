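"""Merged interaction networks and geneset expansion.

Multiple interaction resources (protein-protein, regulatory, ...) are merged
into one undirected graph with per-edge provenance: an edge remembers every
resource that contributed it, the maximum confidence score reported for it,
and any relation labels.  Merging is idempotent — re-adding an edge only
unions sources and maxes scores.

Two expansion strategies grow a query ("seed") gene list using the network:

* **neighbor expansion** — add every gene within ``order`` hops of any seed
  (multi-source breadth-first search), then induce the subgraph on
  seeds + added.  Casts a wide net.
* **connector expansion** — for every seed pair lacking a direct edge, admit
  the non-seed genes lying on shortest paths between them, provided those
  paths have at most ``max_intermediates`` interior nodes (default 1, i.e.
  common-neighbor connectors).  This surfaces genes that efficiently connect
  the input list — e.g. a hub that was not itself differentially expressed
  but interacts with many genes that were.  When several shortest paths tie,
  interior nodes of all of them are admitted, so the result is independent
  of traversal order.

Self-loops are retained in storage but excluded from degree and neighbor
queries: "number of interactions" as a centrality reads naturally as the
count of distinct partners.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import networkx as nx
import pandas as pd

from .resources import EdgeRecord

__all__ = [
    "InteractionNetwork",
    "ExpansionResult",
    "merge_networks",
    "filter_by_score",
    "expand_neighbors",
    "expand_connectors",
    "node_degrees",
    "node_attribute_table",
]


class InteractionNetwork:
    """Undirected gene-interaction graph with per-edge provenance.

    Edge data: ``score`` (max across contributing sources, or ``None`` if no
    source scored it), ``sources`` (set of resource names), ``relations``
    (set of SIF-style labels).  Backed by :class:`networkx.Graph`.
    """

    def __init__(self) -> None:
        self._g = nx.Graph()

    # -- construction -----------------------------------------------------

    def add_edge(
        self,
        gene_a: str,
        gene_b: str,
        score: Optional[float] = None,
        source: str = "",
        relation: Optional[str] = None,
    ) -> None:
        a, b = (gene_a, gene_b) if gene_a <= gene_b else (gene_b, gene_a)
        if self._g.has_edge(a, b):
            data = self._g.edges[a, b]
            if score is not None:
                data["score"] = score if data["score"] is None else max(data["score"], score)
            if source:
                data["sources"].add(source)
            if relation:
                data["relations"].add(relation)
        else:
            self._g.add_edge(
                a,
                b,
                score=score,
                sources={source} if source else set(),
                relations={relation} if relation else set(),
            )

    def add_records(self, records: Iterable[EdgeRecord]) -> None:
        for r in records:
            self.add_edge(r.gene_a, r.gene_b, score=r.score, source=r.source, relation=r.relation)

    # -- queries ----------------------------------------------------------

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self._g.nodes)

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def has_edge(self, a: str, b: str) -> bool:
        return self._g.has_edge(a, b)

    def edge_data(self, a: str, b: str) -> Mapping:
        return self._g.edges[a, b]

    def iter_edges(self) -> Iterator[tuple[tuple[str, str], Mapping]]:
        """Yield ``((a, b), data)`` with canonical (sorted) endpoint order."""
        for u, v, data in self._g.edges(data=True):
            pair = (u, v) if u <= v else (v, u)
            yield pair, data

    def neighbors(self, gene: str) -> set[str]:
        """Distinct interaction partners, self-loops excluded."""
        return {n for n in self._g.neighbors(gene) if n != gene}

    def degree(self, gene: str) -> int:
        return len(self.neighbors(gene))

    def subnetwork(self, genes: Iterable[str]) -> "InteractionNetwork":
        """Induced subgraph on ``genes`` (provenance preserved)."""
        keep = set(genes)
        out = InteractionNetwork()
        out._g = self._g.subgraph(keep).copy()
        for g in keep & set(self._g.nodes):
            if g not in out._g:
                out._g.add_node(g)
        return out

    def to_networkx(self) -> nx.Graph:
        return self._g.copy()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"InteractionNetwork({self.n_nodes} nodes, {self.n_edges} edges)"


def merge_networks(edge_lists: Sequence[Iterable[EdgeRecord]]) -> InteractionNetwork:
    """Union several edge-record lists into one provenance-tracking network.

    Commutative and idempotent: the resulting edge set, per-edge source sets
    and max scores do not depend on input order or repetition.
    """
    if not edge_lists:
        raise ValueError("at least one edge list is required")
    net = InteractionNetwork()
    for records in edge_lists:
        net.add_records(records)
    return net


def filter_by_score(
    network: InteractionNetwork, min_score: float, keep_unscored: bool = True
) -> InteractionNetwork:
    """Confidence filter: keep edges with score >= ``min_score``; unscored
    edges are kept iff ``keep_unscored``.  Nodes left without edges drop out."""
    if not math.isfinite(min_score):
        raise ValueError("min_score must be finite")
    out = InteractionNetwork()
    for (a, b), data in network.iter_edges():
        score = data["score"]
        if (score is None and keep_unscored) or (score is not None and score >= min_score):
            out._g.add_edge(
                a,
                b,
                score=score,
                sources=set(data["sources"]),
                relations=set(data["relations"]),
            )
    return out


@dataclass
class ExpansionResult:
    """Outcome of a neighbor or connector expansion.

    ``node_roles`` labels every subnetwork node ``"seed"`` or ``"added"``;
    ``missing_seeds`` are input seeds absent from the network (reported, not
    errors — real gene lists always contain unmapped symbols).
    """

    seed_genes: frozenset[str]
    added_genes: frozenset[str]
    subnetwork: InteractionNetwork
    node_roles: dict[str, str]
    missing_seeds: frozenset[str] = frozenset()
    method: str = ""

    @property
    def n_added(self) -> int:
        return len(self.added_genes)


def _bfs_within(network: InteractionNetwork, sources: set[str], max_dist: int) -> dict[str, int]:
    """Multi-source BFS distances up to ``max_dist`` (self-loops ignored)."""
    dist = {s: 0 for s in sources}
    frontier = deque(sources)
    while frontier:
        u = frontier.popleft()
        d = dist[u]
        if d == max_dist:
            continue
        for v in network.neighbors(u):
            if v not in dist:
                dist[v] = d + 1
                frontier.append(v)
    return dist


def expand_neighbors(
    network: InteractionNetwork, seeds: Iterable[str], order: int = 1
) -> ExpansionResult:
    """Add every gene within graph distance ``order`` of any seed.

    The subnetwork is the induced subgraph on (seeds present in the network)
    ∪ added.  Seeds missing from the network are recorded in
    ``missing_seeds``; having *no* seed in the network is an error.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    seeds = frozenset(seeds)
    present = {s for s in seeds if s in network.nodes}
    if not present:
        raise ValueError("no seed gene is present in the network")
    dist = _bfs_within(network, present, order)
    added = frozenset(dist) - seeds
    keep = present | added
    sub = network.subnetwork(keep)
    roles = {g: ("seed" if g in seeds else "added") for g in keep}
    return ExpansionResult(
        seed_genes=seeds,
        added_genes=added,
        subnetwork=sub,
        node_roles=roles,
        missing_seeds=seeds - present,
        method=f"neighbors(order={order})",
    )


def _score_weight(data: Mapping) -> float:
    """-log(score) edge cost; unscored edges cost as score=1 (no penalty).

    Confidence scores read as multiplicative reliabilities, so the most
    reliable path minimises the sum of -log(score).  Scores are clipped to
    (0, 1] to keep costs non-negative.
    """
    s = data.get("score")
    if s is None or s >= 1.0:
        return 0.0
    if s <= 0.0:
        return float("inf")
    return -math.log(s)


def expand_connectors(
    network: InteractionNetwork,
    seeds: Iterable[str],
    max_intermediates: int = 1,
    weighted: bool = False,
) -> ExpansionResult:
    """Admit non-seed genes lying on short paths between seed pairs.

    For every unordered pair of seeds present in the network with no direct
    edge, the shortest connecting path is found (unweighted hops by default;
    with ``weighted=True``, -log(score) costs).  If that path has at most
    ``max_intermediates`` interior nodes, every non-seed interior node of
    every tied shortest path is admitted.  Seed pairs joined by a direct
    edge, or unreachable pairs, contribute nothing.
    """
    if max_intermediates < 1:
        raise ValueError("max_intermediates must be >= 1")
    seeds = frozenset(seeds)
    present = sorted(s for s in seeds if s in network.nodes)
    if len(present) < 2:
        raise ValueError("connector expansion requires >=2 seeds present in the network")
    g = network._g
    added: set[str] = set()
    if weighted:
        for i, s in enumerate(present):
            for t in present[i + 1 :]:
                if g.has_edge(s, t):
                    continue
                try:
                    paths = list(
                        nx.all_shortest_paths(g, s, t, weight=lambda u, v, d: _score_weight(d))
                    )
                except nx.NetworkXNoPath:
                    continue
                for path in paths:
                    interior = [n for n in path[1:-1] if n != s and n != t]
                    if len(interior) <= max_intermediates:
                        added.update(n for n in interior if n not in seeds)
    else:
        # node v lies on a shortest s-t path iff dist(s,v) + dist(v,t) == dist(s,t)
        limit = max_intermediates + 1
        dists = {s: _bfs_within(network, {s}, limit) for s in present}
        for i, s in enumerate(present):
            ds = dists[s]
            for t in present[i + 1 :]:
                if g.has_edge(s, t):
                    continue
                d = ds.get(t)
                if d is None or d - 1 > max_intermediates:
                    continue
                dt = dists[t]
                for v, dv in ds.items():
                    if v in seeds:
                        continue
                    if 0 < dv < d and dt.get(v) == d - dv:
                        added.add(v)
    keep = set(present) | added
    sub = network.subnetwork(keep)
    roles = {n: ("seed" if n in seeds else "added") for n in keep}
    return ExpansionResult(
        seed_genes=seeds,
        added_genes=frozenset(added),
        subnetwork=sub,
        node_roles=roles,
        missing_seeds=seeds - set(present),
        method=(
            f"connectors(max_intermediates={max_intermediates}, "
            f"weighted={'score' if weighted else 'hops'})"
        ),
    )


def node_degrees(network: InteractionNetwork) -> dict[str, int]:
    """Distinct-partner count per node (self-loops excluded) — the display
    scaling used to mark how central each gene is."""
    return {n: network.degree(n) for n in network.nodes}


def node_attribute_table(result: ExpansionResult) -> pd.DataFrame:
    """Node attributes (role, degree within the subnetwork) for Cytoscape."""
    degrees = node_degrees(result.subnetwork)
    rows = [
        {"gene": g, "role": result.node_roles[g], "degree": degrees.get(g, 0)}
        for g in sorted(result.node_roles)
    ]
    return pd.DataFrame(rows, columns=["gene", "role", "degree"])
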