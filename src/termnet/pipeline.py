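"""Reproducible end-to-end workflow: load → reduce → enrich → expand → export.

A :class:`RunConfig` captures every input path and threshold of a run and
serialises losslessly to YAML/JSON, so a run re-executed from its saved
config is bit-identical on deterministic stages.  Each run writes a
mandatory provenance JSON recording package and library versions, SHA-256
hashes of every input file, all thresholds, and item counts at every filter
step — no result leaves the pipeline without the settings that produced it.

Figures are never the only carrier of a number: :func:`render_heatmap`
always writes the numeric TSV twin next to the image.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .enrichment import (
    DEFAULT_CAP,
    DEFAULT_MAX_TERM_SIZE,
    DEFAULT_MIN_TERM_SIZE,
    DEFAULT_Q_THRESHOLD,
    EnrichmentMatrix,
    EnrichmentQuery,
    enrichment_matrix,
    resolve_universe,
    results_table,
    term_enrichment,
)
from .network import expand_connectors, expand_neighbors, merge_networks, node_attribute_table
from .overlap import reduce_redundancy
from .resources import (
    read_gene_list,
    read_gmt,
    read_design_matrix,
    read_network,
    write_gmt,
    write_sif,
)

__all__ = ["RunConfig", "StageError", "render_heatmap", "run_pipeline"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Fully serialisable description of one workflow run."""

    gmt_paths: list[str] = field(default_factory=list)
    network_paths: list[str] = field(default_factory=list)
    query_paths: list[str] = field(default_factory=list)
    universe_mode: str = "resource_union"
    universe_path: Optional[str] = None
    design_path: Optional[str] = None
    q_threshold: float = DEFAULT_Q_THRESHOLD
    cap: float = DEFAULT_CAP
    min_term_size: int = DEFAULT_MIN_TERM_SIZE
    max_term_size: int = DEFAULT_MAX_TERM_SIZE
    pool: str = "per_query"
    fdr_method: str = "bh"
    reduce_threshold: Optional[float] = None
    overlap_metric: str = "min_denominator"
    min_score: Optional[float] = None
    keep_unscored: bool = True
    expand_mode: Optional[str] = None  # neighbors | connectors
    expand_order: int = 1
    max_intermediates: int = 1
    seed: int = 0
    out_dir: str = "termnet_out"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _sha256(path: Union[str, Path]) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def render_heatmap(
    matrix: EnrichmentMatrix,
    design: Optional[pd.DataFrame] = None,
    out: Union[str, Path] = "enrichment_heatmap.png",
    cmap: str = "viridis",
) -> Optional[Path]:
    """Render the capped -log10(q) heatmap with an optional study-design band.

    The numeric TSV twin (same stem, ``.tsv``) is always written so every
    plotted value is machine-readable.  An empty matrix is skipped with a
    warning and returns ``None``.  An all-zero matrix still renders, flagged
    "no significant terms" in the title.
    """
    out = Path(out)
    tsv = out.with_suffix(".tsv")
    matrix.values.to_csv(tsv, sep="\t")
    if matrix.empty:
        print(f"[render_heatmap] matrix is empty; skipping figure, wrote {tsv}", file=sys.stderr)
        return None
    design = design if design is not None else matrix.design
    n_rows, n_cols = matrix.values.shape
    has_design = design is not None and not design.empty
    fig_h = max(2.0, 0.3 * n_rows + (0.3 * len(design) if has_design else 0) + 1.5)
    fig_w = max(3.0, 0.6 * n_cols + 3.0)
    if has_design:
        design = design.reindex(columns=matrix.values.columns).fillna(0)
        fig, (ax_d, ax) = plt.subplots(
            2,
            1,
            figsize=(fig_w, fig_h),
            gridspec_kw={"height_ratios": [max(1, len(design)), max(1, n_rows)]},
            sharex=False,
        )
        ax_d.imshow(design.to_numpy(dtype=float), aspect="auto", cmap="Greys", vmin=0, vmax=1)
        ax_d.set_yticks(range(len(design)), design.index)
        ax_d.set_xticks([])
        ax_d.set_title("study design")
    else:
        fig, ax = plt.subplots(figsize=(fig_w, fig_h))
    im = ax.imshow(
        matrix.values.to_numpy(dtype=float), aspect="auto", cmap=cmap, vmin=0, vmax=matrix.cap
    )
    ax.set_xticks(range(n_cols), matrix.values.columns, rotation=45, ha="right")
    ax.set_yticks(range(n_rows), matrix.values.index, fontsize=7)
    title = "term enrichment, capped -log10(q)"
    if not np.any(matrix.values.to_numpy() > 0):
        title += " — no significant terms"
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label=f"-log10(q), capped at {matrix.cap:g}")
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full workflow described by ``config``.

    Stages: load resources/queries/networks → optional redundancy reduction
    → pooled enrichment (per-query results TSV + heatmap matrix TSV/PNG) →
    optional network expansion seeded by the query genes → SIF/attribute
    export → provenance JSON.  Any stage error aborts with the stage name
    and cause.  Returns the output directory.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prov: dict = {
        "termnet_version": __version__,
        "python": sys.version.split()[0],
        "config": config.to_dict(),
        "inputs": {},
        "counts": {},
    }

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as e:  # noqa: BLE001 - re-raised with stage context
                raise StageError(name, e) from e

        return wrap

    # -- load --------------------------------------------------------------
    loader = stage("load")

    def _load():
        for p in [*config.gmt_paths, *config.query_paths, *config.network_paths] + (
            [config.universe_path] if config.universe_path else []
        ) + ([config.design_path] if config.design_path else []):
            if not Path(p).exists():
                raise FileNotFoundError(f"input file not found: {p}")
            prov["inputs"][str(p)] = _sha256(p)
        resources = [read_gmt(p) for p in config.gmt_paths]
        queries_raw = {Path(p).stem: read_gene_list(p) for p in config.query_paths}
        design = read_design_matrix(config.design_path) if config.design_path else None
        return resources, queries_raw, design

    resources, queries_raw, design = loader(_load)
    prov["counts"]["resources"] = len(resources)
    prov["counts"]["terms_loaded"] = sum(len(r) for r in resources)
    prov["counts"]["queries"] = len(queries_raw)

    # -- optional redundancy reduction ------------------------------------
    if config.reduce_threshold is not None:
        red = stage("reduce")(
            reduce_redundancy,
            resources,
            threshold=config.reduce_threshold,
            metric=config.overlap_metric,
        )
        prov["counts"]["terms_kept_after_reduction"] = red.n_kept
        prov["counts"]["terms_dropped_by_reduction"] = red.n_dropped
        reduced = red.to_resource("reduced")
        write_gmt(reduced, out_dir / "reduced.gmt")
        resources = [reduced]

    # -- enrichment --------------------------------------------------------
    def _enrich():
        user_genes = read_gene_list(config.universe_path) if config.universe_path else None
        universe = resolve_universe(
            config.universe_mode,
            resources=resources,
            user_genes=user_genes,
            query_gene_lists=list(queries_raw.values()),
        )
        queries = [
            EnrichmentQuery.from_genes(name, genes, universe)
            for name, genes in queries_raw.items()
        ]
        all_results = []
        skip_total = 0
        for q in queries:
            res, skip = term_enrichment(
                q,
                resources,
                min_term_size=config.min_term_size,
                max_term_size=config.max_term_size,
                method=config.fdr_method,
                cap=config.cap,
            )
            all_results.extend(res)
            skip_total += skip.total
        matrix = enrichment_matrix(
            queries,
            resources,
            cap=config.cap,
            q_threshold=config.q_threshold,
            pool=config.pool,
            min_term_size=config.min_term_size,
            max_term_size=config.max_term_size,
            method=config.fdr_method,
            design=design,
        )
        return queries, all_results, skip_total, matrix

    queries, all_results, skip_total, matrix = stage("enrich")(_enrich)
    prov["counts"]["universe_size"] = len(queries[0].universe) if queries else 0
    prov["counts"]["terms_skipped_by_size"] = skip_total
    prov["counts"]["tests_performed"] = len(all_results)
    prov["counts"]["significant_terms"] = int(matrix.values.shape[0])
    results_table(all_results).to_csv(out_dir / "enrichment.tsv", sep="\t", index=False)
    stage("render")(render_heatmap, matrix, design, out_dir / "enrichment_heatmap.png")

    # -- optional network stages -------------------------------------------
    if config.network_paths:
        def _network():
            nets = [read_network(p) for p in config.network_paths]
            net = merge_networks(nets)
            if config.min_score is not None:
                from .network import filter_by_score

                net = filter_by_score(net, config.min_score, config.keep_unscored)
            return net

        net = stage("network")(_network)
        prov["counts"]["network_nodes"] = net.n_nodes
        prov["counts"]["network_edges"] = net.n_edges
        if config.expand_mode:
            def _expand():
                seeds = set().union(*(q.genes for q in queries))
                if config.expand_mode == "neighbors":
                    return expand_neighbors(net, seeds, order=config.expand_order)
                if config.expand_mode == "connectors":
                    return expand_connectors(
                        net, seeds, max_intermediates=config.max_intermediates
                    )
                raise ValueError(f"unknown expand mode {config.expand_mode!r}")

            result = stage("expand")(_expand)
            prov["counts"]["seed_genes_in_network"] = len(
                result.seed_genes - result.missing_seeds
            )
            prov["counts"]["seed_genes_missing"] = len(result.missing_seeds)
            prov["counts"]["genes_added"] = result.n_added
            prov["expansion_method"] = result.method
            if result.subnetwork.n_edges > 0:
                stage("export")(write_sif, result.subnetwork, out_dir / "subnetwork.sif")
            node_attribute_table(result).to_csv(
                out_dir / "subnetwork.nodes.tsv", sep="\t", index=False
            )

    (out_dir / "provenance.json").write_text(json.dumps(prov, indent=2, sort_keys=True))
    config.to_yaml(out_dir / "config.yaml")
    return out_dir
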