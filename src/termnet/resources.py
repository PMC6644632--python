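"""Domain types and file I/O for geneset resources, interaction networks and gene lists.

Formats handled:

* **GMT** — one geneset per line: ``name<TAB>description<TAB>gene1<TAB>gene2...``
  The second column is always a description (possibly empty), never a member gene.
* **Edge lists** — 2 or 3 delimited columns (gene, gene, optional numeric
  confidence score), with an optional header row that is auto-detected.
* **SIF** — ``gene relation gene`` triples, whitespace separated, as consumed by
  Cytoscape.  Recognised automatically when the middle column of a 3-column row
  is non-numeric and the last column is not a number.
* **Gene lists** — one symbol per line; ``#`` starts a comment.
* **Design matrices** — TSV with gene-list names as columns and condition
  indicators as rows.

Gene identifiers are opaque, case-sensitive strings; an optional
``uppercase`` flag normalises on load for callers who want case-folding.
Namespace harmonisation (Entrez vs. symbol vs. Ensembl) is left to the caller.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence, Union

import pandas as pd

__all__ = [
    "GeneSet",
    "GeneSetResource",
    "EdgeRecord",
    "GmtParseError",
    "NetworkParseError",
    "read_gmt",
    "write_gmt",
    "read_network",
    "write_sif",
    "read_gene_list",
    "read_design_matrix",
]


class GmtParseError(ValueError):
    """Raised for malformed GMT content; message names the offending line/term."""


class NetworkParseError(ValueError):
    """Raised for malformed edge-list/SIF content."""


@dataclass(frozen=True)
class GeneSet:
    """One named term (pathway, GO term, module, disease geneset ...).

    ``genes`` uses set semantics: duplicates collapse on construction and the
    member order carries no meaning.
    """

    name: str
    description: str
    genes: frozenset[str]
    resource: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("geneset name must be non-empty")
        if not isinstance(self.genes, frozenset):
            object.__setattr__(self, "genes", frozenset(self.genes))
        if not self.genes:
            raise ValueError(f"geneset {self.name!r} has no member genes")

    @property
    def size(self) -> int:
        return len(self.genes)

    @property
    def key(self) -> tuple[str, str]:
        """(resource, name) pair identifying this term across resources."""
        return (self.resource, self.name)


class GeneSetResource:
    """Ordered, named collection of genesets — the in-memory form of one GMT file.

    The ``universe`` is the union of all member genes; set names are unique
    within a resource.
    """

    def __init__(self, name: str, sets: Iterable[GeneSet]):
        self.name = name
        self.sets: list[GeneSet] = []
        self._by_name: dict[str, GeneSet] = {}
        for gs in sets:
            if gs.name in self._by_name:
                raise GmtParseError(
                    f"duplicate term name {gs.name!r} in resource {name!r}"
                )
            if gs.resource != name:
                gs = GeneSet(gs.name, gs.description, gs.genes, resource=name)
            self.sets.append(gs)
            self._by_name[gs.name] = gs

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def universe(self) -> frozenset[str]:
        """Union of all genes appearing in any member set."""
        out: set[str] = set()
        for gs in self.sets:
            out |= gs.genes
        return frozenset(out)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GeneSetResource({self.name!r}, {len(self.sets)} sets)"


@dataclass(frozen=True)
class EdgeRecord:
    """One interaction read from an edge list or SIF file.

    ``score`` is an optional non-negative confidence; ``relation`` is the SIF
    edge label when present.  Direction is ignored downstream: networks built
    from these records are undirected.
    """

    gene_a: str
    gene_b: str
    score: Optional[float] = None
    relation: Optional[str] = None
    source: str = ""

    def __post_init__(self) -> None:
        if not self.gene_a or not self.gene_b:
            raise ValueError("edge endpoints must be non-empty symbols")
        if self.score is not None:
            s = float(self.score)
            if not (s >= 0.0) or s != s or s == float("inf"):
                raise ValueError(f"edge score must be finite and >= 0, got {self.score}")

    @property
    def is_self_loop(self) -> bool:
        return self.gene_a == self.gene_b

    @property
    def pair(self) -> tuple[str, str]:
        """Canonical unordered endpoint pair (lexicographically smaller first)."""
        a, b = self.gene_a, self.gene_b
        return (a, b) if a <= b else (b, a)


# ---------------------------------------------------------------------------
# GMT


def read_gmt(
    path: Union[str, Path],
    resource_name: Optional[str] = None,
    uppercase: bool = False,
    strict: bool = False,
) -> GeneSetResource:
    """Load a GMT file into a :class:`GeneSetResource`.

    Each line must have >= 3 tab-separated fields (name, description, >= 1
    gene).  Duplicate gene symbols within a line collapse silently; duplicate
    term names within a file are an error.  ``resource_name`` defaults to the
    file stem.

    With ``strict=True`` a line whose description field also appears among
    its member genes is rejected — a guard against the malformed dialect that
    omits the description column.
    """
    path = Path(path)
    name = resource_name if resource_name is not None else path.stem
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path.name}:{lineno}: expected >=3 tab-separated fields "
                    f"(name, description, genes...), got {len(fields)}"
                )
            term, desc = fields[0], fields[1]
            genes = [g.strip() for g in fields[2:] if g.strip()]
            if not genes:
                raise GmtParseError(
                    f"{path.name}:{lineno}: term {term!r} lists no genes"
                )
            if uppercase:
                genes = [g.upper() for g in genes]
            if strict and desc in genes:
                raise GmtParseError(
                    f"{path.name}:{lineno}: description field {desc!r} duplicates "
                    "a member gene; file may lack a description column"
                )
            if term in seen:
                raise GmtParseError(
                    f"{path.name}:{lineno}: duplicate term name {term!r}"
                )
            seen.add(term)
            sets.append(GeneSet(term, desc, frozenset(genes), resource=name))
    if not sets:
        raise GmtParseError(f"{path.name}: no genesets found")
    return GeneSetResource(name, sets)


def write_gmt(resource: GeneSetResource, path: Union[str, Path]) -> None:
    """Serialise a resource as GMT with member genes in sorted order.

    Sorted gene columns make the serialisation byte-stable, so
    ``read_gmt(write_gmt(r))`` reproduces names, descriptions and gene sets
    exactly.
    """
    if len(resource) == 0:
        raise ValueError("cannot write an empty resource")
    path = Path(path)
    with path.open("w") as fh:
        for gs in resource:
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.genes)]) + "\n")


# ---------------------------------------------------------------------------
# Networks


def _try_float(token: str) -> Optional[float]:
    try:
        return float(token)
    except ValueError:
        return None


def read_network(
    path: Union[str, Path],
    score_column: Optional[int] = None,
    delimiter: Optional[str] = None,
    source: Optional[str] = None,
) -> list[EdgeRecord]:
    """Read an edge list or SIF file into :class:`EdgeRecord` objects.

    Parameters
    ----------
    score_column
        0-based index of the numeric confidence column, if any.  When given,
        a non-numeric value in that column on the first line is treated as a
        header and skipped; elsewhere it is a parse error.
    delimiter
        Column delimiter; ``None`` splits on any whitespace (which also
        enables the SIF dialect).
    source
        Resource name to stamp on each record; defaults to the file stem.

    Rows with a single column are parse errors.  Self-loops are preserved
    (flagged via :attr:`EdgeRecord.is_self_loop`); downstream degree and
    neighbor operations exclude them.  With no declared score column, a
    3-column row with numeric third field is read as (gene, gene, score); a
    non-numeric middle field is read as SIF (gene, relation, gene).
    """
    path = Path(path)
    src = source if source is not None else path.stem
    records: list[EdgeRecord] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split(delimiter) if delimiter else line.split()
            fields = [f for f in fields if f != ""]
            if len(fields) < 2:
                raise NetworkParseError(
                    f"{path.name}:{lineno}: expected >=2 columns, got {len(fields)}"
                )
            score: Optional[float] = None
            relation: Optional[str] = None
            if score_column is not None:
                if score_column >= len(fields):
                    raise NetworkParseError(
                        f"{path.name}:{lineno}: score column {score_column} "
                        f"out of range for {len(fields)}-column row"
                    )
                val = _try_float(fields[score_column])
                if val is None:
                    if not records and lineno == 1:
                        continue  # header row
                    raise NetworkParseError(
                        f"{path.name}:{lineno}: non-numeric score "
                        f"{fields[score_column]!r} in column {score_column}"
                    )
                a, b = fields[0], fields[1]
                score = val
            elif len(fields) >= 3:
                third = _try_float(fields[2])
                if third is not None:
                    a, b, score = fields[0], fields[1], third
                elif _try_float(fields[1]) is None:
                    # SIF triple: gene relation gene
                    a, relation, b = fields[0], fields[1], fields[2]
                else:
                    raise NetworkParseError(
                        f"{path.name}:{lineno}: cannot interpret 3-column row "
                        f"{fields!r} as edge list or SIF"
                    )
            else:
                a, b = fields[0], fields[1]
            records.append(EdgeRecord(a, b, score=score, relation=relation, source=src))
    return records


def write_sif(
    network,
    path: Union[str, Path],
    attrs_path: Optional[Union[str, Path]] = None,
    default_relation: str = "pp",
) -> Path:
    """Write an :class:`~termnet.network.InteractionNetwork` as SIF for Cytoscape.

    Each unordered edge appears once, smaller symbol first.  A companion
    edge-attribute TSV (gene_a, gene_b, relation, score, sources) is written
    alongside (default ``<path>`` with suffix ``.edges.tsv``) so confidence
    and provenance survive the SIF's three-column limit.  Returns the
    attribute-file path.
    """
    path = Path(path)
    if network.n_edges == 0:
        raise ValueError("cannot write an empty network")
    if attrs_path is None:
        attrs_path = path.with_suffix(path.suffix + ".edges.tsv")
    attrs_path = Path(attrs_path)
    rows = []
    for (a, b), data in sorted(network.iter_edges()):
        relation = ",".join(sorted(data["relations"])) if data["relations"] else default_relation
        rows.append((a, relation, b, data["score"], sorted(data["sources"])))
    with path.open("w") as fh:
        for a, relation, b, _, _ in rows:
            fh.write(f"{a}\t{relation}\t{b}\n")
    with attrs_path.open("w") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["gene_a", "gene_b", "relation", "score", "sources"])
        for a, relation, b, score, sources in rows:
            writer.writerow([a, b, relation, "" if score is None else score, ",".join(sources)])
    return attrs_path


# ---------------------------------------------------------------------------
# Gene lists and design matrices


def read_gene_list(path: Union[str, Path], uppercase: bool = False) -> list[str]:
    """Read a plain-text gene list, one symbol per line; '#' comments ignored.

    Order is preserved and duplicates are kept (callers needing set semantics
    take ``set(...)``).
    """
    out: list[str] = []
    with Path(path).open() as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if line:
                out.append(line.upper() if uppercase else line)
    return out


def read_design_matrix(path: Union[str, Path]) -> pd.DataFrame:
    """Read a study-design matrix: rows are condition indicators, columns are
    gene-list (query) names.  TSV with the indicator name in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0)
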