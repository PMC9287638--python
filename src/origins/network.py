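"""Build the cell-differentiation PPI network.

The network scaffold is assembled from two public exports:

1. a GO-annotation table (QuickGO-style TSV) restricted to the biological
   process of interest — cell differentiation, GO:0030154, plus its child
   terms — and to one taxon (human, 9606), which yields the protein catalog
   (the nodes);
2. a Pathway-Commons-style SIF interaction dump, from which we keep the
   interactions whose two participants are both catalog proteins, discarding
   rows that involve chemical compounds (CHEBI: identifiers by default).

The resulting graph is undirected and unweighted: the interaction type never
orients or weights an edge, and each unordered pair is stored once.
Identifier matching is exact string equality after uppercase normalization
(no alias resolution — a documented limitation).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence, TextIO

from .errors import DuplicateEdgeWarning, EmptyCatalogError, FormatError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ProteinCatalog",
    "InteractionRecord",
    "PPIEdgeList",
    "FilterReport",
    "parse_go_annotations",
    "parse_sif",
    "filter_to_catalog",
    "write_edge_list",
    "read_edge_list",
]

Edge = tuple[str, str]


def canonical_edge(a: str, b: str) -> Edge:
    """Uppercase both symbols and order them; (B,A) and (A,B) collapse."""
    a, b = a.strip().upper(), b.strip().upper()
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class ProteinCatalog:
    """Set of gene symbols annotated to a GO term (and its descendants).

    Membership tests are case-insensitive: identifiers are uppercased on
    construction and lookups uppercase the query.
    """

    identifiers: frozenset[str]
    source_term: str = ""
    taxon: str = ""

    def __post_init__(self):
        object.__setattr__(self, "identifiers", frozenset(i.upper() for i in self.identifiers))
        if any(not i for i in self.identifiers):
            raise ValidationError("protein catalog contains an empty identifier")

    def __contains__(self, symbol: str) -> bool:
        return symbol.strip().upper() in self.identifiers

    def __len__(self) -> int:
        return len(self.identifiers)


@dataclass(frozen=True)
class InteractionRecord:
    participant_a: str
    interaction_type: str
    participant_b: str
    source_db: str | None = None


@dataclass
class PPIEdgeList:
    """Unique undirected gene-symbol pairs; the adjacency A_ij of the score."""

    edges: set[Edge] = field(default_factory=set)

    def __post_init__(self):
        canon = set()
        for a, b in self.edges:
            canon.add(canonical_edge(a, b))
        self.edges = canon

    @property
    def gene_universe(self) -> set[str]:
        out: set[str] = set()
        for a, b in self.edges:
            out.add(a)
            out.add(b)
        return out

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_genes(self) -> int:
        return len(self.gene_universe)

    def __iter__(self) -> Iterator[Edge]:
        return iter(sorted(self.edges))

    def __len__(self) -> int:
        return len(self.edges)

    def __eq__(self, other) -> bool:
        if isinstance(other, PPIEdgeList):
            return self.edges == other.edges
        return NotImplemented


@dataclass
class FilterReport:
    """Per-reason drop counts from :func:`filter_to_catalog`.

    Conservation invariant: ``input_rows == chemical_dropped +
    out_of_catalog_dropped + self_loop_dropped + duplicate_collapsed +
    final_edges``.
    """

    input_rows: int = 0
    chemical_dropped: int = 0
    out_of_catalog_dropped: int = 0
    self_loop_dropped: int = 0
    duplicate_collapsed: int = 0
    final_edges: int = 0
    final_genes: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2) + "\n")


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

_SYMBOL_COLUMNS = {"symbol", "gene product symbol", "gene_symbol", "gene symbol"}
_GO_COLUMNS = {"go term", "go_term", "go id", "go_id", "go term id", "goid"}
_TAXON_COLUMNS = {"taxon id", "taxon_id", "taxon", "taxon name id", "tax_id"}


def _open_maybe(stream_or_path) -> TextIO:
    if isinstance(stream_or_path, (str, Path)):
        return open(stream_or_path)
    return stream_or_path


def _find_column(header: Sequence[str], candidates: set[str], what: str, path) -> int:
    lowered = [h.strip().lower() for h in header]
    for i, h in enumerate(lowered):
        if h in candidates:
            return i
    raise FormatError(
        f"annotation table lacks a {what} column (looked for one of {sorted(candidates)})",
        path=path,
    )


def parse_go_annotations(
    table, go_term: str, taxon: int | str, descendants: Iterable[str] = ()
) -> ProteinCatalog:
    """Extract the protein catalog from a QuickGO-style annotation export.

    A row contributes its (uppercased) symbol when its taxon matches and its
    GO ID is ``go_term`` or one of the supplied ``descendants``. The ontology
    traversal that produces the descendant list is deliberately external:
    the caller supplies the child-term accessions (or a pre-filtered export).

    Raises
    ------
    FormatError
        If a required column is missing.
    EmptyCatalogError
        If the table parses but zero rows match.
    """
    accepted = {go_term.strip().upper()} | {d.strip().upper() for d in descendants}
    taxon = str(taxon).strip()
    path = table if isinstance(table, (str, Path)) else None
    fh = _open_maybe(table)
    close = isinstance(table, (str, Path))
    try:
        header_line = fh.readline()
        if not header_line.strip():
            raise FormatError("empty annotation table", path=str(path) if path else None)
        header = header_line.rstrip("\n").split("\t")
        i_sym = _find_column(header, _SYMBOL_COLUMNS, "symbol", path)
        i_go = _find_column(header, _GO_COLUMNS, "GO-ID", path)
        i_tax = _find_column(header, _TAXON_COLUMNS, "taxon", path)
        needed = max(i_sym, i_go, i_tax)
        symbols: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) <= needed:
                raise FormatError(
                    f"expected at least {needed + 1} columns, found {len(fields)}",
                    line=lineno,
                    path=str(path) if path else None,
                )
            if fields[i_tax].strip() != taxon:
                continue
            if fields[i_go].strip().upper() not in accepted:
                continue
            sym = fields[i_sym].strip().upper()
            if sym:
                symbols.add(sym)
    finally:
        if close:
            fh.close()
    if not symbols:
        raise EmptyCatalogError(
            f"no annotation rows matched GO term {go_term} "
            f"({len(accepted) - 1} descendants) and taxon {taxon}"
        )
    return ProteinCatalog(identifiers=frozenset(symbols), source_term=go_term, taxon=taxon)


def parse_sif(stream) -> list[InteractionRecord]:
    """Parse a simple-interaction-format stream into interaction records.

    SIF rows are ``participant_a <TAB> interaction_type <TAB> participant_b``
    with any extra columns ignored. Blank lines and '#' comments are skipped;
    record order is preserved. A row with fewer than three columns raises
    :class:`FormatError` with its line number.
    """
    path = stream if isinstance(stream, (str, Path)) else None
    fh = _open_maybe(stream)
    close = isinstance(stream, (str, Path))
    records: list[InteractionRecord] = []
    try:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"SIF row has {len(fields)} column(s), expected 3",
                    line=lineno,
                    path=str(path) if path else None,
                )
            records.append(
                InteractionRecord(
                    participant_a=fields[0].strip(),
                    interaction_type=fields[1].strip(),
                    participant_b=fields[2].strip(),
                )
            )
    finally:
        if close:
            fh.close()
    return records


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


def _is_chemical(identifier: str, prefixes: frozenset[str]) -> bool:
    up = identifier.strip().upper()
    return any(up.startswith(p) for p in prefixes)


def filter_to_catalog(
    records: Iterable[InteractionRecord],
    catalog: ProteinCatalog,
    chemical_prefixes: Iterable[str] = ("CHEBI:",),
    *,
    keep_self_loops: bool = False,
) -> tuple[PPIEdgeList, FilterReport]:
    """Keep interactions between two catalog proteins; drop the rest.

    A record survives iff neither participant carries a chemical-compound
    prefix and both participants are catalog members. Survivors are
    deduplicated as unordered pairs. Self-interactions are dropped by default
    (an x_i**2 term rewards single-gene expression rather than an
    interaction); pass ``keep_self_loops=True`` to retain them.
    """
    if len(catalog) == 0:
        raise ValidationError("cannot filter against an empty protein catalog")
    prefixes = frozenset(p.upper() for p in chemical_prefixes)
    report = FilterReport()
    edges: set[Edge] = set()
    for rec in records:
        report.input_rows += 1
        a, b = rec.participant_a, rec.participant_b
        if _is_chemical(a, prefixes) or _is_chemical(b, prefixes):
            report.chemical_dropped += 1
            continue
        if a not in catalog or b not in catalog:
            report.out_of_catalog_dropped += 1
            continue
        edge = canonical_edge(a, b)
        if edge[0] == edge[1] and not keep_self_loops:
            report.self_loop_dropped += 1
            continue
        if edge in edges:
            report.duplicate_collapsed += 1
            continue
        edges.add(edge)
    out = PPIEdgeList(edges=edges)
    report.final_edges = out.n_edges
    report.final_genes = out.n_genes
    if report.final_edges == 0:
        warnings.warn("network filtering retained zero edges", UserWarning)
    logger.info(
        "network build: %d rows -> %d edges (%d chemical, %d out-of-catalog, "
        "%d self-loop, %d duplicate)",
        report.input_rows,
        report.final_edges,
        report.chemical_dropped,
        report.out_of_catalog_dropped,
        report.self_loop_dropped,
        report.duplicate_collapsed,
    )
    return out, report


def edge_list_to_records(edges: PPIEdgeList) -> list[InteractionRecord]:
    """Re-express an edge list as interaction records (e.g. to re-filter)."""
    return [
        InteractionRecord(participant_a=a, interaction_type="interacts-with", participant_b=b)
        for a, b in edges
    ]


# ---------------------------------------------------------------------------
# edge-list files
# ---------------------------------------------------------------------------

_HEADER_TOKENS = {
    "gene_a", "gene_b", "participant_a", "participant_b", "source", "target",
    "node1", "node2", "gene1", "gene2", "protein_a", "protein_b",
}


def write_edge_list(edges: PPIEdgeList, path, *, header: bool = True) -> None:
    """Write a two-column TSV, one unordered pair per line, sorted."""
    with open(path, "w") as fh:
        if header:
            fh.write("gene_a\tgene_b\n")
        for a, b in edges:
            fh.write(f"{a}\t{b}\n")


def read_edge_list(path_or_stream, *, keep_self_loops: bool = False) -> PPIEdgeList:
    """Read a two-column TSV edge list (optional header auto-detected).

    Duplicated unordered pairs collapse with a :class:`DuplicateEdgeWarning`;
    self-loops are dropped (warned) unless ``keep_self_loops``.
    """
    path = path_or_stream if isinstance(path_or_stream, (str, Path)) else None
    fh = _open_maybe(path_or_stream)
    close = path is not None
    edges: set[Edge] = set()
    duplicates = 0
    self_loops = 0
    try:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise FormatError(
                    "edge-list row must have two tab-separated symbols",
                    line=lineno,
                    path=str(path) if path else None,
                )
            if lineno == 1 and all(f.strip().lower() in _HEADER_TOKENS for f in fields[:2]):
                continue  # header row
            edge = canonical_edge(fields[0], fields[1])
            if edge[0] == edge[1] and not keep_self_loops:
                self_loops += 1
                continue
            if edge in edges:
                duplicates += 1
                continue
            edges.add(edge)
    finally:
        if close:
            fh.close()
    if duplicates:
        warnings.warn(
            f"edge list contained {duplicates} duplicated unordered pair(s); collapsed",
            DuplicateEdgeWarning,
        )
    if self_loops:
        warnings.warn(f"dropped {self_loops} self-loop(s) from edge list", UserWarning)
    return PPIEdgeList(edges=edges)


def edges_from_pairs(pairs: Iterable[tuple[str, str]], *, keep_self_loops: bool = False) -> PPIEdgeList:
    """Convenience constructor from an iterable of (a, b) symbol pairs."""
    edges = set()
    for a, b in pairs:
        e = canonical_edge(a, b)
        if e[0] == e[1] and not keep_self_loops:
            continue
        edges.add(e)
    return PPIEdgeList(edges=edges)
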