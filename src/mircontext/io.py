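"""Readers and writers for the plain-text formats the tool exchanges.

All normalization happens here, once, at the boundary: gene symbols are
uppercased, duplicate edges collapsed, self-loops in protein networks
dropped.  miRNA identifiers are kept verbatim because miRNA nomenclature
is case-meaningful (``miR-`` denotes the mature strand, ``mir-`` the
hairpin).

Interchange formats are deliberately minimal:

* miRNA-target edges: 2-column TSV (miRNA, gene symbol)
* protein interactions: 2-column TSV (gene, gene), undirected
* gene signatures: one symbol per line, or GMT for collections
* gold-standard / association edges: TSV (signature, miRNA[, score])

Native exports from target-prediction or pathway databases should be cut
down to these shapes first; the parsers are dialect-free on purpose.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

_GENE_TOKEN = re.compile(r"[A-Z0-9][A-Z0-9-]*$")


@dataclass(frozen=True)
class InteractionTable:
    """A deduplicated set of miRNA -> gene edges with an evidence tag."""

    edges: frozenset[tuple[str, str]]
    source_tag: str = "predicted"

    def __post_init__(self) -> None:
        if not self.edges:
            raise ValueError("an InteractionTable cannot be empty")
        for mirna, gene in self.edges:
            if not mirna or not gene:
                raise ValueError("empty miRNA or gene identifier in edge set")

    @property
    def mirnas(self) -> set[str]:
        return {m for m, _ in self.edges}

    @property
    def genes(self) -> set[str]:
        return {g for _, g in self.edges}

    def __len__(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class GeneSignature:
    """A named gene set, e.g. genes repressed after pre-miRNA transfection."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene signature {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


class ProteinNetwork:
    """Undirected gene-gene functional interaction graph.

    Thin wrapper over :class:`networkx.Graph` that enforces symbol
    normalization and forbids self-loops.
    """

    def __init__(self, edges: Iterable[tuple[str, str]]) -> None:
        g = nx.Graph()
        dropped = 0
        for a, b in edges:
            a, b = a.strip().upper(), b.strip().upper()
            if not a or not b:
                continue
            if a == b:
                dropped += 1
                continue
            g.add_edge(a, b)
        if dropped:
            logger.info("dropped %d self-loop edge(s)", dropped)
        self._graph = g

    @property
    def graph(self) -> nx.Graph:
        return self._graph

    @property
    def nodes(self) -> set[str]:
        return set(self._graph.nodes)

    def neighbors(self, gene: str) -> set[str]:
        if gene not in self._graph:
            return set()
        return set(self._graph.neighbors(gene))

    def degree(self, gene: str) -> int:
        if gene not in self._graph:
            return 0
        return self._graph.degree(gene)

    @property
    def n_edges(self) -> int:
        return self._graph.number_of_edges()

    def edge_list(self) -> list[tuple[str, str]]:
        """Deterministic sorted edge list with each pair ordered (min, max)."""
        return sorted(tuple(sorted(e)) for e in self._graph.edges)


def _iter_data_lines(path: str | Path) -> Iterable[tuple[int, str]]:
    text = Path(path).read_text()
    for i, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip()
        if not line or line.lstrip().startswith("#"):
            continue
        yield i, line


def read_mirna_targets(path: str | Path, source_tag: str = "predicted") -> InteractionTable:
    """Read a 2-column TSV of miRNA -> gene-symbol edges.

    Lines starting with ``#`` are comments.  A single header line is
    auto-detected: if column 2 of the first data line is not an
    uppercase-alphanumeric(-dash) token it is treated as a header and
    skipped.  Gene symbols are uppercased, duplicates collapsed.
    """
    path = Path(path)
    edges: set[tuple[str, str]] = set()
    dropped = 0
    first = True
    for lineno, line in _iter_data_lines(path):
        parts = line.split("\t")
        if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
            dropped += 1
            first = False
            continue
        mirna, gene = parts[0].strip(), parts[1].strip()
        if first and not _GENE_TOKEN.match(gene):
            logger.info("skipping header line %d of %s", lineno, path.name)
            first = False
            continue
        first = False
        edge = (mirna, gene.upper())
        if edge in edges:
            dropped += 1
        edges.add(edge)
    if dropped:
        logger.info("%s: dropped %d duplicate/malformed line(s)", path.name, dropped)
    if not edges:
        raise ValueError(f"no interactions parsed from {path}")
    return InteractionTable(edges=frozenset(edges), source_tag=source_tag)


def merge_interaction_tables(a: InteractionTable, b: InteractionTable) -> InteractionTable:
    """Set union of two edge tables, e.g. merging validated-target databases."""
    tag = a.source_tag if a.source_tag == b.source_tag else "merged"
    return InteractionTable(edges=a.edges | b.edges, source_tag=tag)


def read_ppi_edges(path: str | Path) -> ProteinNetwork:
    """Read an undirected 2-column TSV of protein functional interactions."""
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    first = True
    for lineno, line in _iter_data_lines(path):
        parts = line.split("\t")
        if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
            first = False
            continue
        a, b = parts[0].strip(), parts[1].strip()
        if first and not _GENE_TOKEN.match(b):
            logger.info("skipping header line %d of %s", lineno, path.name)
            first = False
            continue
        first = False
        pairs.append((a, b))
    net = ProteinNetwork(pairs)
    if net.n_edges == 0:
        raise ValueError(f"no protein interactions parsed from {path}")
    return net


def read_gene_list(path: str | Path, name: str) -> GeneSignature:
    """Read a one-symbol-per-line gene list into a named signature."""
    genes = {
        line.split("\t")[0].strip().upper()
        for _, line in _iter_data_lines(path)
        if line.split("\t")[0].strip()
    }
    if not genes:
        raise ValueError(f"no genes parsed from {path}")
    return GeneSignature(name=name, genes=frozenset(genes))


def read_gmt(path: str | Path) -> list[GeneSignature]:
    """Read a GMT gene-set file: name TAB description TAB gene TAB gene ...

    Lines with fewer than three fields are skipped with a warning; the
    description field is discarded.
    """
    sigs: list[GeneSignature] = []
    for lineno, line in _iter_data_lines(path):
        parts = [p.strip() for p in line.split("\t")]
        genes = frozenset(g.upper() for g in parts[2:] if g)
        if len(parts) < 3 or not genes:
            logger.warning("GMT line %d has <3 fields; skipped", lineno)
            continue
        sigs.append(GeneSignature(name=parts[0], genes=genes))
    if not sigs:
        raise ValueError(f"no gene sets parsed from {path}")
    return sigs


def filter_gmt_by_size(sets: Sequence[GeneSignature], min_genes: int = 10) -> list[GeneSignature]:
    """Keep gene sets with at least ``min_genes`` members.

    The default of 10 drops the tiny pathway sets that make
    over-representation statistics unstable.
    """
    if min_genes < 1:
        raise ValueError("min_genes must be >= 1")
    return [s for s in sets if len(s.genes) >= min_genes]


def read_edge_pairs(path: str | Path) -> set[tuple[str, str]]:
    """Read (signature, miRNA) pairs from a 2+ column TSV (e.g. a gold standard)."""
    pairs: set[tuple[str, str]] = set()
    first = True
    for _, line in _iter_data_lines(path):
        parts = [p.strip() for p in line.split("\t")]
        if len(parts) < 2 or not parts[0] or not parts[1]:
            first = False
            continue
        # header heuristic: a first line whose second column is a column label
        if first and parts[1].lower() in {"mirna", "mirna_id", "mir"}:
            first = False
            continue
        first = False
        pairs.add((parts[0], parts[1]))
    if not pairs:
        raise ValueError(f"no edges parsed from {path}")
    return pairs


def write_table(
    rows: Sequence[Mapping[str, object]] | pd.DataFrame,
    path: str | Path,
    columns: Sequence[str] | None = None,
) -> None:
    """Write records as a TSV with header.

    Row order is preserved as given; callers are responsible for sorting
    deterministically.  Floats use a 10-significant-digit format so
    identical runs produce byte-identical files.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        df = pd.DataFrame(list(rows), columns=list(columns) if columns else None)
        if columns is not None and df.empty:
            df = pd.DataFrame(columns=list(columns))
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")
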