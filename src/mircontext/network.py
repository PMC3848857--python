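"""Context-specific miRNA effect: target sets expanded one hop into the
protein-interaction network, assembled into a gene x miRNA design matrix.

A miRNA represses its direct targets through 3'UTR binding; the protein
products of those targets sit in complexes and functional modules, so the
repression propagates one interaction hop outward.  The *context target
set* of a miRNA is therefore its direct targets plus the protein-network
neighbors of those targets.  Encoding each miRNA's context set as a
column of influence values over a common gene universe yields the design
matrix on which a gene signature is regressed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .io import GeneSignature, InteractionTable, ProteinNetwork, write_table

logger = logging.getLogger(__name__)

# provenance codes in ContextEffectMatrix.provenance
NONE, DIRECT, INDIRECT = 0, 1, 2


@dataclass(frozen=True)
class ContextTargets:
    """Direct and indirect (one-hop partner) target sets of one miRNA."""

    direct: frozenset[str]
    indirect: frozenset[str]

    @property
    def all(self) -> frozenset[str]:
        return self.direct | self.indirect


@dataclass
class ContextEffectMatrix:
    """Gene x miRNA influence design matrix.

    ``values[i, j]`` is 1 if gene i is a direct target of miRNA j,
    ``w_indirect`` if it is only an interaction partner of a direct
    target, and 0 otherwise.  ``provenance`` stores the same support with
    codes 1 (direct) and 2 (indirect); a cell that qualifies as both is
    recorded as direct.
    """

    gene_index: list[str]
    mirna_index: list[str]
    values: np.ndarray
    provenance: np.ndarray
    w_indirect: float = 1.0

    def __post_init__(self) -> None:
        n, p = self.values.shape
        if len(self.gene_index) != n or len(self.mirna_index) != p:
            raise ValueError("index lengths do not match matrix shape")
        if self.provenance.shape != (n, p):
            raise ValueError("provenance shape mismatch")
        if not 0.0 < self.w_indirect <= 1.0:
            raise ValueError("w_indirect must be in (0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gene_pos(self, gene: str) -> int:
        return self.gene_index.index(gene)

    def column(self, mirna: str) -> np.ndarray:
        return self.values[:, self.mirna_index.index(mirna)]

    def target_counts(self, direct_only: bool = False) -> dict[str, int]:
        """Number of in-universe (context or direct) targets per miRNA."""
        mask = self.provenance == DIRECT if direct_only else self.provenance != NONE
        counts = mask.sum(axis=0)
        return {m: int(c) for m, c in zip(self.mirna_index, counts)}

    def to_triplets(self) -> pd.DataFrame:
        """Sparse triplet representation: one row per nonzero cell."""
        rows, cols = np.nonzero(self.provenance)
        prov = np.where(self.provenance[rows, cols] == DIRECT, "direct", "indirect")
        df = pd.DataFrame(
            {
                "gene": [self.gene_index[i] for i in rows],
                "mirna": [self.mirna_index[j] for j in cols],
                "value": self.values[rows, cols],
                "provenance": prov,
            }
        )
        return df.sort_values(["gene", "mirna"], kind="mergesort").reset_index(drop=True)

    def write_triplets(self, path: str | Path) -> None:
        write_table(self.to_triplets(), path)

    @classmethod
    def from_triplets(cls, df: pd.DataFrame) -> "ContextEffectMatrix":
        genes = sorted(df["gene"].unique())
        mirnas = sorted(df["mirna"].unique())
        gi = {g: i for i, g in enumerate(genes)}
        mi = {m: j for j, m in enumerate(mirnas)}
        values = np.zeros((len(genes), len(mirnas)))
        prov = np.zeros((len(genes), len(mirnas)), dtype=np.int8)
        indirect_vals = set()
        for gene, mirna, value, p in df.itertuples(index=False):
            i, j = gi[gene], mi[mirna]
            values[i, j] = value
            prov[i, j] = DIRECT if p == "direct" else INDIRECT
            if p == "indirect":
                indirect_vals.add(float(value))
        w = indirect_vals.pop() if len(indirect_vals) == 1 else 1.0
        return cls(genes, mirnas, values, prov, w_indirect=w)

    @classmethod
    def read_triplets(cls, path: str | Path) -> "ContextEffectMatrix":
        df = pd.read_csv(path, sep="\t")
        return cls.from_triplets(df)


@dataclass(frozen=True)
class AlignedResponse:
    """A gene signature aligned to a matrix universe as a 0/1 vector."""

    y: np.ndarray
    n_in_universe: int
    dropped_genes: frozenset[str]

    @property
    def coverage(self) -> float:
        total = self.n_in_universe + len(self.dropped_genes)
        return self.n_in_universe / total if total else 0.0


def direct_target_map(table: InteractionTable) -> dict[str, set[str]]:
    """Group the edge table into miRNA -> set-of-direct-targets."""
    out: dict[str, set[str]] = {}
    for mirna, gene in table.edges:
        out.setdefault(mirna, set()).add(gene)
    return out


def context_target_map(
    table: InteractionTable, ppi: ProteinNetwork
) -> dict[str, ContextTargets]:
    """Expand each miRNA's direct targets by their one-hop PPI partners.

    A gene that is both a direct target and a partner of another direct
    target counts as direct only; the two sets are disjoint.
    """
    out: dict[str, ContextTargets] = {}
    for mirna, direct in direct_target_map(table).items():
        partners: set[str] = set()
        for g in direct:
            partners |= ppi.neighbors(g)
        out[mirna] = ContextTargets(
            direct=frozenset(direct), indirect=frozenset(partners - direct)
        )
    return out


def build_design_matrix(
    context: Mapping[str, ContextTargets],
    universe_mode: Literal["union", "ppi_restricted"] = "ppi_restricted",
    w_indirect: float = 1.0,
    direct_only: bool = False,
    ppi_nodes: set[str] | None = None,
) -> ContextEffectMatrix:
    """Assemble the gene x miRNA influence matrix.

    Parameters
    ----------
    context
        miRNA -> :class:`ContextTargets` mapping from :func:`context_target_map`.
    universe_mode
        ``"union"`` takes every gene appearing in any (direct or indirect)
        target set; ``"ppi_restricted"`` additionally intersects with the
        protein-network node set, i.e. keeps genes that are targeted by a
        miRNA *and* interact at the protein level.
    w_indirect
        Influence value assigned to indirect-only cells, in (0, 1].
    direct_only
        Ignore indirect sets entirely (the no-network regression baseline).
    ppi_nodes
        Node set of the protein network; required for ``ppi_restricted``.

    miRNA columns and gene rows that end up with no nonzero entries are
    dropped (and logged); row/column order is sorted, hence deterministic.
    """
    if not context:
        raise ValueError("context mapping is empty")
    if not 0.0 < w_indirect <= 1.0:
        raise ValueError("w_indirect must be in (0, 1]")
    if universe_mode == "ppi_restricted" and ppi_nodes is None:
        raise ValueError("ppi_restricted universe requires ppi_nodes")

    universe: set[str] = set()
    for ct in context.values():
        universe |= ct.direct
        if not direct_only:
            universe |= ct.indirect
    if universe_mode == "ppi_restricted":
        universe &= ppi_nodes  # type: ignore[operator]
    if not universe:
        raise ValueError("empty gene universe after restriction")

    genes = sorted(universe)
    mirnas = sorted(context)
    gi = {g: i for i, g in enumerate(genes)}
    values = np.zeros((len(genes), len(mirnas)))
    prov = np.zeros((len(genes), len(mirnas)), dtype=np.int8)
    for j, m in enumerate(mirnas):
        ct = context[m]
        if not direct_only:
            for g in ct.indirect:
                i = gi.get(g)
                if i is not None:
                    values[i, j] = w_indirect
                    prov[i, j] = INDIRECT
        for g in ct.direct:  # direct written last: wins over indirect
            i = gi.get(g)
            if i is not None:
                values[i, j] = 1.0
                prov[i, j] = DIRECT

    col_keep = prov.any(axis=0)
    if not col_keep.all():
        dropped = [m for m, k in zip(mirnas, col_keep) if not k]
        logger.info("dropping %d miRNA(s) with no in-universe targets: %s",
                    len(dropped), ", ".join(dropped[:10]))
        values, prov = values[:, col_keep], prov[:, col_keep]
        mirnas = [m for m, k in zip(mirnas, col_keep) if k]
    row_keep = prov.any(axis=1)
    if not row_keep.all():
        logger.info("dropping %d gene(s) with no targeting miRNA", int((~row_keep).sum()))
        values, prov = values[row_keep], prov[row_keep]
        genes = [g for g, k in zip(genes, row_keep) if k]
    if not mirnas or not genes:
        raise ValueError("empty gene universe after restriction")
    return ContextEffectMatrix(genes, mirnas, values, prov, w_indirect=w_indirect)


def align_signature(matrix: ContextEffectMatrix, sig: GeneSignature) -> AlignedResponse:
    """Encode signature membership as a 0/1 response over the matrix rows."""
    universe = set(matrix.gene_index)
    hits = sig.genes & universe
    if not hits:
        raise ValueError(
            f"signature {sig.name!r} has no overlap with model universe"
        )
    dropped = sig.genes - universe
    y = np.array([1.0 if g in hits else 0.0 for g in matrix.gene_index])
    resp = AlignedResponse(y=y, n_in_universe=len(hits), dropped_genes=frozenset(dropped))
    logger.info(
        "signature %s: %d/%d genes in universe (coverage %.2f)",
        sig.name, len(hits), len(sig.genes), resp.coverage,
    )
    return resp
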