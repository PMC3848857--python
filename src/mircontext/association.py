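"""Batch enrichment over signature collections and gold-standard scoring.

Running the influence regression once per disease or pathway signature
yields a bipartite signature-miRNA association network (an edge per
nonzero coefficient).  Against a curated gold standard the network is
scored by overlap counts (common / missed / novel) and by AUC, treating
each candidate (signature, miRNA) pair as a scored instance labeled by
gold membership.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneSignature
from .enrichment import fit_enrichment
from .network import ContextEffectMatrix
from .solver import RegressionConfig

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AssociationNetwork:
    """Bipartite signature-miRNA edges weighted by influence coefficient."""

    edges: frozenset[tuple[str, str, float]]
    threshold_applied: float | None = None

    def __post_init__(self) -> None:
        pairs = [(s, m) for s, m, _ in self.edges]
        if len(pairs) != len(set(pairs)):
            raise ValueError("duplicate (signature, miRNA) pair in network")
        if self.threshold_applied is not None and any(
            c <= self.threshold_applied for _, _, c in self.edges
        ):
            raise ValueError("edge at or below the applied threshold")

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return {(s, m) for s, m, _ in self.edges}

    @property
    def signatures(self) -> set[str]:
        return {s for s, _, _ in self.edges}

    @property
    def mirnas(self) -> set[str]:
        return {m for _, m, _ in self.edges}

    def coefficient(self, signature: str, mirna: str) -> float:
        for s, m, c in self.edges:
            if (s, m) == (signature, mirna):
                return c
        return 0.0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            sorted(self.edges), columns=["signature", "mirna", "coefficient"]
        )
        return df

    def __len__(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class EvaluationReport:
    """Overlap counts and AUC of a predicted network vs a gold standard."""

    n_common: int
    n_missed: int
    n_novel: int
    auc: float
    labeled_pairs: pd.DataFrame  # signature, mirna, score, in_gold

    def summary(self) -> str:
        return (
            f"common={self.n_common} missed={self.n_missed} "
            f"novel={self.n_novel} auc={self.auc:.4f}"
        )


def batch_enrich(
    matrix: ContextEffectMatrix,
    sigs: list[GeneSignature],
    config: RegressionConfig | None = None,
) -> AssociationNetwork:
    """One enrichment fit per signature; edges for nonzero coefficients.

    Signatures with no overlap with the matrix universe are skipped with
    a warning; if every signature is skipped, that is an error.
    """
    config = config or RegressionConfig()
    edges: set[tuple[str, str, float]] = set()
    n_fit = 0
    for sig in sigs:
        try:
            res = fit_enrichment(matrix, sig, config)
        except ValueError as exc:
            if "no overlap" in str(exc):
                logger.warning("skipping signature %s: %s", sig.name, exc)
                continue
            raise
        n_fit += 1
        nz = res.table[res.table["beta"] != 0.0]
        for rec in nz.itertuples(index=False):
            edges.add((sig.name, rec.mirna_id, float(rec.beta)))
    if n_fit == 0:
        raise ValueError("all signatures were skipped (no universe overlap)")
    return AssociationNetwork(edges=frozenset(edges))


def threshold_network(net: AssociationNetwork, min_coef: float = 0.5) -> AssociationNetwork:
    """Keep only highly significant associations: coefficient strictly
    greater than ``min_coef``."""
    kept = frozenset(e for e in net.edges if e[2] > min_coef)
    return AssociationNetwork(edges=kept, threshold_applied=min_coef)


def mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the Mann-Whitney statistic; tied scores contribute 1/2."""
    pos = labels.astype(bool)
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = stats.rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def compare_to_gold(
    net: AssociationNetwork,
    gold: set[tuple[str, str]],
    candidate_space: set[tuple[str, str]] | None = None,
    mirna_universe: set[str] | None = None,
) -> EvaluationReport:
    """Score a predicted network against a gold-standard edge set.

    common = predicted & gold, missed = gold - predicted, novel =
    predicted - gold.  The AUC labels every pair of ``candidate_space``
    (default: the network's signatures crossed with ``mirna_universe``,
    which itself defaults to the miRNAs of the network) by gold
    membership and scores it by its coefficient, 0 if unpredicted.
    Gold pairs whose signature falls outside the candidate space still
    count as missed but are excluded from the AUC, with a warning.
    """
    if not gold:
        raise ValueError("gold standard is empty")
    predicted = net.pairs
    common = predicted & gold
    missed = gold - predicted
    novel = predicted - gold

    if candidate_space is None:
        sigs = sorted(net.signatures)
        mirnas = sorted(mirna_universe if mirna_universe is not None else net.mirnas)
        candidate_space = {(s, m) for s in sigs for m in mirnas}
    outside = {pair for pair in gold if pair not in candidate_space}
    if outside:
        warnings.warn(
            f"{len(outside)} gold pair(s) outside the candidate space; "
            "excluded from AUC but counted as missed",
            stacklevel=2,
        )
    coef = {(s, m): c for s, m, c in net.edges}
    pairs = sorted(candidate_space)
    scores = np.array([coef.get(p, 0.0) for p in pairs])
    labels = np.array([p in gold for p in pairs])
    auc = mann_whitney_auc(scores, labels)
    labeled = pd.DataFrame(
        {
            "signature": [p[0] for p in pairs],
            "mirna": [p[1] for p in pairs],
            "score": scores,
            "in_gold": labels,
        }
    )
    return EvaluationReport(
        n_common=len(common),
        n_missed=len(missed),
        n_novel=len(novel),
        auc=auc,
        labeled_pairs=labeled,
    )
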