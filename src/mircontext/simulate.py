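"""Synthetic benchmark generator with planted ground truth.

Emulates the three data layers the tool consumes — a miRNA-target edge
table, an undirected protein functional-interaction network, and gene
signatures — at a configurable scale, with a known "planted" miRNA whose
targets seed each signature.  This makes every pipeline stage testable
end to end without downloading any database: the generator writes the
same TSV/GMT dialects the readers parse, plus a truth table.

Design choices mirror what is known about real miRNA targetomes:
targets-per-miRNA in the dozens-to-hundreds, a heavy-tailed protein
network, and (optionally) a bias for highly connected proteins to
accumulate miRNA target sites (``hub_bias``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Mapping

import networkx as nx
import numpy as np

from .io import GeneSignature, InteractionTable, ProteinNetwork, write_table
from .network import ContextTargets

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of one synthetic study.

    Scale defaults (305 miRNAs over a 3,235-gene universe) match the
    size of a TargetScan-predictions-restricted-to-a-protein-network
    dataset; the :func:`small_scenario` preset scales down for tests.
    """

    n_mirnas: int = 305
    n_genes: int = 3235
    targets_per_mirna: tuple[int, int] = (60, 120)
    ppi_mean_degree: float = 6.0
    ppi_model: Literal["erdos_renyi", "preferential_attachment"] = "preferential_attachment"
    hub_bias: float = 1.0
    planted: tuple[str, ...] = ("miR-0001",)
    sig_n_direct: int = 60
    sig_n_indirect: int = 20
    sig_n_noise: int = 20
    gold_fp_rate: float = 0.0
    gold_fn_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mirnas < 1 or self.n_genes < 2:
            raise ValueError("need at least 1 miRNA and 2 genes")
        lo, hi = self.targets_per_mirna
        if not 1 <= lo <= hi:
            raise ValueError("targets_per_mirna must satisfy 1 <= min <= max")
        if hi > self.n_genes:
            raise ValueError("targets_per_mirna max exceeds the gene universe")
        if not (0 <= self.gold_fp_rate < 1 and 0 <= self.gold_fn_rate < 1):
            raise ValueError("gold corruption rates must be in [0, 1)")
        if self.hub_bias < 0:
            raise ValueError("hub_bias must be >= 0")

    def gene_ids(self) -> list[str]:
        width = max(4, len(str(self.n_genes)))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    def mirna_ids(self) -> list[str]:
        width = max(4, len(str(self.n_mirnas)))
        return [f"miR-{i:0{width}d}" for i in range(1, self.n_mirnas + 1)]


def small_scenario(**overrides) -> SyntheticScenario:
    """Reduced-scale preset (100 miRNAs, 1,500 genes) used by the test
    suite and quick demonstrations; other defaults unchanged."""
    params = dict(n_mirnas=100, n_genes=1500)
    params.update(overrides)
    return SyntheticScenario(**params)


@dataclass(frozen=True)
class GroundTruth:
    """What was planted: the enriched miRNA(s) behind each signature."""

    planted_by_signature: Mapping[str, tuple[str, ...]]
    true_edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.true_edges:
            raise ValueError("ground truth has no edges")


def _rng(scenario: SyntheticScenario, stage: int) -> np.random.Generator:
    # independent streams per generation stage, all derived from one seed
    return np.random.default_rng(np.random.SeedSequence([scenario.seed, stage]))


def simulate_ppi(scenario: SyntheticScenario) -> ProteinNetwork:
    """Seeded random protein network over the synthetic gene ids."""
    n = scenario.n_genes
    seed = int(_rng(scenario, 1).integers(2**31))
    if scenario.ppi_model == "erdos_renyi":
        g = nx.fast_gnp_random_graph(n, scenario.ppi_mean_degree / (n - 1), seed=seed)
    elif scenario.ppi_model == "preferential_attachment":
        m = max(1, round(scenario.ppi_mean_degree / 2))
        g = nx.barabasi_albert_graph(n, m, seed=seed)
    else:
        raise ValueError(f"unknown ppi_model {scenario.ppi_model!r}")
    ids = scenario.gene_ids()
    return ProteinNetwork((ids[a], ids[b]) for a, b in g.edges)


def simulate_interactions(
    scenario: SyntheticScenario, ppi: ProteinNetwork
) -> InteractionTable:
    """Draw each miRNA's target set, optionally biased toward PPI hubs.

    Target-set size is uniform on ``targets_per_mirna``; genes are
    sampled without replacement with probability proportional to
    ``1 + hub_bias * degree``, so ``hub_bias=0`` is uniform sampling and
    larger values concentrate target sites on well-connected proteins.
    """
    rng = _rng(scenario, 2)
    genes = scenario.gene_ids()
    degree = np.array([ppi.degree(g) for g in genes], dtype=np.float64)
    weights = 1.0 + scenario.hub_bias * degree
    prob = weights / weights.sum()
    lo, hi = scenario.targets_per_mirna
    edges: set[tuple[str, str]] = set()
    for mirna in scenario.mirna_ids():
        k = int(rng.integers(lo, hi + 1))
        chosen = rng.choice(len(genes), size=k, replace=False, p=prob)
        for i in chosen:
            edges.add((mirna, genes[i]))
    return InteractionTable(edges=frozenset(edges), source_tag="synthetic")


def plant_signature(
    context: Mapping[str, ContextTargets],
    scenario: SyntheticScenario,
    name: str = "planted_signature",
) -> tuple[GeneSignature, GroundTruth]:
    """Build a signature seeded by the planted miRNA(s)' targets.

    Samples (without replacement) ``sig_n_direct`` genes from the pooled
    direct targets of the planted miRNAs, ``sig_n_indirect`` from their
    pooled indirect targets, and ``sig_n_noise`` from genes outside
    their context sets but inside some miRNA's context (so noise genes
    survive universe restriction).
    """
    rng = _rng(scenario, 3)
    missing = [m for m in scenario.planted if m not in context]
    if missing:
        raise ValueError(f"planted miRNA(s) not in context mapping: {missing}")
    direct_pool: set[str] = set()
    indirect_pool: set[str] = set()
    for m in scenario.planted:
        direct_pool |= context[m].direct
        indirect_pool |= context[m].indirect
    indirect_pool -= direct_pool
    planted_all = direct_pool | indirect_pool
    noise_pool = set()
    for ct in context.values():
        noise_pool |= ct.all
    noise_pool -= planted_all

    wanted = (
        (sorted(direct_pool), scenario.sig_n_direct, "direct"),
        (sorted(indirect_pool), scenario.sig_n_indirect, "indirect"),
        (sorted(noise_pool), scenario.sig_n_noise, "noise"),
    )
    genes: set[str] = set()
    for pool, k, label in wanted:
        if k > len(pool):
            raise ValueError(
                f"requested {k} {label} genes but pool has only {len(pool)} "
                f"(pools: direct={len(direct_pool)}, indirect={len(indirect_pool)}, "
                f"noise={len(noise_pool)})"
            )
        if k:
            genes |= {pool[i] for i in rng.choice(len(pool), size=k, replace=False)}
    sig = GeneSignature(name=name, genes=frozenset(genes))
    truth = GroundTruth(
        planted_by_signature={name: tuple(scenario.planted)},
        true_edges=frozenset((name, m) for m in scenario.planted),
    )
    return sig, truth


def corrupt_gold(
    truth: GroundTruth, scenario: SyntheticScenario,
    mirna_pool: list[str] | None = None,
) -> set[tuple[str, str]]:
    """Derive a noisy gold standard from the planted truth.

    Each true edge is dropped independently with probability
    ``gold_fn_rate``; ``round(|true| * gold_fp_rate)`` spurious edges
    (pairs not in the truth) are added, drawn over the truth's
    signatures crossed with ``mirna_pool`` (default: all scenario
    miRNAs).  With both rates 0 the gold standard equals the truth.
    """
    rng = _rng(scenario, 4)
    true_edges = sorted(truth.true_edges)
    keep = [e for e in true_edges if rng.random() >= scenario.gold_fn_rate]
    n_fp = round(len(true_edges) * scenario.gold_fp_rate)
    gold = set(keep)
    if n_fp:
        sigs = sorted({s for s, _ in true_edges})
        pool = mirna_pool if mirna_pool is not None else scenario.mirna_ids()
        candidates = sorted(
            {(s, m) for s in sigs for m in pool} - truth.true_edges
        )
        if n_fp > len(candidates):
            raise ValueError("not enough candidate pairs for requested false positives")
        idx = rng.choice(len(candidates), size=n_fp, replace=False)
        gold |= {candidates[i] for i in idx}
    return gold


def write_scenario_files(
    out_dir: str | Path,
    table: InteractionTable,
    ppi: ProteinNetwork,
    sig: GeneSignature,
    truth: GroundTruth,
    gold: set[tuple[str, str]],
) -> dict[str, Path]:
    """Write every generated object in the interchange dialects the
    readers parse, so the CLI can run end to end on generated files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "targets": out / "targets.tsv",
        "ppi": out / "ppi.tsv",
        "signature": out / "signature.txt",
        "gmt": out / "signatures.gmt",
        "truth": out / "truth.tsv",
        "gold": out / "gold.tsv",
    }
    write_table(
        [{"mirna": m, "gene": g} for m, g in sorted(table.edges)], paths["targets"]
    )
    write_table([{"gene_a": a, "gene_b": b} for a, b in ppi.edge_list()], paths["ppi"])
    paths["signature"].write_text("\n".join(sorted(sig.genes)) + "\n")
    paths["gmt"].write_text(
        "\t".join([sig.name, "synthetic planted signature", *sorted(sig.genes)]) + "\n"
    )
    write_table(
        [
            {"signature": s, "mirna": m}
            for s, planted in sorted(truth.planted_by_signature.items())
            for m in planted
        ],
        paths["truth"],
    )
    write_table([{"signature": s, "mirna": m} for s, m in sorted(gold)], paths["gold"])
    return paths
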