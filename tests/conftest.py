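from __future__ import annotations

import numpy as np
import pytest

import mircontext as mc


@pytest.fixture(scope="session")
def tiny_scenario() -> mc.SyntheticScenario:
    """A very small planted scenario for fast structural tests."""
    return mc.small_scenario(
        n_mirnas=20, n_genes=300, targets_per_mirna=(20, 40), ppi_mean_degree=4.0,
        sig_n_direct=18, sig_n_indirect=10, sig_n_noise=5, seed=7,
    )


@pytest.fixture(scope="session")
def tiny_pipeline(tiny_scenario):
    """Generated PPI, target table, context map and design matrix."""
    ppi = mc.simulate_ppi(tiny_scenario)
    table = mc.simulate_interactions(tiny_scenario, ppi)
    context = mc.context_target_map(table, ppi)
    matrix = mc.build_design_matrix(context, ppi_nodes=ppi.nodes)
    return ppi, table, context, matrix


def random_regression(seed: int, n: int = 30, p: int = 8, sparsity: int = 3):
    """A seeded dense regression instance with a sparse true coefficient."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = np.zeros(p)
    beta[:sparsity] = rng.normal(scale=2.0, size=sparsity)
    y = X @ beta + 0.3 * rng.normal(size=n)
    return X, y
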