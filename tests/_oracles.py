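"""Independent oracles used to check the coordinate-descent solver.

The elastic-net objective is reformulated with split positive/negative
parts (beta = bp - bn, bp, bn >= 0), which makes it smooth on a box, and
minimized with bound-constrained L-BFGS-B at high precision.  This path
shares no code with the package solver.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def elastic_net_oracle(
    X: np.ndarray, y: np.ndarray, lambda_: float, alpha: float
) -> tuple[np.ndarray, float]:
    """High-precision minimizer of
    (1/2n)||y - b0 - X beta||^2 + lambda * sum[(1-alpha)/2 beta^2 + alpha|beta|].

    Returns (beta, intercept) on the original scale.
    """
    n, p = X.shape

    def fun_grad(z):
        b0, bp, bn = z[0], z[1 : p + 1], z[p + 1 :]
        beta = bp - bn
        resid = y - b0 - X @ beta
        f = resid @ resid / (2 * n) + lambda_ * np.sum(
            0.5 * (1 - alpha) * beta**2 + alpha * (bp + bn)
        )
        g_beta = -X.T @ resid / n + lambda_ * (1 - alpha) * beta
        g = np.concatenate(
            ([-resid.mean()], g_beta + lambda_ * alpha, -g_beta + lambda_ * alpha)
        )
        return f, g

    z0 = np.zeros(2 * p + 1)
    bounds = [(None, None)] + [(0.0, None)] * (2 * p)
    res = minimize(
        fun_grad, z0, jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 100_000, "ftol": 1e-18, "gtol": 1e-12, "maxfun": 1_000_000},
    )
    b0, bp, bn = res.x[0], res.x[1 : p + 1], res.x[p + 1 :]
    return bp - bn, float(b0)


def hypergeom_tail_enum(overlap: int, universe: int, targets: int, draw: int) -> float:
    """P(X >= overlap) by direct enumeration of the hypergeometric pmf."""
    from math import comb

    if overlap <= 0:
        return 1.0
    denom = comb(universe, draw)
    num = sum(
        comb(targets, k) * comb(universe - targets, draw - k)
        for k in range(overlap, min(targets, draw) + 1)
    )
    return num / denom


def auc_enum(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by exhaustive pairwise comparison (ties count 1/2)."""
    pos = np.flatnonzero(labels)
    neg = np.flatnonzero(~np.asarray(labels, dtype=bool))
    total = 0.0
    for i in pos:
        for j in neg:
            if scores[i] > scores[j]:
                total += 1.0
            elif scores[i] == scores[j]:
                total += 0.5
    return total / (len(pos) * len(neg))
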