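"""Elastic-net least squares by cyclic coordinate descent.

The model regresses a gene-signature membership vector y on the columns
of the miRNA influence matrix X, minimizing

    (1/2n) * sum_i (y_i - b0 - x_i . beta)^2
        + lambda * sum_j [ (1-alpha)/2 * beta_j^2 + alpha * |beta_j| ]

with an unpenalized intercept b0.  alpha = 1 is the lasso, alpha = 0 is
ridge; intermediate alpha keeps groups of correlated predictors while
still producing sparse solutions.  The objective uses the glmnet scaling
convention (the 1/2n data-fit factor), so lambda values are comparable
to glmnet's.

Coordinate descent runs on precomputed Gram products (covariance
updates), which is the right regime here: the number of genes (rows) far
exceeds the number of miRNAs (columns).  Lambda paths are fitted warm-
started from large to small lambda.  The inner loops are JIT-compiled
with numba.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit

logger = logging.getLogger(__name__)

ALPHA_FLOOR = 1e-3  # keeps lambda_max finite as alpha -> 0


@dataclass
class RegressionConfig:
    """Knobs of the penalized fit and its cross-validated model selection.

    alpha : float or "auto"
        Elastic-net mixing parameter in [0, 1].  "auto" selects it by the
        lambda-min stabilization rule (see :func:`optimize_alpha`).
    alpha_grid : grid scanned when alpha="auto"; default 20 evenly spaced
        values from 0 to 1.
    n_lambda, lambda_min_ratio : the penalty path is n_lambda log-spaced
        values from lambda_max down to lambda_max * lambda_min_ratio.
    lambda_ : optional fixed penalty; bypasses cross-validation.
    n_folds : folds for cross-validation (stratified on the 0/1 response).
    standardize : scale predictors to unit variance before fitting;
        coefficients are reported back on the original scale.
    tol : convergence threshold on the max absolute coefficient change
        per sweep (standardized scale).
    """

    alpha: float | str = 0.6
    alpha_grid: tuple[float, ...] = tuple(np.linspace(0.0, 1.0, 20))
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-4
    lambda_: float | None = None
    n_folds: int = 10
    seed: int = 0
    standardize: bool = True
    tol: float = 1e-7
    max_iter: int = 10_000
    stability_tol: float = 0.05

    def __post_init__(self) -> None:
        if self.alpha != "auto" and not 0.0 <= float(self.alpha) <= 1.0:
            raise ValueError("alpha must be in [0, 1] or 'auto'")
        if list(self.alpha_grid) != sorted(self.alpha_grid):
            raise ValueError("alpha_grid must be sorted ascending")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass(frozen=True)
class FitResult:
    """A fitted model at one (alpha, lambda), on the original predictor scale."""

    beta: np.ndarray
    intercept: float
    lambda_: float
    alpha: float
    n_iter: int
    converged: bool

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.beta))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + X @ self.beta


@dataclass(frozen=True)
class CVCurve:
    """Cross-validated error along a descending lambda path."""

    lambdas: np.ndarray
    mean_mse: np.ndarray
    sd_mse: np.ndarray
    lambda_min: float

    def to_frame(self, alpha: float) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "alpha": alpha,
                "lambda": self.lambdas,
                "mean_mse": self.mean_mse,
                "sd_mse": self.sd_mse,
            }
        )


def soft_threshold(z: float, gamma: float) -> float:
    """sign(z) * max(|z| - gamma, 0): the proximal map of gamma*|.|."""
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    return float(np.sign(z) * max(abs(z) - gamma, 0.0))


@njit(cache=True)
def _cd_path(G, c, gdiag, lambdas, alpha, tol, max_iter, beta0):
    """Coordinate descent over a descending lambda path on Gram products.

    G = X'X/n, c = X'y/n, gdiag = diag(G); beta0 is the warm start for
    the first lambda.  Returns (betas, n_iters, converged) per lambda.
    Uses an active-set strategy: after each full sweep, inner sweeps
    touch only currently-nonzero coordinates until they stabilize.
    """
    L, p = lambdas.shape[0], c.shape[0]
    betas = np.zeros((L, p))
    n_iters = np.zeros(L, dtype=np.int64)
    converged = np.zeros(L, dtype=np.bool_)
    beta = beta0.copy()
    for k in range(L):
        lam = lambdas[k]
        thr = lam * alpha
        ridge = lam * (1.0 - alpha)
        it = 0
        done = False
        while it < max_iter and not done:
            # full sweep over all coordinates
            maxd = 0.0
            for j in range(p):
                if gdiag[j] <= 0.0:
                    continue
                z = c[j] - np.dot(G[j], beta) + gdiag[j] * beta[j]
                if z > thr:
                    bnew = (z - thr) / (gdiag[j] + ridge)
                elif z < -thr:
                    bnew = (z + thr) / (gdiag[j] + ridge)
                else:
                    bnew = 0.0
                d = bnew - beta[j]
                if d != 0.0:
                    beta[j] = bnew
                    if abs(d) > maxd:
                        maxd = abs(d)
            it += 1
            if maxd < tol:
                done = True
                break
            # inner sweeps over the active set only
            while it < max_iter:
                maxd = 0.0
                for j in range(p):
                    if beta[j] == 0.0 or gdiag[j] <= 0.0:
                        continue
                    z = c[j] - np.dot(G[j], beta) + gdiag[j] * beta[j]
                    if z > thr:
                        bnew = (z - thr) / (gdiag[j] + ridge)
                    elif z < -thr:
                        bnew = (z + thr) / (gdiag[j] + ridge)
                    else:
                        bnew = 0.0
                    d = bnew - beta[j]
                    if d != 0.0:
                        beta[j] = bnew
                        if abs(d) > maxd:
                            maxd = abs(d)
                it += 1
                if maxd < tol:
                    break
        betas[k] = beta
        n_iters[k] = it
        converged[k] = done or maxd < tol
    return betas, n_iters, converged


@dataclass(frozen=True)
class _Standardized:
    """Centered/scaled design with the statistics needed to back-transform."""

    Xs: np.ndarray
    yc: np.ndarray
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    keep: np.ndarray  # mask of non-constant columns


def _prepare(X: np.ndarray, y: np.ndarray, standardize: bool) -> _Standardized:
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.shape[0]:
        raise ValueError("dimension mismatch between X and y")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in X or y")
    x_mean = X.mean(axis=0)
    sd = X.std(axis=0)  # population sd, glmnet convention
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} constant predictor column(s)",
            stacklevel=3,
        )
    Xc = X[:, keep] - x_mean[keep]
    scale = sd[keep] if standardize else np.ones(keep.sum())
    Xs = Xc / scale
    y_mean = float(y.mean())
    return _Standardized(Xs, y - y_mean, x_mean, scale, y_mean, keep)


def _back_transform(prep: _Standardized, beta_std: np.ndarray, p_full: int) -> tuple[np.ndarray, float]:
    beta = np.zeros(p_full)
    beta[prep.keep] = beta_std / prep.x_scale
    intercept = prep.y_mean - float(prep.x_mean @ beta)
    return beta, intercept


def coordinate_descent(
    X: np.ndarray,
    y: np.ndarray,
    lambda_: float,
    alpha: float,
    config: RegressionConfig | None = None,
    warm_start: np.ndarray | None = None,
) -> FitResult:
    """Fit the elastic net at one (alpha, lambda) by coordinate descent.

    Constant (zero-variance) columns are dropped with a warning and get
    coefficient 0.  Coefficients are returned on the original predictor
    scale; the intercept is unpenalized.
    """
    config = config or RegressionConfig()
    if lambda_ < 0:
        raise ValueError("lambda must be >= 0")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    X = np.asarray(X, dtype=np.float64)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    prep = _prepare(X, y, config.standardize)
    n = X.shape[0]
    G = prep.Xs.T @ prep.Xs / n
    c = prep.Xs.T @ prep.yc / n
    beta0 = np.zeros(c.shape[0])
    if warm_start is not None:
        ws = np.asarray(warm_start, dtype=np.float64)[prep.keep]
        beta0 = ws * prep.x_scale  # original -> standardized scale
    betas, n_iters, conv = _cd_path(
        G, c, np.diag(G).copy(), np.array([lambda_]), float(alpha),
        config.tol, config.max_iter, beta0,
    )
    if not conv[0]:
        warnings.warn(
            f"coordinate descent did not converge in {config.max_iter} sweeps",
            stacklevel=2,
        )
    beta, intercept = _back_transform(prep, betas[0], X.shape[1])
    return FitResult(
        beta=beta, intercept=intercept, lambda_=float(lambda_),
        alpha=float(alpha), n_iter=int(n_iters[0]), converged=bool(conv[0]),
    )


def elastic_net_objective(
    X: np.ndarray, y: np.ndarray, beta: np.ndarray, intercept: float,
    lambda_: float, alpha: float,
) -> float:
    """The penalized objective this solver minimizes (original scale)."""
    n = X.shape[0]
    resid = y - intercept - X @ beta
    penalty = lambda_ * np.sum(0.5 * (1 - alpha) * beta**2 + alpha * np.abs(beta))
    return float(resid @ resid / (2 * n) + penalty)


def compute_lambda_max(
    X: np.ndarray, y: np.ndarray, alpha: float, standardize: bool = True
) -> float:
    """Smallest penalty at which every penalized coefficient is zero.

    Computed as max_j |<x_j, y - ybar>| / (n * max(alpha, 1e-3)); the
    floor keeps the path anchor finite in the ridge limit.
    """
    prep = _prepare(X, y, standardize)
    if not np.any(prep.yc):
        raise ValueError("degenerate response: y is constant after centering")
    n = X.shape[0]
    return float(np.max(np.abs(prep.Xs.T @ prep.yc)) / (n * max(alpha, ALPHA_FLOOR)))


def lambda_path(lambda_max: float, n_lambda: int = 100, ratio: float = 1e-4) -> np.ndarray:
    """Log-spaced descending path from lambda_max to lambda_max * ratio."""
    if n_lambda < 2:
        raise ValueError("n_lambda must be >= 2")
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be in (0, 1)")
    return lambda_max * np.logspace(0.0, np.log10(ratio), n_lambda)


def _stratified_folds(y: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Seeded fold labels, stratified on the response when it is discrete
    (the 0/1 membership case) so every fold sees signature members; plain
    shuffled folds otherwise."""
    rng = np.random.default_rng(seed)
    fold = np.empty(len(y), dtype=np.int64)
    classes = np.unique(y)
    if len(classes) <= max(2, len(y) // (2 * n_folds)):
        start = 0  # rotate the fold offset so no fold is left empty overall
        for cls in classes:
            idx = np.flatnonzero(y == cls)
            rng.shuffle(idx)
            fold[idx] = (np.arange(len(idx)) + start) % n_folds
            start += len(idx)
    else:
        idx = rng.permutation(len(y))
        fold[idx] = np.arange(len(y)) % n_folds
    return fold


def kfold_cv(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    lambdas: np.ndarray,
    n_folds: int = 10,
    seed: int = 0,
    config: RegressionConfig | None = None,
) -> CVCurve:
    """Cross-validated mean squared error along a lambda path.

    Folds are assigned deterministically from the seed, stratified on the
    response.  Each fold fits the whole path warm-started; held-out MSE
    is averaged across folds.  lambda_min is the path value minimizing
    the mean MSE, ties resolved toward the larger (sparser) lambda.
    """
    config = config or RegressionConfig()
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    lambdas = np.asarray(lambdas, dtype=np.float64)
    if X.shape[0] < n_folds:
        raise ValueError("need at least n_folds samples")
    fold = _stratified_folds(y, n_folds, seed)
    fold_mse = []
    skipped = 0
    for f in range(n_folds):
        tr, te = fold != f, fold == f
        if not te.any():
            continue
        if np.ptp(y[tr]) == 0:
            warnings.warn(f"fold {f}: constant training response; skipped", stacklevel=2)
            skipped += 1
            continue
        prep = _prepare(X[tr], y[tr], config.standardize)
        n_tr = int(tr.sum())
        G = prep.Xs.T @ prep.Xs / n_tr
        betas, _, _ = _cd_path(
            G, prep.Xs.T @ prep.yc / n_tr, np.diag(G).copy(), lambdas,
            float(alpha), config.tol, config.max_iter, np.zeros(G.shape[0]),
        )
        mses = np.empty(len(lambdas))
        for k in range(len(lambdas)):
            beta, intercept = _back_transform(prep, betas[k], X.shape[1])
            resid = y[te] - intercept - X[te] @ beta
            mses[k] = float(resid @ resid / len(resid))
        fold_mse.append(mses)
    if skipped > n_folds / 2:
        raise ValueError(f"{skipped}/{n_folds} folds skipped (constant response)")
    M = np.vstack(fold_mse)
    mean_mse = M.mean(axis=0)
    sd_mse = M.std(axis=0, ddof=1) if M.shape[0] > 1 else np.zeros(len(lambdas))
    # lambdas descend, so the first argmin is the largest lambda at the min
    lambda_min = float(lambdas[int(np.argmin(mean_mse))])
    return CVCurve(lambdas=lambdas, mean_mse=mean_mse, sd_mse=sd_mse, lambda_min=lambda_min)


def optimize_alpha(
    X: np.ndarray, y: np.ndarray, config: RegressionConfig
) -> tuple[float, pd.DataFrame]:
    """Pick alpha by lambda-min stabilization over an alpha grid.

    For each grid alpha, the cross-validated lambda_min is computed; the
    selected alpha is the smallest one from which lambda_min stays within
    ``stability_tol`` relative change across all subsequent grid points.
    If the curve never stabilizes, falls back to 0.6 with a warning.
    Returns (alpha_star, table of per-alpha lambda_min values).
    """
    grid = [float(a) for a in config.alpha_grid]
    lmins: list[float] = []
    for a in grid:
        lmax = compute_lambda_max(X, y, a, config.standardize)
        path = lambda_path(lmax, config.n_lambda, config.lambda_min_ratio)
        curve = kfold_cv(X, y, a, path, config.n_folds, config.seed, config)
        lmins.append(curve.lambda_min)
    table = pd.DataFrame({"alpha": grid, "lambda_min": lmins})
    alpha_star = select_stable_alpha(grid, lmins, config.stability_tol)
    if alpha_star is None:
        warnings.warn(
            "lambda_min never stabilized across the alpha grid; falling back to alpha=0.6",
            stacklevel=2,
        )
        alpha_star = 0.6
    return float(alpha_star), table


def select_stable_alpha(
    alphas: Sequence[float], lambda_mins: Sequence[float], stability_tol: float = 0.05
) -> float | None:
    """Smallest alpha after which lambda_min changes by < stability_tol
    (relative) between every subsequent pair of grid points; None if the
    sequence never settles.  A single-point grid trivially qualifies."""
    k = len(alphas)
    if k == 1:
        return float(alphas[0])
    rel = [
        abs(lambda_mins[i + 1] - lambda_mins[i]) / abs(lambda_mins[i])
        for i in range(k - 1)
    ]
    for i in range(k - 1):
        if all(r < stability_tol for r in rel[i:]):
            return float(alphas[i])
    return None
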