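"""Comparator inference methods: least squares, Zscore, and LASSO.

All three share the row-decoupled linear model p_i = H a_i + e with
H = -Y^T, return a full signed N x N weight matrix in the columns-to-rows
edge convention, and defer binarization to the evaluation threshold sweep.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import Lasso
from sklearn.model_selection import KFold

from .core import design_from_data

__all__ = [
    "BaselineResult",
    "lsco_inference",
    "zscore_inference",
    "lasso_inference",
]

logger = logging.getLogger(__name__)


@dataclass
class BaselineResult:
    """Signed weight matrix produced by a comparator method."""

    weights: np.ndarray
    method_name: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.all(np.isfinite(self.weights)):
            raise ValueError(f"{self.method_name}: non-finite weights")


def _check_shapes(Y: np.ndarray, P: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    Y = np.asarray(Y, dtype=float)
    P = np.asarray(P, dtype=float)
    if Y.shape != P.shape:
        raise ValueError(f"Y has shape {Y.shape} but P has shape {P.shape}")
    return Y, P


def lsco_inference(Y: np.ndarray, P: np.ndarray) -> BaselineResult:
    """Least-squares estimate of the network (LSCO family, no cutoff).

    Solves every row problem p_i = H a_i at once via the pseudo-inverse,
    which gives the minimum-norm solution when H is rank-deficient.
    """
    Y, P = _check_shapes(Y, P)
    H = design_from_data(Y)
    A = np.linalg.pinv(H) @ P.T  # column i = a_i
    return BaselineResult(weights=A.T, method_name="lsco", params={})


def zscore_inference(Y: np.ndarray, P: np.ndarray) -> BaselineResult:
    """Knockdown z-score weights.

    Each gene's expression row is standardized with its population mean and
    standard deviation across all experiments; weight(i, j) is gene i's mean
    standardized response over the experiments in which P perturbs gene j.
    A constant expression row yields zero weights for that target gene.
    """
    Y, P = _check_shapes(Y, P)
    n = Y.shape[0]
    mean = Y.mean(axis=1, keepdims=True)
    sd = Y.std(axis=1, keepdims=True)  # population sd (ddof=0)
    Z = np.zeros_like(Y)
    degenerate = sd[:, 0] == 0.0
    if degenerate.any():
        logger.warning(
            "zscore: %d gene row(s) with zero standard deviation set to 0",
            int(degenerate.sum()),
        )
    ok = ~degenerate
    Z[ok] = (Y[ok] - mean[ok]) / sd[ok]
    weights = np.zeros((n, n))
    perturbed = P != 0.0  # column k of P perturbs the genes flagged here
    for j in range(n):
        cols = perturbed[j]
        if cols.any():
            weights[:, j] = Z[:, cols].mean(axis=1)
    return BaselineResult(weights=weights, method_name="zscore", params={})


def _lasso_path_row(H: np.ndarray, p: np.ndarray, lam: float) -> np.ndarray:
    """Single L1 fit minimizing 1/2 ||p - Ha||^2 + lam ||a||_1."""
    m = H.shape[0]
    if lam == 0.0:
        return np.linalg.pinv(H) @ p
    # sklearn minimizes 1/(2M)||.||^2 + alpha||.||_1 -> alpha = lam / M
    model = Lasso(alpha=lam / m, fit_intercept=False, max_iter=50_000, tol=1e-8)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(H, p)
    return model.coef_.copy()


def lasso_inference(
    Y: np.ndarray,
    P: np.ndarray,
    lambda_grid: list[float] | None = None,
    selection: str = "cv",
    n_folds: int = 5,
    seed: int = 0,
) -> BaselineResult:
    """Per-row L1-penalized regression over a penalty grid.

    The penalty convention is 1/2 ||p - Ha||^2 + lambda ||a||_1. With
    ``selection="cv"`` each row's lambda minimizes seeded K-fold
    cross-validated squared error; ``selection="fixed"`` (also the fallback
    when there are too few measurements to fold) uses the first grid value.
    """
    Y, P = _check_shapes(Y, P)
    if lambda_grid is None:
        lambda_grid = list(np.logspace(-3.0, 0.0, 10))
    if not lambda_grid or any(l < 0 for l in lambda_grid):
        raise ValueError("lambda_grid must be nonempty with nonnegative values")
    H = design_from_data(Y)
    m, n = H.shape
    use_cv = selection == "cv" and len(lambda_grid) > 1 and m >= 2 * n_folds
    weights = np.zeros((n, n))
    chosen = np.zeros(n)
    if use_cv:
        folds = list(KFold(n_folds, shuffle=True, random_state=seed).split(H))
    for i in range(n):
        p = P[i]
        if use_cv:
            errs = np.zeros(len(lambda_grid))
            for train, test in folds:
                for k, lam in enumerate(lambda_grid):
                    a = _lasso_path_row(H[train], p[train], lam)
                    errs[k] += float(np.sum((p[test] - H[test] @ a) ** 2))
            lam = lambda_grid[int(np.argmin(errs))]
        else:
            lam = lambda_grid[0]
        weights[i] = _lasso_path_row(H, p, lam)
        chosen[i] = lam
    return BaselineResult(
        weights=weights,
        method_name="lasso",
        params={
            "lambda_grid": list(map(float, lambda_grid)),
            "selection": "cv" if use_cv else "fixed",
            "chosen_lambda": chosen,
            "seed": seed,
        },
    )
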