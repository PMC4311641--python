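"""Semantic gating: predicting the mixture component from a second brain area.

High-level visual areas carry category information that the low-level
encoding model does not.  Gating learns ``P(c|z)`` with l1-penalized
multinomial logistic regression,

    P(c|z) = exp(alpha_c + gamma_c' z) / sum_k exp(alpha_k + gamma_k' z),

maximizing the objective ``(1/N) sum_i log P(c_i|z_i) - lambda *
sum_k ||gamma_k||_1`` (intercepts unpenalized) by proximal gradient ascent
with soft-thresholding.  The fitted per-trial log-probabilities replace
the uniform mixture weights in the decoder's responsibility computation.

The softmax is over-parameterized (one weight vector per class, no
reference class); the l1 penalty plus a zero-mean constraint on the
intercepts resolves the identifiability.  The proximal step size 1/Lip,
with Lip half the largest eigenvalue of the augmented Gram matrix divided
by N, guarantees the penalized objective never decreases across
iterations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "GatingModel",
    "gating_probabilities",
    "fit_gating",
    "lambda_max",
    "make_penalty_grid",
    "select_gating_penalty",
    "gated_log_weights",
]

logger = logging.getLogger(__name__)


@dataclass
class GatingModel:
    """Fitted multinomial-logistic gate: intercepts, sparse weights, penalty."""

    intercepts: np.ndarray  # (K,)
    weights: np.ndarray  # (K, q')
    penalty: float
    class_order: np.ndarray  # (K,)
    objective_path: np.ndarray | None = None

    @property
    def n_classes(self) -> int:
        return self.intercepts.shape[0]

    @property
    def n_features(self) -> int:
        return self.weights.shape[1]


def _log_probs(A: np.ndarray, G: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Row-wise log softmax of alpha_k + gamma_k' z, shape (N, K)."""
    eta = Z @ G.T + A[None, :]
    return eta - logsumexp(eta, axis=1, keepdims=True)


def gating_probabilities(model: GatingModel, z: np.ndarray) -> np.ndarray:
    """``P(c|z)`` for a single response vector, via log-sum-exp."""
    z = np.asarray(z, dtype=float)
    if z.shape != (model.n_features,):
        raise ValueError(
            f"expected a length-{model.n_features} response, got {z.shape}"
        )
    lp = _log_probs(model.intercepts, model.weights, z[None, :])
    return np.exp(lp[0])


def _encode_classes(classes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    class_order = np.unique(classes)
    lookup = {c: k for k, c in enumerate(class_order)}
    y = np.array([lookup[c] for c in classes], dtype=int)
    return y, class_order


def _objective(
    A: np.ndarray, G: np.ndarray, Z: np.ndarray, Yind: np.ndarray, penalty: float
) -> float:
    lp = _log_probs(A, G, Z)
    loglik = float(np.sum(Yind * lp)) / Z.shape[0]
    return loglik - penalty * float(np.abs(G).sum())


def fit_gating(
    Z: np.ndarray,
    classes: np.ndarray,
    penalty: float,
    max_iter: int = 1000,
    tol: float = 1e-6,
    warm_start: tuple[np.ndarray, np.ndarray] | None = None,
) -> GatingModel:
    """Fit the l1-penalized multinomial logistic gate.

    Accelerated proximal gradient ascent (monotone FISTA) on the mean
    log-likelihood with soft-thresholding of the weights; intercepts are
    unpenalized and kept zero-mean.  The monotone safeguard keeps the
    kept iterate whenever the accelerated step would lower the penalized
    objective, so the objective path never decreases.  Stops when the
    relative objective change falls below ``tol``; warns if ``max_iter``
    is reached first, and warns on apparent perfect separation when
    ``penalty == 0``.  ``warm_start`` seeds the iteration with
    ``(intercepts, weights)`` from a neighboring penalty.
    """
    Z = np.asarray(Z, dtype=float)
    if not np.all(np.isfinite(Z)):
        raise ValueError("Z must be finite")
    classes = np.asarray(classes)
    if penalty < 0:
        raise ValueError("penalty must be nonnegative")
    y, class_order = _encode_classes(classes)
    K = class_order.size
    if K < 2:
        raise ValueError("need at least 2 classes")
    N, q = Z.shape
    Yind = np.zeros((N, K))
    Yind[np.arange(N), y] = 1.0

    # Lipschitz bound for the multinomial log-likelihood gradient:
    # 1/2 * lambda_max([1 Z]'[1 Z]) / N
    Zaug = np.hstack([np.ones((N, 1)), Z])
    smax = np.linalg.svd(Zaug, compute_uv=False)[0]
    step = 1.0 / max(0.5 * smax**2 / N, 1e-12)

    if warm_start is not None:
        A = np.array(warm_start[0], dtype=float)
        G = np.array(warm_start[1], dtype=float)
    else:
        A = np.zeros(K)
        G = np.zeros((K, q))

    def prox_step(Av, Gv):
        P = np.exp(_log_probs(Av, Gv, Z))
        resid = Yind - P  # (N, K)
        An = Av + step * resid.mean(axis=0)
        An = An - An.mean()  # identifiability: zero-mean intercepts
        Gn = Gv + step * (resid.T @ Z / N)
        Gn = np.sign(Gn) * np.maximum(np.abs(Gn) - step * penalty, 0.0)
        return An, Gn

    Av, Gv = A, G  # momentum point
    t_k = 1.0
    path = [_objective(A, G, Z, Yind, penalty)]
    for it in range(max_iter):
        Az, Gz = prox_step(Av, Gv)
        obj_z = _objective(Az, Gz, Z, Yind, penalty)
        if obj_z < path[-1]:
            # momentum overshot: restart at the current best point, where
            # a plain proximal step with step <= 1/L cannot decrease the
            # objective
            t_k = 1.0
            Az, Gz = prox_step(A, G)
            obj_z = _objective(Az, Gz, Z, Yind, penalty)
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_k**2))
        Av = Az + ((t_k - 1.0) / t_next) * (Az - A)
        Gv = Gz + ((t_k - 1.0) / t_next) * (Gz - G)
        A_prev, G_prev = A, G
        A, G = Az, Gz
        t_k = t_next
        path.append(obj_z)
        denom = max(abs(path[-2]), 1e-12)
        if abs(obj_z - path[-2]) <= tol * denom:
            break
    else:
        warnings.warn(
            f"gating fit did not converge in {max_iter} iterations "
            f"(final objective {path[-1]:.6g})",
            RuntimeWarning,
        )
    if penalty == 0 and np.abs(G).max() > 50:
        warnings.warn(
            "weights diverging at penalty = 0: classes may be perfectly "
            "separable",
            RuntimeWarning,
        )
    return GatingModel(
        intercepts=A,
        weights=G,
        penalty=float(penalty),
        class_order=class_order,
        objective_path=np.asarray(path),
    )


def lambda_max(Z: np.ndarray, classes: np.ndarray) -> float:
    """Smallest penalty at which all gating weights are exactly zero.

    At gamma = 0 with intercepts at the class-frequency optimum, the
    largest absolute component of the log-likelihood gradient with respect
    to the weights bounds the sub-gradient condition for an all-zero
    solution.
    """
    Z = np.asarray(Z, dtype=float)
    y, class_order = _encode_classes(np.asarray(classes))
    K = class_order.size
    N = Z.shape[0]
    Yind = np.zeros((N, K))
    Yind[np.arange(N), y] = 1.0
    freqs = Yind.mean(axis=0)
    grad = (Yind - freqs[None, :]).T @ Z / N
    return float(np.abs(grad).max())


def make_penalty_grid(
    Z: np.ndarray, classes: np.ndarray, n_points: int = 20, decades: float = 3.0
) -> np.ndarray:
    """Log-spaced penalty grid from lambda_max down by ``decades``, ascending."""
    lmax = lambda_max(Z, classes)
    if lmax <= 0:
        lmax = 1e-4
    return np.logspace(np.log10(lmax) - decades, np.log10(lmax), n_points)


def select_gating_penalty(
    Z: np.ndarray,
    classes: np.ndarray,
    n_folds: int = 10,
    penalty_grid: np.ndarray | None = None,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> float:
    """Penalty maximizing mean held-out log-likelihood over stratified folds.

    Ties are broken toward the larger penalty (sparser model).
    """
    Z = np.asarray(Z, dtype=float)
    classes = np.asarray(classes)
    if penalty_grid is None:
        penalty_grid = make_penalty_grid(Z, classes)
    penalty_grid = np.sort(np.asarray(penalty_grid, dtype=float))
    if Z.shape[0] < n_folds:
        raise ValueError("need at least n_folds trials")
    splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    scores = np.zeros(penalty_grid.size)
    for train, test in splitter.split(Z, classes):
        # walk the grid from sparse to dense with warm starts, glmnet-style
        warm = None
        for j in range(penalty_grid.size - 1, -1, -1):
            lam = penalty_grid[j]
            m = fit_gating(
                Z[train], classes[train], lam, max_iter, tol, warm_start=warm
            )
            warm = (m.intercepts, m.weights)
            lp = _log_probs(m.intercepts, m.weights, Z[test])
            # map held-out classes onto the fitted class order; unseen
            # classes in a fold contribute the worst possible likelihood
            order = {c: k for k, c in enumerate(m.class_order)}
            ll = 0.0
            for i, c in zip(range(test.size), classes[test]):
                if c in order:
                    ll += lp[i, order[c]]
                else:  # pragma: no cover - stratification prevents this
                    ll += -745.0
            scores[j] += ll / test.size
    scores /= n_folds
    # ties toward larger penalty: scan from the large end
    best = scores.size - 1 - int(np.argmax(scores[::-1]))
    logger.info(
        "gating penalty %.4g (mean held-out loglik %.4f)",
        penalty_grid[best], scores[best],
    )
    return float(penalty_grid[best])


def gated_log_weights(model: GatingModel, Z_test: np.ndarray) -> np.ndarray:
    """Per-trial ``log P(c|z)`` matrix to use as decoder prior weights.

    Rows exponentiate to simplex vectors; pass the result to
    ``decode_batch(..., gating_log_weights=...)`` so it replaces the
    uniform ``log pi_c`` term of the responsibility computation.  The
    caller must ensure ``model.class_order`` matches the prior's component
    order.
    """
    Z_test = np.asarray(Z_test, dtype=float)
    if Z_test.ndim != 2 or Z_test.shape[1] != model.n_features:
        raise ValueError("Z_test shape does not match the fitted gate")
    return _log_probs(model.intercepts, model.weights, Z_test)
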