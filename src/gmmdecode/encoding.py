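"""Linear Gaussian encoding model fit voxel-by-voxel with ridge regression.

The forward model is ``y = B'x + eps`` with ``eps ~ N(0, diag(sigma2))``:
each voxel responds linearly to the pixel vector of the presented image,
with independent Gaussian noise.  Each voxel's weight vector is the ridge
estimate ``beta = (X'X + lambda I)^{-1} X'y`` at a penalty chosen per voxel
on a grid placed by effective degrees of freedom, using K-fold
cross-validated residual variance.  The same cross-validated residuals at
the chosen penalty provide the voxel noise variance ``sigma2``; voxels with
``sigma2 <= threshold`` (default 0.99, on per-voxel standardized responses)
are flagged as informative and used by the decoder.

The SVD of the design matrix is computed once per fold and reused across
the full penalty grid and all voxels, so fitting scales with the number of
trials rather than the number of pixels cubed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from .containers import ImageSet, ResponseSet

__all__ = [
    "EncodingConfig",
    "EncodingModel",
    "SingularSystemError",
    "fit_ridge",
    "fit_ridge_svd_path",
    "make_lambda_grid",
    "select_lambda",
    "estimate_noise",
    "select_voxels",
    "fit_encoding_model",
]

logger = logging.getLogger(__name__)

#: relative singular-value cutoff below which directions count as null space
RANK_RTOL = 1e-12


class SingularSystemError(np.linalg.LinAlgError):
    """Raised when an unpenalized ridge system has no unique solution."""


@dataclass
class EncodingConfig:
    """Settings for fitting the encoding model.

    ``grid_size`` is the number of penalties on the effective-degrees-of-
    freedom grid; ``voxel_variance_threshold`` is the cross-validated noise
    variance above which a voxel is considered uninformative (responses are
    standardized to unit variance, so 0.99 means "barely better than
    predicting the mean").
    """

    n_folds: int = 5
    grid_size: int = 30
    voxel_variance_threshold: float = 0.99
    seed: int = 0
    center_residuals: bool = True

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.grid_size < 2:
            raise ValueError("grid_size must be >= 2")
        if not (0 < self.voxel_variance_threshold <= 1):
            raise ValueError("voxel_variance_threshold must lie in (0, 1]")


@dataclass
class EncodingModel:
    """Fitted per-voxel ridge weights, penalties, noise variances and mask.

    ``B`` is pixels-by-voxels; column ``i`` is the ridge solution for voxel
    ``i`` at penalty ``lambdas[i]`` on the full (standardized) training set.
    ``response_mean`` / ``response_std`` store the per-voxel affine
    standardization estimated on the training responses; apply it to any
    test responses with :meth:`standardize`.
    """

    B: np.ndarray
    sigma2: np.ndarray
    lambdas: np.ndarray
    selected: np.ndarray
    response_mean: np.ndarray
    response_std: np.ndarray
    threshold: float
    seed: int
    lambda_grid: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n_pixels(self) -> int:
        return self.B.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.B.shape[1]

    def standardize(self, Y: np.ndarray) -> np.ndarray:
        """Apply the stored training standardization to responses ``Y``."""
        return (np.asarray(Y, dtype=float) - self.response_mean) / self.response_std


# ---------------------------------------------------------------------------
# core ridge algebra


def _validate_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("inputs must be finite")
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if y.shape[0] != X.shape[0]:
        raise ValueError("X and y disagree on the number of trials")
    return X, y


def _thin_svd(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Thin SVD with near-zero singular values dropped."""
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    if s.size == 0 or s[0] <= 0:
        raise ValueError("X has no nonzero singular value")
    keep = s > s[0] * RANK_RTOL
    return U[:, keep], s[keep], Vt[keep]


def fit_ridge(X: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Ridge solution ``(X'X + lam I)^{-1} X'y`` for a single target.

    With ``lam = 0`` the system must be nonsingular (full column rank);
    otherwise a :class:`SingularSystemError` is raised rather than silently
    returning one of infinitely many minimizers.
    """
    X, y = _validate_xy(X, y)
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    p = X.shape[1]
    if lam == 0:
        _, s, _ = np.linalg.svd(X, full_matrices=False)
        if s.size < p or s[-1] <= s[0] * RANK_RTOL:
            raise SingularSystemError(
                "X'X is singular at lam = 0; the ridge solution is not unique"
            )
    A = X.T @ X + lam * np.eye(p)
    from scipy.linalg import solve

    return solve(A, X.T @ y, assume_a="pos")


def fit_ridge_svd_path(
    X: np.ndarray, y: np.ndarray, grid: np.ndarray
) -> np.ndarray:
    """Ridge solutions for every penalty in ``grid`` from one SVD of ``X``.

    Returns a ``p x len(grid)`` matrix whose column ``j`` equals
    ``fit_ridge(X, y, grid[j])``.
    """
    X, y = _validate_xy(X, y)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("penalty grid must be nonempty")
    if np.any(grid < 0):
        raise ValueError("penalties must be nonnegative")
    U, s, Vt = _thin_svd(X)
    if np.any(grid == 0) and s.size < X.shape[1]:
        raise SingularSystemError(
            "grid contains lam = 0 but X is rank deficient"
        )
    uy = U.T @ y  # (r,)
    # shrinkage factors s / (s^2 + lam), shape (r, L)
    shrink = s[:, None] / (s[:, None] ** 2 + grid[None, :])
    return Vt.T @ (shrink * uy[:, None])


def effective_df(s: np.ndarray, lam: float) -> float:
    """Effective degrees of freedom of a ridge fit: sum d^2 / (d^2 + lam)."""
    return float(np.sum(s**2 / (s**2 + lam)))


def make_lambda_grid(X: np.ndarray, L: int) -> np.ndarray:
    """Penalty grid whose effective degrees of freedom are evenly spaced.

    The L df targets run from ``rank(X)`` (attained at lam = 0) down to
    ``rank(X)/L``; each penalty is found by monotone bisection to within
    1e-6 in df.  Returned penalties are increasing.
    """
    X = np.asarray(X, dtype=float)
    if L < 1:
        raise ValueError("L must be >= 1")
    _, s, _ = _thin_svd(X)
    rank = s.size
    targets = np.linspace(rank, rank / L, L)
    grid = np.empty(L)
    for j, t in enumerate(targets):
        if t >= rank:
            grid[j] = 0.0
            continue
        lo, hi = 0.0, 1.0
        while effective_df(s, hi) > t:
            hi *= 10.0
        # df is strictly decreasing in lam: bisect
        mid = 0.5 * (lo + hi)
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if abs(effective_df(s, mid) - t) < 1e-6:
                break
            if effective_df(s, mid) > t:
                lo = mid
            else:
                hi = mid
        grid[j] = mid
    return grid


# ---------------------------------------------------------------------------
# cross-validation machinery (vectorized over targets)


def _make_folds(
    n: int, n_folds: int, seed: int, labels: np.ndarray | None = None
) -> list[np.ndarray]:
    """Seeded shuffled K-fold test-index lists, stratified when labels exist."""
    if n < n_folds:
        raise ValueError("need at least n_folds trials")
    idx = np.arange(n)
    if labels is not None:
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        return [test for _, test in splitter.split(idx, labels)]
    splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [test for _, test in splitter.split(idx)]


def _cv_residuals_multi(
    X: np.ndarray,
    Y: np.ndarray,
    grid: np.ndarray,
    folds: list[np.ndarray],
) -> np.ndarray:
    """Held-out residuals for every (trial, target, penalty).

    Returns an (N, q, L) array: residual of trial ``n`` for target ``j`` when
    that trial's fold is held out and the model is fit at ``grid[l]`` on the
    complement.
    """
    N, q = Y.shape
    L = grid.size
    R = np.empty((N, q, L))
    all_idx = np.arange(N)
    for test in folds:
        if test.size == 0:
            raise ValueError("cross-validation fold has zero trials")
        train = np.setdiff1d(all_idx, test, assume_unique=False)
        U, s, Vt = _thin_svd(X[train])
        UtY = U.T @ Y[train]  # (r, q)
        Xv = X[test]
        XvV = Xv @ Vt.T  # (n_test, r)
        for l, lam in enumerate(grid):
            shrink = s / (s**2 + lam)  # (r,)
            # predictions on the held-out fold: Xv V diag(shrink) U'Y
            pred = XvV @ (shrink[:, None] * UtY)
            R[test, :, l] = Y[test] - pred
    return R


def _pick_lambdas(
    resid: np.ndarray, grid: np.ndarray, center: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Per-target penalty index minimizing residual variance, ties -> larger lam.

    Returns (chosen index per target, residual variance matrix (q, L)).
    """
    ddof_resid = resid - resid.mean(axis=0, keepdims=True) if center else resid
    var = np.mean(ddof_resid**2, axis=0)  # (q, L) population variance
    # ties broken toward larger lam: scan the reversed grid for the argmin
    rev = var[:, ::-1]
    idx = var.shape[1] - 1 - np.argmin(rev, axis=1)
    return idx, var


def select_lambda(
    X: np.ndarray,
    y: np.ndarray,
    grid: np.ndarray,
    n_folds: int = 5,
    seed: int = 0,
    labels: np.ndarray | None = None,
    center_residuals: bool = True,
) -> tuple[float, np.ndarray]:
    """Choose the grid penalty minimizing cross-validated residual variance.

    The held-out residuals from all K folds are concatenated (in trial
    order) and their population variance is the selection criterion; ties
    are broken toward the larger penalty.  Returns ``(lambda_hat,
    residuals)`` where ``residuals`` is the (N, L) held-out residual matrix.
    """
    X, y = _validate_xy(X, y)
    grid = np.asarray(grid, dtype=float)
    folds = _make_folds(X.shape[0], n_folds, seed, labels)
    R = _cv_residuals_multi(X, y[:, None], grid, folds)
    idx, _ = _pick_lambdas(R, grid, center_residuals)
    return float(grid[idx[0]]), R[:, 0, :]


def estimate_noise(
    X: np.ndarray,
    y: np.ndarray,
    lambda_hat: float,
    n_folds: int = 5,
    seed: int = 0,
    labels: np.ndarray | None = None,
    center_residuals: bool = True,
) -> float:
    """Noise variance = variance of cross-validated residuals at ``lambda_hat``.

    Uses the same seeded fold partition as :func:`select_lambda`.  A
    zero-variance residual vector (noiseless fit) is floored at machine
    epsilon with a warning, keeping downstream ``1/sigma2`` finite.
    """
    X, y = _validate_xy(X, y)
    folds = _make_folds(X.shape[0], n_folds, seed, labels)
    R = _cv_residuals_multi(X, y[:, None], np.array([lambda_hat]), folds)
    r = R[:, 0, 0]
    if center_residuals:
        r = r - r.mean()
    var = float(np.mean(r**2))
    if var < np.finfo(float).eps:
        warnings.warn(
            "cross-validated residuals have zero variance; flooring sigma2 "
            "at machine epsilon",
            RuntimeWarning,
        )
        var = float(np.finfo(float).eps)
    return var


def select_voxels(sigma2: np.ndarray, threshold: float) -> np.ndarray:
    """Informative-voxel mask: ``sigma2 <= threshold`` (boundary inclusive)."""
    sigma2 = np.asarray(sigma2, dtype=float)
    if not np.all(np.isfinite(sigma2)):
        raise ValueError("sigma2 must be finite")
    mask = sigma2 <= threshold
    if not mask.any():
        raise ValueError(
            f"no voxel has sigma2 <= {threshold}; relax the threshold to "
            "keep at least one voxel"
        )
    return mask


def fit_encoding_model(
    train_images: ImageSet,
    train_responses: ResponseSet,
    cfg: EncodingConfig | None = None,
) -> EncodingModel:
    """Fit the per-voxel ridge encoding model with CV penalty selection.

    Responses are standardized per voxel (training mean 0, variance 1)
    before fitting; the transform is stored on the model so test responses
    receive the identical affine map.  Per voxel: penalty grid by effective
    degrees of freedom, K-fold cross-validated residual variance selects
    ``lambda_hat`` and provides ``sigma2``, the final weights are refit on
    the full training set, and the informative-voxel mask applies the
    ``sigma2 <= threshold`` filter.
    """
    cfg = cfg or EncodingConfig()
    X = train_images.data
    Y_raw = train_responses.data
    if X.shape[0] != Y_raw.shape[0]:
        raise ValueError("images and responses disagree on trial count")

    mean = Y_raw.mean(axis=0)
    std = Y_raw.std(axis=0)
    if np.any(std == 0):
        bad = int(np.flatnonzero(std == 0)[0])
        raise ValueError(f"voxel {bad} has constant response; cannot standardize")
    Y = (Y_raw - mean) / std

    grid = make_lambda_grid(X, cfg.grid_size)
    folds = _make_folds(X.shape[0], cfg.n_folds, cfg.seed, train_images.labels)

    logger.info(
        "fitting encoding model: %d trials, %d pixels, %d voxels, %d-point grid",
        X.shape[0], X.shape[1], Y.shape[1], grid.size,
    )
    R = _cv_residuals_multi(X, Y, grid, folds)
    idx, var = _pick_lambdas(R, grid, cfg.center_residuals)
    lambdas = grid[idx]
    sigma2 = var[np.arange(Y.shape[1]), idx]
    floored = sigma2 < np.finfo(float).eps
    if floored.any():
        warnings.warn(
            f"{int(floored.sum())} voxel(s) had zero residual variance; "
            "flooring sigma2 at machine epsilon",
            RuntimeWarning,
        )
        sigma2 = np.where(floored, np.finfo(float).eps, sigma2)

    # final refit on the full training set, grouped by chosen penalty
    U, s, Vt = _thin_svd(X)
    UtY = U.T @ Y
    B = np.empty((X.shape[1], Y.shape[1]))
    for l in np.unique(idx):
        cols = idx == l
        shrink = s / (s**2 + grid[l])
        B[:, cols] = Vt.T @ (shrink[:, None] * UtY[:, cols])
        logger.info(
            "lambda=%.4g: %d voxel(s)", grid[l], int(cols.sum())
        )

    selected = select_voxels(sigma2, cfg.voxel_variance_threshold)
    logger.info(
        "selected %d / %d voxels with sigma2 <= %.3g",
        int(selected.sum()), sigma2.size, cfg.voxel_variance_threshold,
    )
    return EncodingModel(
        B=B,
        sigma2=sigma2,
        lambdas=lambdas,
        selected=selected,
        response_mean=mean,
        response_std=std,
        threshold=cfg.voxel_variance_threshold,
        seed=cfg.seed,
        lambda_grid=grid,
    )
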