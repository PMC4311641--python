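"""Reconstruction quality measures and discriminative baselines.

Two complementary measures: the structural similarity index (SSIM, Wang et
al. formulation — windowed luminance/contrast/structure agreement, 1 for
identical images) for low-level fidelity, and classification accuracy for
semantic readout.  Two discriminative baselines put the generative decoder
in context: ridge regression straight from responses to pixels, and
l1-penalized multinomial logistic regression straight from responses to
class labels (sharing the gating implementation).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from skimage.metrics import structural_similarity

from .containers import ImageSet, ResponseSet
from .encoding import (
    EncodingConfig,
    _cv_residuals_multi,
    _make_folds,
    _pick_lambdas,
    _thin_svd,
    make_lambda_grid,
)
from .gating import fit_gating, gated_log_weights, select_gating_penalty

__all__ = [
    "EvalReport",
    "ssim",
    "ssim_set",
    "classification_report",
    "chance_level",
    "discriminative_pixel_baseline",
    "discriminative_class_baseline",
    "evaluate_reconstructions",
]

logger = logging.getLogger(__name__)


@dataclass
class EvalReport:
    """Per-trial SSIM plus classification summary for one decoding variant."""

    ssim_per_trial: list[float]
    ssim_sum: float
    ssim_mean: float
    n_trials: int
    n_correct: int | None = None
    accuracy: float | None = None
    chance: float | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "EvalReport":
        return cls(**json.loads(text))


def ssim(
    a: np.ndarray,
    b: np.ndarray,
    window: int = 11,
    k1: float = 0.01,
    k2: float = 0.03,
    data_range: float | None = None,
    sigma: float = 1.5,
) -> float:
    """Structural similarity between two images.

    Uses an 11x11 Gaussian window (sigma 1.5) with stabilizers
    ``C1 = (k1 * data_range)^2`` and ``C2 = (k2 * data_range)^2``; the data
    range defaults to the joint min-to-max span of the two images.  Images
    smaller than the window fall back to a single uniform window covering
    the whole image, with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("images must be 2-D and share a shape")
    if data_range is None:
        data_range = float(max(a.max(), b.max()) - min(a.min(), b.min()))
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    if min(a.shape) < window:
        warnings.warn(
            "image smaller than the SSIM window; using a single uniform "
            "window over the whole image",
            RuntimeWarning,
        )
        return _global_ssim(a, b, k1, k2, data_range)
    return float(
        structural_similarity(
            a,
            b,
            win_size=window,
            gaussian_weights=True,
            sigma=sigma,
            use_sample_covariance=False,
            K1=k1,
            K2=k2,
            data_range=data_range,
        )
    )


def _global_ssim(
    a: np.ndarray, b: np.ndarray, k1: float, k2: float, data_range: float
) -> float:
    """SSIM with one uniform window spanning the whole image."""
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    mu_a, mu_b = a.mean(), b.mean()
    va, vb = a.var(), b.var()
    cov = ((a - mu_a) * (b - mu_b)).mean()
    num = (2 * mu_a * mu_b + c1) * (2 * cov + c2)
    den = (mu_a**2 + mu_b**2 + c1) * (va + vb + c2)
    return float(num / den)


def ssim_set(
    reconstructions: ImageSet, originals: ImageSet, **kwargs
) -> np.ndarray:
    """Per-trial SSIM between paired reconstruction and original sets."""
    if reconstructions.data.shape != originals.data.shape:
        raise ValueError("sets must pair trial for trial")
    return np.array(
        [
            ssim(reconstructions.image(i), originals.image(i), **kwargs)
            for i in range(originals.n_trials)
        ]
    )


def classification_report(
    predicted_labels, true_labels
) -> tuple[int, float]:
    """Exact count and fraction of correctly classified trials."""
    pred = np.asarray(predicted_labels)
    true = np.asarray(true_labels)
    if pred.shape != true.shape:
        raise ValueError("label vectors must have equal length")
    if pred.size == 0:
        raise ValueError("empty label vectors")
    n_correct = int(np.sum(pred == true))
    return n_correct, n_correct / pred.size


def chance_level(n_categories: int) -> float:
    """Uniform-guess accuracy ``1/n_categories``."""
    if n_categories < 1:
        raise ValueError("need at least one category")
    return 1.0 / n_categories


def discriminative_pixel_baseline(
    train_responses: ResponseSet,
    train_images: ImageSet,
    test_responses: ResponseSet,
    cfg: EncodingConfig | None = None,
) -> ImageSet:
    """Ridge regression straight from responses to pixel values.

    The roles of the encoding fit are swapped: the response matrix is the
    design and each pixel is a regression target, with the same
    effective-degrees-of-freedom penalty grid and cross-validated penalty
    selection per pixel.  Both sides are centered on training means
    (intercept unpenalized), so with uninformative responses the
    prediction shrinks to the training pixel mean.
    """
    cfg = cfg or EncodingConfig()
    Z = train_responses.data
    P = train_images.data
    if Z.shape[0] != P.shape[0]:
        raise ValueError("responses and images disagree on trial count")
    z_mean = Z.mean(axis=0)
    p_mean = P.mean(axis=0)
    Zc = Z - z_mean
    Pc = P - p_mean

    grid = make_lambda_grid(Zc, cfg.grid_size)
    folds = _make_folds(Z.shape[0], cfg.n_folds, cfg.seed, train_images.labels)
    R = _cv_residuals_multi(Zc, Pc, grid, folds)
    idx, _ = _pick_lambdas(R, grid, cfg.center_residuals)

    U, s, Vt = _thin_svd(Zc)
    UtP = U.T @ Pc
    W = np.empty((Z.shape[1], P.shape[1]))
    for l in np.unique(idx):
        cols = idx == l
        shrink = s / (s**2 + grid[l])
        W[:, cols] = Vt.T @ (shrink[:, None] * UtP[:, cols])
    pred = (test_responses.data - z_mean) @ W + p_mean
    return ImageSet(pred, train_images.grid_shape)


def discriminative_class_baseline(
    train_responses: ResponseSet,
    train_labels,
    test_responses: ResponseSet,
    n_folds: int = 10,
    seed: int = 0,
    penalty_grid: np.ndarray | None = None,
) -> np.ndarray:
    """Predict class labels straight from responses.

    l1-penalized multinomial logistic regression (the gating
    implementation) with cross-validated penalty, applied to the low-level
    responses; returns the most probable label per test trial.
    """
    labels = np.asarray(train_labels)
    lam = select_gating_penalty(
        train_responses.data, labels, n_folds=n_folds,
        penalty_grid=penalty_grid, seed=seed,
    )
    model = fit_gating(train_responses.data, labels, lam)
    lp = gated_log_weights(model, test_responses.data)
    return model.class_order[np.argmax(lp, axis=1)]


def evaluate_reconstructions(
    reconstructions: ImageSet,
    originals: ImageSet,
    predicted_labels=None,
    true_labels=None,
    n_categories: int | None = None,
    **ssim_kwargs,
) -> EvalReport:
    """Bundle SSIM and (optionally) classification into one report."""
    scores = ssim_set(reconstructions, originals, **ssim_kwargs)
    n_correct = accuracy = chance = None
    if predicted_labels is not None and true_labels is not None:
        n_correct, accuracy = classification_report(predicted_labels, true_labels)
        if n_categories is None:
            n_categories = np.unique(np.asarray(true_labels)).size
        chance = chance_level(n_categories)
    return EvalReport(
        ssim_per_trial=[float(v) for v in scores],
        ssim_sum=float(scores.sum()),
        ssim_mean=float(scores.mean()),
        n_trials=int(scores.size),
        n_correct=n_correct,
        accuracy=accuracy,
        chance=chance,
    )
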