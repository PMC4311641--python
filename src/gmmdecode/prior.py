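"""Gaussian-mixture image priors, supervised by labels or via K-means.

The image prior is ``P(x) = sum_c pi_c N(x; m_c, R_c)``.  Each component
is a semantic category (supervised, one Gaussian per label) or a K-means
cluster of the prior image set (unsupervised).  Component moments use the
1/N_c estimator; component weights default to uniform 1/C.  A
cluster-to-label frequency table ``P(l | c)`` supports letter readout from
cluster responsibilities when clusters are unsupervised.

Covariances are never inverted downstream (the decoder works with
``(I + R_c D)^{-1}``), so rank-deficient components are admissible; only
singleton or rank-0 clusters receive a small diagonal jitter for
log-determinant stability.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .containers import ImageSet

__all__ = [
    "ImageNormalization",
    "MixturePrior",
    "normalize_images",
    "build_supervised_prior",
    "build_unsupervised_prior",
    "label_distribution",
]

logger = logging.getLogger(__name__)


@dataclass
class ImageNormalization:
    """Stored min-max parameters so test stimuli get the identical transform.

    The transform rescales pixel intensities to [0, 1] using the *prior
    set's* global min/max, then scales each image to unit Euclidean norm.
    """

    vmin: float
    vmax: float

    def apply(self, images: ImageSet) -> ImageSet:
        X = (images.data - self.vmin) / (self.vmax - self.vmin)
        norms = np.linalg.norm(X, axis=1)
        if np.any(norms == 0):
            raise ValueError("an image is identically zero after min-max scaling")
        return ImageSet(X / norms[:, None], images.grid_shape, images.labels)


@dataclass
class MixturePrior:
    """Per-component means, covariances, weights, and label frequency table."""

    means: np.ndarray  # (C, p)
    covariances: np.ndarray  # (C, p, p)
    weights: np.ndarray  # (C,)
    label_table: np.ndarray | None = None  # (C, L) row-stochastic
    label_names: np.ndarray | None = None  # (L,)
    normalization: ImageNormalization | None = None
    grid_shape: tuple[int, int] | None = None
    assignments: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.covariances = np.asarray(self.covariances, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        C, p = self.means.shape
        if self.covariances.shape != (C, p, p):
            raise ValueError("covariance stack shape mismatch")
        if self.weights.shape != (C,):
            raise ValueError("weights length mismatch")
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must form a probability simplex")
        if self.label_table is not None:
            self.label_table = np.asarray(self.label_table, dtype=float)
            if self.label_table.shape[0] != C:
                raise ValueError("label_table must have one row per component")
            if not np.allclose(self.label_table.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("label_table rows must sum to 1")

    @property
    def n_components(self) -> int:
        return self.means.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.means.shape[1]


def normalize_images(images: ImageSet) -> tuple[ImageSet, ImageNormalization]:
    """Min-max rescale the set to [0, 1], then unit-norm each image.

    Returns the normalized set and the parameters needed to apply the same
    transform to stimuli and test images.  Idempotent: a set that already
    went through the transform maps to itself (the global minimum 0 is
    preserved and re-unit-norming after a common rescale is the identity).
    """
    vmin = float(images.data.min())
    vmax = float(images.data.max())
    if vmax <= vmin:
        raise ValueError("degenerate image set: max pixel equals min pixel")
    params = ImageNormalization(vmin=vmin, vmax=vmax)
    return params.apply(images), params


def _component_moments(X: np.ndarray, mean: np.ndarray) -> np.ndarray:
    """Covariance about ``mean`` with the 1/N estimator."""
    Xc = X - mean
    return (Xc.T @ Xc) / X.shape[0]


def _jitter_scale(data: np.ndarray) -> float:
    """Diagonal jitter for degenerate components: 1e-6 of mean pixel variance."""
    v = float(np.var(data, axis=0).mean())
    return 1e-6 * v if v > 0 else 1e-12


def build_supervised_prior(
    images: ImageSet,
    uniform_weights: bool = True,
) -> MixturePrior:
    """One Gaussian component per label, moments from that label's images.

    Components are ordered by sorted label.  Weights are uniform 1/C by
    default (empirical proportions N_c/N with ``uniform_weights=False``);
    the label table is the identity since class and label coincide.
    """
    if images.labels is None:
        raise ValueError("supervised prior requires labels")
    label_names = np.unique(images.labels)
    C = label_names.size
    p = images.n_pixels
    means = np.empty((C, p))
    covs = np.empty((C, p, p))
    counts = np.empty(C)
    assignments = np.empty(images.n_trials, dtype=int)
    for c, lab in enumerate(label_names):
        members = images.labels == lab
        n_c = int(members.sum())
        if n_c < 2:
            raise ValueError(f"label {lab!r} has fewer than 2 images")
        X = images.data[members]
        means[c] = X.mean(axis=0)
        covs[c] = _component_moments(X, means[c])
        counts[c] = n_c
        assignments[members] = c
    weights = np.full(C, 1.0 / C) if uniform_weights else counts / counts.sum()
    return MixturePrior(
        means=means,
        covariances=covs,
        weights=weights,
        label_table=np.eye(C),
        label_names=label_names,
        grid_shape=images.grid_shape,
        assignments=assignments,
    )


def build_unsupervised_prior(
    images: ImageSet,
    C: int,
    restarts: int = 10,
    seed: int = 0,
    uniform_weights: bool = True,
) -> MixturePrior:
    """K-means mixture prior: centroid means, member covariances, uniform pi.

    K-means uses Euclidean distance with k-means++ initialization, keeping
    the best of ``restarts`` runs by within-cluster sum of squares.
    Singleton or rank-0 clusters receive a small diagonal jitter so their
    log-determinant terms stay finite.  If labels are present on the image
    set a cluster-to-label frequency table is attached.
    """
    if not (1 <= C <= images.n_trials):
        raise ValueError("need 1 <= C <= number of images")
    X = images.data
    p = images.n_pixels
    if C == 1:
        assignments = np.zeros(images.n_trials, dtype=int)
        centroids = X.mean(axis=0, keepdims=True)
    else:
        km = KMeans(
            n_clusters=C,
            n_init=restarts,
            init="k-means++",
            max_iter=300,
            random_state=seed,
        ).fit(X)
        assignments = km.labels_.astype(int)
        centroids = km.cluster_centers_

    jitter = _jitter_scale(X)
    means = np.empty((C, p))
    covs = np.empty((C, p, p))
    keep = np.ones(C, dtype=bool)
    for c in range(C):
        members = assignments == c
        n_c = int(members.sum())
        if n_c == 0:
            warnings.warn(
                f"cluster {c} is empty after K-means; dropping it",
                RuntimeWarning,
            )
            keep[c] = False
            means[c] = centroids[c]
            covs[c] = np.eye(p) * jitter
            continue
        means[c] = centroids[c]
        covs[c] = _component_moments(X[members], centroids[c])
        if n_c == 1 or np.allclose(covs[c], 0):
            logger.warning("cluster %d is degenerate; adding diagonal jitter", c)
            covs[c] = covs[c] + np.eye(p) * jitter
    if not keep.all():
        means = means[keep]
        covs = covs[keep]
        # reindex assignments onto surviving clusters
        remap = -np.ones(C, dtype=int)
        remap[np.flatnonzero(keep)] = np.arange(int(keep.sum()))
        assignments = remap[assignments]
        C = int(keep.sum())

    if uniform_weights:
        weights = np.full(C, 1.0 / C)
    else:
        counts = np.bincount(assignments, minlength=C).astype(float)
        weights = counts / counts.sum()

    label_table = None
    label_names = None
    if images.labels is not None:
        label_names = np.unique(images.labels)
        label_table = label_distribution(
            assignments, images.labels, C, label_names=label_names
        )
    return MixturePrior(
        means=means,
        covariances=covs,
        weights=weights,
        label_table=label_table,
        label_names=label_names,
        grid_shape=images.grid_shape,
        assignments=assignments,
    )


def label_distribution(
    assignments: np.ndarray,
    labels: np.ndarray,
    C: int,
    label_names: np.ndarray | None = None,
) -> np.ndarray:
    """Row-stochastic ``P(l | c)``: label frequencies within each cluster.

    Entry (c, l) is the fraction of cluster-c images carrying label l.  An
    empty cluster gets a uniform row with a warning.
    """
    assignments = np.asarray(assignments)
    labels = np.asarray(labels)
    if assignments.shape != labels.shape:
        raise ValueError("assignments and labels must align")
    if np.any(assignments < 0) or np.any(assignments >= C):
        raise ValueError("assignments out of range [0, C)")
    if label_names is None:
        label_names = np.unique(labels)
    L = label_names.size
    label_idx = {lab: j for j, lab in enumerate(label_names)}
    table = np.zeros((C, L))
    for c in range(C):
        members = labels[assignments == c]
        if members.size == 0:
            warnings.warn(
                f"cluster {c} has no members; using a uniform label row",
                RuntimeWarning,
            )
            table[c] = 1.0 / L
            continue
        for lab in members:
            table[c, label_idx[lab]] += 1.0
        table[c] /= members.size
    return table
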