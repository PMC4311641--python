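"""Seeded forward simulator for end-to-end testing of the decoding pipeline.

Real use of the decoder needs stimulus images, paired voxel responses from
a low-level visual area, and optionally responses from a higher-level area
that carry category information.  This module generates all three with the
statistical structure the model assumes: category-structured images built
from binary glyph templates with toroidal shifts and pixel noise, voxel
responses ``y = B'x + eps`` from Gaussian receptive fields with diagonal
Gaussian noise, and gating responses ``z`` that embed the category along
mutually orthogonal directions at a controllable signal-to-noise ratio.

The default configuration uses a 12 x 12 pixel grid (p = 144) rather than
a full-resolution stimulus canvas so that the p x p covariance algebra
runs in seconds; a larger grid is a config change away.  Everything is
deterministic under the config seed, and each bundle carries a manifest
from which it can be regenerated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .containers import ImageSet, ResponseSet
from .prior import ImageNormalization, normalize_images

__all__ = [
    "SyntheticConfig",
    "SyntheticBundle",
    "TEMPLATE_NAMES",
    "make_templates",
    "sample_images",
    "make_forward_model",
    "simulate_responses",
    "simulate_gating_responses",
    "generate_dataset",
]

logger = logging.getLogger(__name__)

#: the built-in glyph categories, in fixed order
TEMPLATE_NAMES = (
    "hbar", "vbar", "cross", "diag", "adiag", "ring", "square", "checker",
)


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    ``response_noise`` scales each voxel's noise standard deviation
    relative to that voxel's signal standard deviation over the training
    stimuli, so it is ``1/sqrt(SNR)``; the default 1/sqrt(2) gives a
    per-voxel SNR of about 2.  ``gating_snr`` scales the category
    embedding in the high-level responses against unit observation noise.
    """

    grid_shape: tuple[int, int] = (12, 12)
    n_categories: int = 6
    n_prior_per_cat: int = 200
    n_train: int = 300
    n_test: int = 60
    n_voxels: int = 200
    n_gating_voxels: int = 30
    pixel_jitter: float = 0.10
    shift_range: int = 1
    rf_width: float = 2.0
    weight_scale: float = 1.0
    response_noise: float = 2.0 ** -0.5
    gating_snr: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_categories", "n_prior_per_cat", "n_train", "n_test",
            "n_voxels", "n_gating_voxels",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.pixel_jitter < 0 or self.response_noise < 0 or self.gating_snr < 0:
            raise ValueError("noise levels must be nonnegative")
        if self.n_categories > len(TEMPLATE_NAMES):
            raise ValueError(
                f"at most {len(TEMPLATE_NAMES)} glyph categories are available"
            )


@dataclass
class SyntheticBundle:
    """Everything one pipeline run needs, plus the generating ground truth."""

    prior_images: ImageSet
    train_images: ImageSet
    test_images: ImageSet
    train_responses: ResponseSet
    test_responses: ResponseSet
    train_gating: ResponseSet
    test_gating: ResponseSet
    B_true: np.ndarray
    sigma_true: np.ndarray
    normalization: ImageNormalization
    manifest: dict = field(default_factory=dict)


def make_templates(
    n_categories: int, grid_shape: tuple[int, int] = (12, 12)
) -> np.ndarray:
    """Deterministic binary glyph templates, one per category.

    Returns an ``(n_categories, H*W)`` matrix of {0, 1} images in the
    fixed order of :data:`TEMPLATE_NAMES`.
    """
    if n_categories > len(TEMPLATE_NAMES):
        raise ValueError(
            f"at most {len(TEMPLATE_NAMES)} glyph categories are available"
        )
    H, W = grid_shape
    ii, jj = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    bar = max(1, H // 6)
    mid_i, mid_j = H // 2, W // 2
    glyphs = {}
    glyphs["hbar"] = (np.abs(ii - mid_i) < bar).astype(float)
    glyphs["vbar"] = (np.abs(jj - mid_j) < bar).astype(float)
    glyphs["cross"] = np.maximum(glyphs["hbar"], glyphs["vbar"])
    glyphs["diag"] = (np.abs(ii - jj) < bar).astype(float)
    glyphs["adiag"] = (np.abs(ii + jj - (W - 1)) < bar).astype(float)
    r = (ii - (H - 1) / 2) ** 2 + (jj - (W - 1) / 2) ** 2
    r_out = (min(H, W) / 2.5) ** 2
    r_in = (min(H, W) / 4.5) ** 2
    glyphs["ring"] = ((r <= r_out) & (r >= r_in)).astype(float)
    q = min(H, W) // 4
    glyphs["square"] = (
        (np.abs(ii - mid_i) <= q) & (np.abs(jj - mid_j) <= q)
    ).astype(float)
    glyphs["checker"] = (((ii // bar) + (jj // bar)) % 2).astype(float)
    out = np.stack(
        [glyphs[name].ravel() for name in TEMPLATE_NAMES[:n_categories]]
    )
    return out


def sample_images(
    templates: np.ndarray,
    n_per_cat: int,
    pixel_jitter: float,
    shift_range: int,
    seed: int,
    grid_shape: tuple[int, int],
) -> ImageSet:
    """Noisy shifted instances of each template, with category labels.

    Each instance is its template rolled by up to ``shift_range`` pixels
    per axis (toroidal, so image energy is preserved) plus i.i.d. Gaussian
    pixel noise, clipped to [0, 1].
    """
    if pixel_jitter < 0:
        raise ValueError("pixel_jitter must be nonnegative")
    rng = np.random.default_rng(seed)
    H, W = grid_shape
    K = templates.shape[0]
    rows, labels = [], []
    for c in range(K):
        t = templates[c].reshape(H, W)
        for _ in range(n_per_cat):
            if shift_range > 0:
                di = rng.integers(-shift_range, shift_range + 1)
                dj = rng.integers(-shift_range, shift_range + 1)
                img = np.roll(np.roll(t, di, axis=0), dj, axis=1)
            else:
                img = t
            img = img + rng.normal(0.0, pixel_jitter, size=(H, W))
            rows.append(np.clip(img, 0.0, 1.0).ravel())
            labels.append(TEMPLATE_NAMES[c])
    return ImageSet(np.array(rows), grid_shape, np.array(labels))


def make_forward_model(
    p: int,
    q: int,
    rf_width: float,
    weight_scale: float,
    noise_sd: float,
    seed: int,
    grid_shape: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-receptive-field weights and per-voxel noise scales.

    Each voxel's weight map is a Gaussian bump at a random grid location
    with width ``rf_width`` (pixels), normalized to unit norm and scaled;
    every voxel shares the noise scale ``noise_sd``.  Returns ``(B, sigma)``
    with ``B`` of shape (p, q).
    """
    if q < 1:
        raise ValueError("need at least one voxel")
    H, W = grid_shape
    if H * W != p:
        raise ValueError("grid_shape does not match p")
    rng = np.random.default_rng(seed)
    ii, jj = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    B = np.empty((p, q))
    for v in range(q):
        ci = rng.uniform(0, H - 1)
        cj = rng.uniform(0, W - 1)
        rf = np.exp(-((ii - ci) ** 2 + (jj - cj) ** 2) / (2 * rf_width**2))
        rf = rf.ravel()
        B[:, v] = weight_scale * rf / np.linalg.norm(rf)
    sigma = np.full(q, float(noise_sd))
    return B, sigma


def simulate_responses(
    B: np.ndarray, sigma: np.ndarray, images: ImageSet, seed: int
) -> ResponseSet:
    """Linear Gaussian responses ``Y = X B + eps``, ``eps ~ N(0, diag(sigma^2))``."""
    X = images.data
    if X.shape[1] != B.shape[0]:
        raise ValueError("image pixel count does not match forward model")
    rng = np.random.default_rng(seed)
    Y = X @ B + rng.normal(0.0, 1.0, size=(X.shape[0], B.shape[1])) * sigma
    return ResponseSet(Y)


def simulate_gating_responses(
    labels: np.ndarray, q_prime: int, gating_snr: float, seed: int
) -> ResponseSet:
    """Category-informative high-level responses.

    Each category maps to one row of a random orthonormal embedding
    (mutually orthogonal, hence >= 90 degrees apart); the response is
    ``gating_snr * embedding + N(0, I)``.  The embedding depends only on
    the seed and the sorted category set, so train and test calls with the
    same seed share it.
    """
    labels = np.asarray(labels)
    cats = np.unique(labels)
    if q_prime < cats.size:
        raise ValueError("need at least as many gating voxels as categories")
    rng = np.random.default_rng(seed)
    raw = rng.normal(size=(q_prime, q_prime))
    Qmat, _ = np.linalg.qr(raw)
    embedding = Qmat[:, : cats.size].T  # (K, q') orthonormal rows
    lookup = {c: k for k, c in enumerate(cats)}
    idx = np.array([lookup[c] for c in labels])
    Z = gating_snr * embedding[idx] + rng.normal(size=(labels.size, q_prime))
    return ResponseSet(Z)


def _balanced_counts(total: int, k: int) -> np.ndarray:
    base = np.full(k, total // k)
    base[: total % k] += 1
    return base


def _sample_balanced(
    templates: np.ndarray, total: int, cfg: SyntheticConfig, seed: int
) -> ImageSet:
    counts = _balanced_counts(total, cfg.n_categories)
    rng_seeds = np.random.SeedSequence(seed).generate_state(cfg.n_categories)
    parts = [
        sample_images(
            templates[c : c + 1], int(counts[c]), cfg.pixel_jitter,
            cfg.shift_range, int(rng_seeds[c] % 2**31), cfg.grid_shape,
        )
        for c in range(cfg.n_categories)
    ]
    data = np.vstack([p.data for p in parts])
    labels = np.concatenate(
        [np.full(int(counts[c]), TEMPLATE_NAMES[c]) for c in range(cfg.n_categories)]
    )
    # shuffle trial order so folds and batches are label-mixed
    order = np.random.default_rng(seed + 1).permutation(total)
    return ImageSet(data[order], cfg.grid_shape, labels[order])


def generate_dataset(cfg: SyntheticConfig | None = None) -> SyntheticBundle:
    """One call producing prior, train and test sets plus ground truth.

    Images are normalized with the prior set's transform before responses
    are simulated, so the linear forward model holds exactly in the
    normalized space the decoder works in.  Per-voxel noise is scaled to
    the voxel's signal standard deviation over the training stimuli (see
    :class:`SyntheticConfig`).  Train and test trials are sampled
    independently, so the sets are disjoint by construction.
    """
    cfg = cfg or SyntheticConfig()
    ss = np.random.SeedSequence(cfg.seed)
    seeds = [int(s % 2**31) for s in ss.generate_state(8)]

    templates = make_templates(cfg.n_categories, cfg.grid_shape)
    prior_raw = sample_images(
        templates, cfg.n_prior_per_cat, cfg.pixel_jitter, cfg.shift_range,
        seeds[0], cfg.grid_shape,
    )
    train_raw = _sample_balanced(templates, cfg.n_train, cfg, seeds[1])
    test_raw = _sample_balanced(templates, cfg.n_test, cfg, seeds[2])

    prior_images, norm = normalize_images(prior_raw)
    train_images = norm.apply(train_raw)
    test_images = norm.apply(test_raw)

    p = cfg.grid_shape[0] * cfg.grid_shape[1]
    B, _ = make_forward_model(
        p, cfg.n_voxels, cfg.rf_width, cfg.weight_scale, 0.0,
        seeds[3], cfg.grid_shape,
    )
    signal = train_images.data @ B
    sigma = cfg.response_noise * signal.std(axis=0)
    sigma = np.maximum(sigma, 1e-12)

    train_responses = simulate_responses(B, sigma, train_images, seeds[4])
    test_responses = simulate_responses(B, sigma, test_images, seeds[5])
    train_gating = simulate_gating_responses(
        train_images.labels, cfg.n_gating_voxels, cfg.gating_snr, seeds[6]
    )
    # test gating shares the embedding (same seed, same sorted category
    # set) but needs an independent noise draw
    rng = np.random.default_rng(seeds[7])
    cats = np.unique(train_images.labels)
    raw = np.random.default_rng(seeds[6]).normal(
        size=(cfg.n_gating_voxels, cfg.n_gating_voxels)
    )
    Qmat, _ = np.linalg.qr(raw)
    embedding = Qmat[:, : cats.size].T
    lookup = {c: k for k, c in enumerate(cats)}
    idx = np.array([lookup[c] for c in test_images.labels])
    Z_test = cfg.gating_snr * embedding[idx] + rng.normal(
        size=(cfg.n_test, cfg.n_gating_voxels)
    )
    test_gating = ResponseSet(Z_test)

    manifest = {
        "config": asdict(cfg),
        "seeds": seeds,
        "conventions": {"flattening": "row-major", "indexing": "0-based"},
    }
    logger.info(
        "synthetic bundle: %d prior / %d train / %d test trials, %d voxels",
        prior_images.n_trials, cfg.n_train, cfg.n_test, cfg.n_voxels,
    )
    return SyntheticBundle(
        prior_images=prior_images,
        train_images=train_images,
        test_images=test_images,
        train_responses=train_responses,
        test_responses=test_responses,
        train_gating=train_gating,
        test_gating=test_gating,
        B_true=B,
        sigma_true=sigma,
        normalization=norm,
        manifest=manifest,
    )
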