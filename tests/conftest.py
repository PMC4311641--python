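"""Shared fixtures: synthetic bundles and fitted models reused across tests."""

import numpy as np
import pytest

import gmmdecode as g
from gmmdecode.encoding import EncodingModel
from gmmdecode.prior import MixturePrior


@pytest.fixture(scope="session")
def small_bundle():
    """Reduced-scale bundle for fast unit and integration tests."""
    cfg = g.SyntheticConfig(
        n_prior_per_cat=50, n_train=120, n_test=24, n_voxels=80, seed=7
    )
    return g.generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_model(small_bundle):
    return g.fit_encoding_model(
        small_bundle.train_images, small_bundle.train_responses,
        g.EncodingConfig(seed=7),
    )


@pytest.fixture(scope="session")
def default_bundle():
    """The default study conditions: 6 categories, 12x12 grid, 200 voxels,
    300 train / 60 test trials, per-voxel SNR about 2."""
    return g.generate_dataset(g.SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def default_model(default_bundle):
    return g.fit_encoding_model(
        default_bundle.train_images, default_bundle.train_responses,
        g.EncodingConfig(seed=0),
    )


def random_decoder_instance(rng, p=None, q=None, C=None, full_rank=True):
    """A random small encoding model + mixture prior for analytic checks."""
    p = p or int(rng.integers(2, 5))
    q = q or int(rng.integers(2, 7))
    C = C or int(rng.integers(1, 4))
    B = rng.normal(size=(p, q))
    sigma2 = rng.uniform(0.3, 2.0, q)
    means = rng.normal(size=(C, p))
    covs = np.empty((C, p, p))
    for c in range(C):
        A = rng.normal(size=(p, p + 2))
        covs[c] = A @ A.T / (p + 2)
        if not full_rank:
            covs[c] = 0.0 * covs[c]
    weights = rng.dirichlet(np.ones(C))
    model = EncodingModel(
        B=B, sigma2=sigma2, lambdas=np.zeros(q),
        selected=np.ones(q, dtype=bool), response_mean=np.zeros(q),
        response_std=np.ones(q), threshold=0.99, seed=0,
    )
    prior = MixturePrior(means=means, covariances=covs, weights=weights)
    return model, prior
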