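"""Unit tests for the analytic mixture-posterior decoder."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

import gmmdecode as g
from gmmdecode.containers import ResponseSet
from gmmdecode.decoder import HARD
from conftest import random_decoder_instance


def marginal_log_responsibilities(model, prior, y):
    """Independent oracle: normalized log N(y; B'm_c, Sigma + B'R_c B)."""
    B, s2 = model.B, model.sigma2
    C = prior.n_components
    out = np.empty(C)
    for c in range(C):
        cov = np.diag(s2) + B.T @ prior.covariances[c] @ B
        out[c] = np.log(prior.weights[c]) + multivariate_normal.logpdf(
            y, B.T @ prior.means[c], cov
        )
    return out - np.logaddexp.reduce(out)


class TestPrecomputeState:
    def test_zero_prior_covariance_identities(self):
        rng = np.random.default_rng(0)
        model, prior = random_decoder_instance(rng, p=3, q=4, C=2, full_rank=False)
        state = g.precompute_state(model, prior)
        p = prior.n_pixels
        for c in range(2):
            np.testing.assert_allclose(state.U[c], np.eye(p), atol=1e-12)
            np.testing.assert_allclose(state.Q[c], 0.0, atol=1e-12)
            assert state.logdet_U[c] == pytest.approx(0.0, abs=1e-12)

    def test_infinite_noise_limit(self):
        """As sigma2 grows without bound, D -> 0 and U_c -> I."""
        rng = np.random.default_rng(1)
        model, prior = random_decoder_instance(rng, p=3, q=4, C=2)
        model.sigma2 = model.sigma2 * 1e12
        state = g.precompute_state(model, prior)
        np.testing.assert_allclose(state.D, 0.0, atol=1e-9)
        for c in range(2):
            np.testing.assert_allclose(state.U[c], np.eye(3), atol=1e-9)

    def test_logdet_matches_determinant_oracle(self):
        rng = np.random.default_rng(2)
        model, prior = random_decoder_instance(rng, p=4, q=5, C=3)
        state = g.precompute_state(model, prior)
        for c in range(3):
            M = np.eye(4) + prior.covariances[c] @ state.D
            expected = -np.log(np.linalg.det(M))
            assert state.logdet_U[c] == pytest.approx(expected, abs=1e-9)

    def test_woodbury_identity_on_random_psd_pairs(self):
        """(I + RD)^{-1} R = R (I + DR)^{-1} — the form that avoids R^{-1}."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = int(rng.integers(2, 6))
            A = rng.normal(size=(p, p + 1))
            R = A @ A.T / p
            Bm = rng.normal(size=(p, p + 1))
            D = Bm @ Bm.T / p
            lhs = np.linalg.solve(np.eye(p) + R @ D, R)
            rhs = R @ np.linalg.inv(np.eye(p) + D @ R)
            np.testing.assert_allclose(lhs, rhs, atol=1e-8)


class TestTransformResponse:
    def test_zero_response_maps_to_zero(self):
        rng = np.random.default_rng(4)
        model, _ = random_decoder_instance(rng, p=3, q=5, C=1)
        np.testing.assert_array_equal(
            g.transform_response(model, np.zeros(5)), 0.0
        )

    def test_unit_noise_reduces_to_By(self):
        rng = np.random.default_rng(5)
        model, _ = random_decoder_instance(rng, p=3, q=5, C=1)
        model.sigma2 = np.ones(5)
        y = rng.normal(size=5)
        np.testing.assert_allclose(
            g.transform_response(model, y), model.B @ y, atol=1e-12
        )

    def test_matches_elementwise_loop(self):
        rng = np.random.default_rng(6)
        model, _ = random_decoder_instance(rng, p=4, q=6, C=1)
        y = rng.normal(size=6)
        f = g.transform_response(model, y)
        loop = np.zeros(4)
        for i in range(4):
            for j in range(6):
                loop[i] += model.B[i, j] * y[j] / model.sigma2[j]
        np.testing.assert_allclose(f, loop, atol=1e-12)

    def test_length_mismatch_raises(self):
        rng = np.random.default_rng(7)
        model, _ = random_decoder_instance(rng, p=3, q=5, C=1)
        with pytest.raises(ValueError):
            g.transform_response(model, np.zeros(4))


class TestPosteriorMean:
    def test_zero_covariance_collapses_to_prior_mean(self):
        rng = np.random.default_rng(8)
        model, prior = random_decoder_instance(rng, p=3, q=4, C=2, full_rank=False)
        state = g.precompute_state(model, prior)
        f = rng.normal(size=3)
        for c in range(2):
            np.testing.assert_allclose(
                g.posterior_mean(state, f, c), prior.means[c], atol=1e-12
            )

    def test_no_data_information_collapses_to_prior_mean(self):
        rng = np.random.default_rng(9)
        model, prior = random_decoder_instance(rng, p=3, q=4, C=2)
        model.sigma2 = model.sigma2 * 1e14  # D -> 0 and fbar -> 0
        state = g.precompute_state(model, prior)
        y = rng.normal(size=4)
        f = g.transform_response(model, y)
        for c in range(2):
            np.testing.assert_allclose(
                g.posterior_mean(state, f, c), prior.means[c], atol=1e-6
            )

    @pytest.mark.parametrize("seed", range(5))
    def test_information_form_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        model, prior = random_decoder_instance(rng, p=3, q=5, C=2)
        state = g.precompute_state(model, prior)
        y = rng.normal(size=5)
        f = g.transform_response(model, y)
        for c in range(2):
            Rinv = np.linalg.inv(prior.covariances[c])
            oracle = np.linalg.solve(
                Rinv + state.D, Rinv @ prior.means[c] + f
            )
            np.testing.assert_allclose(
                g.posterior_mean(state, f, c), oracle, atol=1e-8
            )


class TestLogResponsibilities:
    def test_single_cluster_certainty(self):
        rng = np.random.default_rng(10)
        model, prior = random_decoder_instance(rng, p=3, q=4, C=1)
        state = g.precompute_state(model, prior)
        f = rng.normal(size=3)
        lr = g.log_responsibilities(state, prior, f)
        assert lr[0] == pytest.approx(0.0, abs=1e-12)

    def test_identical_clusters_split_evenly(self):
        rng = np.random.default_rng(11)
        model, prior = random_decoder_instance(rng, p=3, q=4, C=2)
        prior.means[1] = prior.means[0]
        prior.covariances[1] = prior.covariances[0]
        prior.weights = np.array([0.5, 0.5])
        state = g.precompute_state(model, prior)
        f = g.transform_response(model, rng.normal(size=4))
        r = np.exp(g.log_responsibilities(state, prior, f))
        np.testing.assert_allclose(r, [0.5, 0.5], atol=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_marginal_gaussian_oracle(self, seed):
        rng = np.random.default_rng(200 + seed)
        model, prior = random_decoder_instance(rng)
        state = g.precompute_state(model, prior)
        y = rng.normal(size=model.B.shape[1])
        f = g.transform_response(model, y)
        lr = g.log_responsibilities(state, prior, f)
        oracle = marginal_log_responsibilities(model, prior, y)
        np.testing.assert_allclose(lr, oracle, atol=1e-8)

    def test_shift_invariance_of_normalization(self):
        rng = np.random.default_rng(12)
        model, prior = random_decoder_instance(rng, p=3, q=4, C=3)
        state = g.precompute_state(model, prior)
        f = g.transform_response(model, rng.normal(size=4))
        base = g.log_responsibilities(state, prior, f)
        shifted = g.log_responsibilities(
            state, prior, f, np.log(prior.weights) + 17.3
        )
        np.testing.assert_allclose(base, shifted, atol=1e-10)

    def test_data_free_limit_returns_prior_weights(self):
        rng = np.random.default_rng(13)
        model, prior = random_decoder_instance(rng, p=3, q=4, C=3)
        model.sigma2 = model.sigma2 * 1e14
        state = g.precompute_state(model, prior)
        f = g.transform_response(model, rng.normal(size=4))
        r = np.exp(g.log_responsibilities(state, prior, f))
        np.testing.assert_allclose(r, prior.weights, atol=1e-6)

    def test_all_zero_weights_rejected(self):
        rng = np.random.default_rng(14)
        model, prior = random_decoder_instance(rng, p=3, q=4, C=2)
        state = g.precompute_state(model, prior)
        with pytest.raises(ValueError):
            g.log_responsibilities(
                state, prior, np.zeros(3), np.array([-np.inf, -np.inf])
            )


class TestReconstruct:
    def test_single_cluster_any_temperature(self):
        rng = np.random.default_rng(15)
        model, prior = random_decoder_instance(rng, p=3, q=4, C=1)
        state = g.precompute_state(model, prior)
        f = g.transform_response(model, rng.normal(size=4))
        n1 = g.posterior_mean(state, f, 0)
        for T in (HARD, 1.0, 0.3):
            x, winner = g.reconstruct(state, prior, f, np.array([1.0]), T)
            np.testing.assert_allclose(x, n1, atol=1e-12)
            assert winner == 0

    def test_hard_mode_takes_most_probable(self):
        rng = np.random.default_rng(16)
        model, prior = random_decoder_instance(rng, p=3, q=4, C=2)
        state = g.precompute_state(model, prior)
        f = g.transform_response(model, rng.normal(size=4))
        x, winner = g.reconstruct(state, prior, f, np.array([0.9, 0.1]), HARD)
        assert winner == 0
        np.testing.assert_allclose(x, g.posterior_mean(state, f, 0))

    def test_tie_broken_toward_lowest_index(self):
        rng = np.random.default_rng(17)
        model, prior = random_decoder_instance(rng, p=3, q=4, C=2)
        state = g.precompute_state(model, prior)
        f = g.transform_response(model, rng.normal(size=4))
        _, winner = g.reconstruct(state, prior, f, np.array([0.5, 0.5]), HARD)
        assert winner == 0

    def test_weighted_average_matches_loop_oracle(self):
        rng = np.random.default_rng(18)
        model, prior = random_decoder_instance(rng, p=3, q=4, C=3)
        state = g.precompute_state(model, prior)
        f = g.transform_response(model, rng.normal(size=4))
        r = np.array([0.5, 0.3, 0.2])
        for T in (1.0, 0.5):
            x, _ = g.reconstruct(state, prior, f, r, T)
            w = r ** (1 / T)
            w = w / w.sum()
            loop = sum(
                w[c] * g.posterior_mean(state, f, c) for c in range(3)
            )
            np.testing.assert_allclose(x, loop, atol=1e-10)

    def test_temperature_one_weights_equal_responsibilities(self):
        rng = np.random.default_rng(19)
        model, prior = random_decoder_instance(rng, p=3, q=4, C=3)
        state = g.precompute_state(model, prior)
        f = g.transform_response(model, rng.normal(size=4))
        r = np.array([0.6, 0.3, 0.1])
        x, _ = g.reconstruct(state, prior, f, r, 1.0)
        loop = sum(r[c] * g.posterior_mean(state, f, c) for c in range(3))
        np.testing.assert_allclose(x, loop, atol=1e-12)

    def test_nonpositive_temperature_rejected(self):
        rng = np.random.default_rng(20)
        model, prior = random_decoder_instance(rng, p=3, q=4, C=2)
        state = g.precompute_state(model, prior)
        with pytest.raises(ValueError):
            g.reconstruct(state, prior, np.zeros(3), np.array([0.5, 0.5]), -1.0)


class TestLetterProbability:
    def test_identity_table_passthrough(self):
        r = np.array([0.2, 0.3, 0.5])
        np.testing.assert_allclose(g.letter_probability(r, np.eye(3)), r)

    def test_uniform_table_gives_uniform(self):
        r = np.array([0.9, 0.1])
        table = np.full((2, 4), 0.25)
        np.testing.assert_allclose(g.letter_probability(r, table), 0.25)

    def test_hand_computed_product(self):
        r = np.array([0.5, 0.25, 0.25])
        table = np.array([[1.0, 0.0], [0.4, 0.6], [0.0, 1.0]])
        np.testing.assert_allclose(
            g.letter_probability(r, table), [0.6, 0.4], atol=1e-12
        )

    def test_output_sums_to_one(self):
        rng = np.random.default_rng(21)
        r = rng.dirichlet(np.ones(4))
        table = rng.dirichlet(np.ones(3), size=4)
        assert g.letter_probability(r, table).sum() == pytest.approx(1, abs=1e-12)


class TestDecodeBatch:
    def test_batch_of_one_equals_single_trial_path(self, small_bundle, small_model):
        prior = g.build_supervised_prior(small_bundle.prior_images)
        one = small_bundle.test_responses.subset([0])
        res = g.decode_batch(small_model, prior, one)
        state = g.precompute_state(small_model, prior)
        y = small_model.standardize(small_bundle.test_responses.data[0])
        f = g.transform_response(small_model, y[small_model.selected])
        lr = g.log_responsibilities(state, prior, f)
        r = np.exp(lr)
        r /= r.sum()
        x, winner = g.reconstruct(state, prior, f, r, HARD)
        np.testing.assert_allclose(res.reconstructions[0], x, atol=1e-12)
        assert res.winners[0] == winner

    def test_permutation_equivariance(self, small_bundle, small_model):
        prior = g.build_supervised_prior(small_bundle.prior_images)
        res = g.decode_batch(small_model, prior, small_bundle.test_responses)
        perm = np.random.default_rng(22).permutation(
            small_bundle.test_responses.n_trials
        )
        res_p = g.decode_batch(
            small_model, prior, small_bundle.test_responses.subset(perm)
        )
        np.testing.assert_array_equal(
            res_p.reconstructions, res.reconstructions[perm]
        )
        np.testing.assert_array_equal(res_p.winners, res.winners[perm])

    def test_low_noise_recovery(self, small_bundle, small_model):
        """Most winners match the true category under the default SNR."""
        prior = g.build_supervised_prior(small_bundle.prior_images)
        res = g.decode_batch(small_model, prior, small_bundle.test_responses)
        acc = np.mean(res.predicted_labels == small_bundle.test_images.labels)
        assert acc >= 0.9

    def test_responsibilities_are_simplex_rows(self, small_bundle, small_model):
        prior = g.build_supervised_prior(small_bundle.prior_images)
        res = g.decode_batch(small_model, prior, small_bundle.test_responses)
        np.testing.assert_allclose(res.responsibilities.sum(axis=1), 1, atol=1e-9)
        assert (res.responsibilities >= 0).all()
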