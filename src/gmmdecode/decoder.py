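"""Analytic inversion of the encoding model under the mixture prior.

Given the linear Gaussian likelihood ``P(y|x) = N(y; B'x, Sigma)`` and the
mixture prior ``P(x) = sum_c pi_c N(x; m_c, R_c)``, the per-cluster
posterior of the image is Gaussian with mean

    n_c(y) = Q_c fbar(y) + U_c m_c,

where ``D = B Sigma^{-1} B'``, ``U_c = (I + R_c D)^{-1}``, ``Q_c = U_c R_c``
and ``fbar(y) = B Sigma^{-1} y`` is the response mapped into image space.
Cluster responsibilities follow from the marginal likelihood of y under
each component,

    log P(c|y) = log pi_c + 1/2 log det U_c + 1/2 fbar' Q_c fbar
                 - 1/2 m_c' D U_c m_c + fbar' U_c m_c + const,

normalized by log-sum-exp.  The reconstruction is either the single most
probable cluster's posterior mean (hard assignment, the default) or a
temperature-weighted average with weights proportional to P(c|y)^(1/T).

``U_c`` is never obtained by inverting ``R_c``: all per-cluster quantities
come from a factorized linear solve against ``(I + R_c D)``, so singular
prior covariances are handled exactly.  Everything that does not depend on
the trial is cached in :class:`DecoderState`, leaving O(C p^2) work per
decoded response.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import lu_factor, lu_solve
from scipy.special import logsumexp

from .containers import ResponseSet
from .encoding import EncodingModel
from .prior import MixturePrior

__all__ = [
    "DecoderState",
    "DecodeResult",
    "precompute_state",
    "transform_response",
    "posterior_mean",
    "log_responsibilities",
    "reconstruct",
    "letter_probability",
    "decode_batch",
]

logger = logging.getLogger(__name__)

#: floor applied to log-responsibilities before exponentiation
LOG_FLOOR = -745.0

#: sentinel for the hard-assignment (T -> 0) reconstruction mode
HARD = "hard"


@dataclass
class DecoderState:
    """Trial-independent decoder quantities, computed once per model/prior."""

    D: np.ndarray  # (p, p)
    U: np.ndarray  # (C, p, p)
    Q: np.ndarray  # (C, p, p)
    logdet_U: np.ndarray  # (C,)
    Um: np.ndarray  # (C, p) = U_c m_c
    mDUm: np.ndarray  # (C,) = m_c' D U_c m_c
    temperature: float | str = HARD

    @property
    def n_components(self) -> int:
        return self.U.shape[0]


@dataclass
class DecodeResult:
    """Per-trial outputs of :func:`decode_batch`."""

    reconstructions: np.ndarray  # (N, p)
    winners: np.ndarray  # (N,) int cluster indices
    responsibilities: np.ndarray  # (N, C)
    letter_probabilities: np.ndarray | None = None  # (N, L)
    predicted_labels: np.ndarray | None = None  # (N,)
    cluster_means: np.ndarray | None = field(default=None, repr=False)


def _check_temperature(T) -> None:
    if T == HARD:
        return
    if not (np.isscalar(T) and float(T) > 0):
        raise ValueError(
            "temperature must be positive or the 'hard' assignment mode"
        )


def precompute_state(
    model: EncodingModel, prior: MixturePrior, T: float | str = HARD
) -> DecoderState:
    """Cache D, U_c, Q_c, log det U_c and the prior-mean products.

    The model is restricted to its selected voxels.  ``(I + R_c D)`` is LU
    factorized once per cluster; U_c and its log-determinant both come from
    that factorization, and Q_c = U_c R_c is symmetrized to absorb solver
    round-off.
    """
    _check_temperature(T)
    sel = model.selected
    Bs = model.B[:, sel]
    s2 = model.sigma2[sel]
    p = Bs.shape[0]
    if prior.n_pixels != p:
        raise ValueError("prior pixel count does not match encoding model")
    D = (Bs / s2) @ Bs.T
    D = 0.5 * (D + D.T)

    C = prior.n_components
    U = np.empty((C, p, p))
    Q = np.empty((C, p, p))
    logdet_U = np.empty(C)
    Um = np.empty((C, p))
    mDUm = np.empty(C)
    I = np.eye(p)
    for c in range(C):
        R = prior.covariances[c]
        M = I + R @ D
        sign, ld = np.linalg.slogdet(M)
        if sign <= 0:
            raise np.linalg.LinAlgError(
                f"(I + R_c D) is not positive for cluster {c}"
            )
        try:
            lu = lu_factor(M)
        except np.linalg.LinAlgError as err:  # pragma: no cover - PSD inputs
            raise np.linalg.LinAlgError(
                f"(I + R_c D) is singular for cluster {c}"
            ) from err
        Uc = lu_solve(lu, I)
        Qc = Uc @ R
        U[c] = Uc
        Q[c] = 0.5 * (Qc + Qc.T)
        logdet_U[c] = -ld
        Um[c] = Uc @ prior.means[c]
        mDUm[c] = float(prior.means[c] @ (D @ Um[c]))
    return DecoderState(
        D=D, U=U, Q=Q, logdet_U=logdet_U, Um=Um, mDUm=mDUm, temperature=T
    )


def transform_response(model: EncodingModel, y: np.ndarray) -> np.ndarray:
    """Map a standardized selected-voxel response into image space.

    Computes ``fbar(y) = B Sigma^{-1} y`` on the selected-voxel subspace;
    ``y`` must already be standardized by the model's stored training
    transform and restricted to selected voxels.
    """
    sel = model.selected
    y = np.asarray(y, dtype=float)
    if y.shape != (int(sel.sum()),):
        raise ValueError(
            f"expected a response over the {int(sel.sum())} selected voxels, "
            f"got shape {y.shape}"
        )
    return model.B[:, sel] @ (y / model.sigma2[sel])


def posterior_mean(state: DecoderState, f_bar: np.ndarray, c: int) -> np.ndarray:
    """Cluster-conditional posterior mean ``n_c(y) = Q_c fbar + U_c m_c``."""
    return state.Q[c] @ f_bar + state.Um[c]


def log_responsibilities(
    state: DecoderState,
    prior: MixturePrior,
    f_bar: np.ndarray,
    log_prior_weights: np.ndarray | None = None,
) -> np.ndarray:
    """Normalized ``log P(c|y)`` from the cached per-cluster quantities.

    ``log_prior_weights`` defaults to ``log pi_c``; semantic gating passes
    per-trial ``log P(c|z)`` instead.  Terms independent of c are absorbed
    by the log-sum-exp normalization, so the output always exponentiates to
    a simplex.
    """
    if log_prior_weights is None:
        log_prior_weights = np.log(prior.weights)
    log_prior_weights = np.asarray(log_prior_weights, dtype=float)
    if log_prior_weights.shape != (state.n_components,):
        raise ValueError("log_prior_weights length must match cluster count")
    if np.all(np.isneginf(log_prior_weights)):
        raise ValueError("all prior weights are zero")
    if np.any(np.isnan(log_prior_weights)) or np.any(log_prior_weights == np.inf):
        raise ValueError("log_prior_weights must be finite or -inf")

    quad = 0.5 * np.einsum("i,cij,j->c", f_bar, state.Q, f_bar)
    cross = state.Um @ f_bar
    lr = log_prior_weights + 0.5 * state.logdet_U + quad - 0.5 * state.mDUm + cross
    lr = lr - logsumexp(lr)
    return np.clip(lr, LOG_FLOOR, None)


def reconstruct(
    state: DecoderState,
    prior: MixturePrior,
    f_bar: np.ndarray,
    responsibilities: np.ndarray,
    T: float | str = HARD,
) -> tuple[np.ndarray, int]:
    """Combine per-cluster posterior means into the final reconstruction.

    In hard mode (the T -> 0 limit, the default) the reconstruction is the
    posterior mean of the most probable cluster, ties broken toward the
    lowest cluster index.  With finite T the weights are the tempered
    softmax ``w_c proportional to P(c|y)^(1/T)``; T = 1 reduces to the raw
    responsibilities.  Returns ``(x_star, winning_cluster)``.
    """
    _check_temperature(T)
    r = np.asarray(responsibilities, dtype=float)
    if abs(r.sum() - 1.0) > 1e-6 or np.any(r < 0):
        raise ValueError("responsibilities must form a simplex")
    winner = int(np.argmax(r))  # argmax takes the lowest index on ties
    if T == HARD:
        return posterior_mean(state, f_bar, winner), winner
    logr = np.log(np.clip(r, np.exp(LOG_FLOOR), None))
    logw = logr / float(T)
    w = np.exp(logw - logsumexp(logw))
    x = np.zeros(prior.n_pixels)
    for c in range(state.n_components):
        x += w[c] * posterior_mean(state, f_bar, c)
    return x, winner


def letter_probability(
    responsibilities: np.ndarray, label_table: np.ndarray
) -> np.ndarray:
    """Marginal label probabilities ``P(l|y) = sum_c P(c|y) P(l|c)``."""
    r = np.asarray(responsibilities, dtype=float)
    table = np.asarray(label_table, dtype=float)
    out = r @ table
    return out / out.sum()


def decode_batch(
    model: EncodingModel,
    prior: MixturePrior,
    responses: ResponseSet,
    gating_log_weights: np.ndarray | None = None,
    T: float | str = HARD,
) -> DecodeResult:
    """Decode every trial of a response set.

    Raw responses are standardized by the model's stored training transform
    and restricted to selected voxels; per-cluster matrices are computed
    once and only ``fbar(y)`` varies per trial.  When the prior carries a
    label table, per-trial label probabilities and predicted labels are
    attached.  ``gating_log_weights`` (N x C log-probabilities from a
    fitted gating model) replace ``log pi_c`` trial by trial.
    """
    state = precompute_state(model, prior, T)
    Y = model.standardize(responses.data)[:, model.selected]
    N = Y.shape[0]
    C = prior.n_components
    if gating_log_weights is not None:
        gating_log_weights = np.asarray(gating_log_weights, dtype=float)
        if gating_log_weights.shape != (N, C):
            raise ValueError("gating_log_weights must be (n_trials, n_clusters)")

    recon = np.empty((N, prior.n_pixels))
    winners = np.empty(N, dtype=int)
    resp = np.empty((N, C))
    letter = None
    pred_labels = None
    if prior.label_table is not None:
        letter = np.empty((N, prior.label_table.shape[1]))
    for n in range(N):
        f_bar = model.B[:, model.selected] @ (Y[n] / model.sigma2[model.selected])
        logw = None if gating_log_weights is None else gating_log_weights[n]
        lr = log_responsibilities(state, prior, f_bar, logw)
        r = np.exp(lr)
        r = r / r.sum()
        resp[n] = r
        recon[n], winners[n] = reconstruct(state, prior, f_bar, r, T)
        if letter is not None:
            letter[n] = letter_probability(r, prior.label_table)
    if letter is not None and prior.label_names is not None:
        pred_labels = prior.label_names[np.argmax(letter, axis=1)]
    return DecodeResult(
        reconstructions=recon,
        winners=winners,
        responsibilities=resp,
        letter_probabilities=letter,
        predicted_labels=pred_labels,
    )
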