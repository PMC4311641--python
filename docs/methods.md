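# Methods

## Model

`gmmdecode` treats image reconstruction as inference in a two-layer
generative model.  The observation layer is a linear Gaussian encoding
model: for an image `x ∈ R^p` (a flattened H×W grayscale grid) each voxel
`i` responds `y_i = β_i'x + ε_i` with independent noise
`ε_i ~ N(0, σ²_i)`.  The latent layer is a Gaussian-mixture image prior
`P(x) = Σ_c π_c N(x; m_c, R_c)` whose components correspond to semantic
categories or to unsupervised clusters of a prior image set.  Conditioned
on the component, likelihood and prior are both Gaussian in `x`, so the
posterior `P(x|y,c)` is Gaussian with mean `n_c(y) = Q_c f̄(y) + U_c m_c`,
where `D = B Σ⁻¹ B'`, `U_c = (I + R_c D)⁻¹`, `Q_c = U_c R_c`, and
`f̄(y) = B Σ⁻¹ y` is the response projected into image space.  Component
responsibilities `P(c|y)` come from the marginal likelihood of `y` under
each component and are computed in log space with five per-cluster terms
plus a log-sum-exp normalization; the normalization absorbs all terms
that do not depend on `c`, so the absolute value of `log P(y|c)` is never
needed.

Two deliberate consequences of this formulation:

- `R_c` is never inverted.  All per-cluster quantities come from a
  factorized linear solve against `(I + R_c D)`, so rank-deficient or
  even zero prior covariances are handled exactly (with `R_c = 0` the
  posterior collapses to the prior mean, as it must).  `Q_c` is
  symmetrized after the solve to absorb solver round-off.
- The decoder caches everything trial-independent (`D`, `U_c`, `Q_c`,
  `log det U_c`, `U_c m_c`, `m_c'D U_c m_c`), so decoding a trial costs
  `O(C p²)`.

Reconstruction uses hard assignment by default — the posterior mean of
the most probable component, the limit of tempered weights
`w_c ∝ P(c|y)^{1/T}` as `T↓0` — because averaging across components blurs
images from different categories into each other.  Finite `T` is exposed
for the weighted variant; `T = 1` uses the raw responsibilities.  Argmax
ties break toward the lowest component index, deterministically.

## Encoding fit

Responses are standardized per voxel (training mean 0, variance 1) inside
the fit; the same affine transform is stored on the model and applied to
test responses.  The ridge estimator is `β̂ = (X'X + λI)⁻¹X'y`.  Penalties
are selected per voxel from an L-point grid (default L = 30) placed so
that the effective degrees of freedom `df(λ) = Σ_j d_j²/(d_j² + λ)` are
evenly spaced between `rank(X)` and `rank(X)/L`; each grid point is found
by monotone bisection to within 1e-6 in df.  Selection minimizes the
population variance of mean-centered held-out residuals concatenated
across K = 5 shuffled folds (stratified by stimulus category when labels
exist), with ties broken toward the larger penalty; the residual variance
at the chosen penalty is the voxel's noise estimate `σ̂²`.  On
unit-variance responses `σ̂² ≈ 1` means the voxel carries no stimulus
information, so the informative-voxel filter keeps `σ̂² ≤ 0.99`
(boundary inclusive).  The SVD of the design is computed once per fold
and shared across the entire penalty grid and all voxels, making the fit
`O(N²p)` rather than `O(p³)` per voxel.

Numerical details: singular values below `max(d)·1e-12` count as zero for
rank; zero-variance residuals floor `σ̂²` at machine epsilon with a
warning; an unpenalized fit on a rank-deficient design raises rather than
silently returning one of many minimizers.

## Priors

Prior images are normalized by a global min-max rescale to [0, 1]
followed by scaling each image to unit Euclidean norm; the parameters are
stored and the identical transform is applied to train/test stimuli.
This choice (per-image norm rather than per-pixel z-score) keeps pixel
covariances on a common scale across images and makes the transform
idempotent.  Supervised components use each label's sample mean and
1/N_c covariance; unsupervised components come from K-means (Euclidean,
k-means++ init, best of 10 restarts, ≤ 300 iterations) with the centroid
as mean and the 1/N_c covariance of assigned members about it.  Component
weights default to uniform 1/C (empirical proportions are a flag).
Because the decoder never inverts `R_c`, no shrinkage is applied; only
singleton or rank-0 clusters receive a diagonal jitter of 1e-6 times the
mean pixel variance so their log-determinant terms stay finite.  Empty
clusters are re-handled by K-means itself; if one survives to moment
estimation it is dropped with a warning and the weights renormalized.

A row-stochastic table `P(l|c)` — label frequencies of the prior images
assigned to each cluster — converts cluster responsibilities into label
probabilities `P(l|y) = Σ_c P(c|y) P(l|c)` for classification with
unsupervised priors.  For supervised priors the table is the identity.

## Semantic gating

`P(c|z)` is an over-parameterized multinomial logistic model (one weight
vector per class, no reference class), fit by maximizing the mean
log-likelihood minus `λ Σ_k ||γ_k||₁` with intercepts unpenalized;
identifiability comes from the penalty plus a zero-mean constraint on the
intercepts.  The optimizer is accelerated proximal gradient ascent
(monotone FISTA): soft-thresholding prox, step 1/L with
`L = λ_max([1 Z]'[1 Z]) / (2N)`, and a restart safeguard that re-takes a
plain proximal step from the incumbent whenever momentum would lower the
objective — so the objective path is non-decreasing by construction.
Convergence is declared at relative objective change below 1e-6 (default
cap 1000 iterations).  The penalty grid has 20 points log-spaced over
three decades down from `λ_max`, the smallest penalty with an all-zero
solution (computed from the gradient at the intercept-only optimum), and
is searched by 10-fold stratified cross-validated held-out log-likelihood
with warm starts from sparse to dense, ties toward the sparser model.

Gating enters the decoder by substituting per-trial `log P(c|z)` for
`log π_c` in the responsibility computation — no extra mixing weight —
so a uniform gate reproduces ungated decoding bit for bit.  Gating is
intended for supervised (category-aligned) priors; gating unsupervised
clusters is possible through the same interface but unvalidated, since
cluster splits are rarely balanced enough to estimate the logistic model
well.

## Evaluation

SSIM follows the standard windowed formulation: 11×11 Gaussian window
(σ = 1.5), stabilizers `C1 = (0.01·L)²`, `C2 = (0.03·L)²` with data range
`L` taken from the joint span of the two images being compared.  Images
smaller than the window fall back to a single uniform window with a
warning.  Both mean and sum of per-trial SSIM are reported, since the sum
scales with test-set size.  Classification is exact counting of correct
most-probable-label assignments; the chance level is `1/n_categories`.
Two discriminative baselines contextualize the generative decoder: ridge
regression straight from responses to pixels (same penalty-grid CV
machinery with the roles of images and responses swapped, both sides
centered so uninformative responses shrink to the training pixel mean),
and l1-multinomial-logistic classification straight from the low-level
responses (the gating implementation applied to `y`).

## Synthetic data

The simulator generates what the model assumes, at a scale where the
`p × p` covariance algebra runs in seconds: 12×12 glyph images (p = 144)
from up to eight binary templates (bars, cross, diagonals, ring, square,
checkerboard), each instance toroidally shifted by ±1 pixel and perturbed
with Gaussian pixel noise (sd 0.10, clipped to [0, 1]); voxel responses
from unit-norm Gaussian receptive fields at random grid locations (width
2 px) with diagonal Gaussian noise; and gating responses that place each
category at `snr ×` an orthonormal embedding vector plus unit Gaussian
noise.  `response_noise` is defined relative to each voxel's signal sd
over the training stimuli, so it equals `1/√SNR`; the default `2^{-1/2}`
gives per-voxel SNR ≈ 2.  Default sizes: 200 prior images per category,
300 train and 60 test trials, 200 voxels, 30 gating voxels.  Responses
are simulated from the *normalized* images, so the linear forward model
holds exactly in the space the decoder works in.

What the simulator deliberately does not emulate: hemodynamic dynamics,
spatial autocorrelation of fMRI noise, trial-order effects, subject
motion, or the heavy-tailed variability of real BOLD estimates.  Passing
tests therefore demonstrate correctness of the inference machinery and
qualitative behavior of the method under its own model class — not
performance on real recordings, where voxel selection and noise modeling
dominate.

## Problem sizes used in tests

The test suite and `scripts/acceptance.py` use the default bundle above
for recovery and sweep checks, and a reduced bundle (60 prior images per
category, 180 train / 36 test trials, 100 voxels) with `response_noise =
3.0` (per-voxel SNR ≈ 1/9) and `gating_snr = 3.0` for the
gating-benefit comparison, where low-level responses must be ambiguous
for gating to have room to help.  Analytic identities (responsibilities
vs marginal Gaussian densities, posterior mean vs information form,
SVD path vs direct solves) are checked on batches of random small
instances at tolerances of 1e-8, and against dense-grid numerical
integration at 1e-3.

## Known limitations

- The hard-assignment reconstruction inherits the prior's failure mode:
  when the wrong component wins, the reconstruction is a plausible image
  of the wrong category.
- Covariances are estimated without shrinkage; with very few images per
  component the posterior can overfit the component subspace (mitigated,
  not removed, by the decoder's tolerance of rank deficiency).
- The unsupervised sweep treats the cluster count as an external choice;
  no model-selection criterion is provided.
- Min-max normalization is estimated from the prior set; stimuli far
  outside the prior's intensity range would be clipped only implicitly by
  the unit-norm step.
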