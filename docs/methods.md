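# Methods

This note documents the models, estimation procedures, numerical choices
and known limitations of `hmmkernels`. It is the place where design
decisions that were genuinely open are recorded, in the package's own
terms.

## The Gaussian HMM and its estimation

The observation model is a K-state hidden Markov chain with multivariate
Gaussian emissions: q₁ ~ Cat(π), q_t | q_{t−1}=k ~ Cat(A_k), and
x_t | q_t=k ~ N(μ_k, Σ_k). Channels are z-scored per subject
(population-SD convention) before modelling, so state means are patterns
of relative amplitude and state covariances are functional-connectivity
patterns. A `zero_mean` flag pins all μ_k to zero, leaving a
covariance-only (Wishart-like) state model; it is a configuration flag,
not a separate code path.

**Estimation** is maximum-a-posteriori EM (Baum–Welch) on the concatenated
data of all subjects, with each subject (or session) treated as an
independent chain restarting from π:

- *Initialisation*: k-means on pooled timepoints (subsampled to at most
  20,000 rows) for the state means, the pooled covariance for every
  state, uniform π, and a sticky transition matrix (diagonal 0.9).
  `n_restarts` (default 3) k-means seeds are tried and the best final
  log-likelihood is kept. All randomness flows from a single seed.
- *Regularisation*: each M-step adds `cov_reg · trace(Σ_k)/M` (default
  `cov_reg = 1e−5`) to the covariance diagonal, which keeps Σ_k SPD when
  a state's occupancy is low. π is re-estimated from the first timepoint
  of each session, smoothed by ε = 1e−3 and renormalised, so single-chain
  fits do not produce a degenerate one-hot π.
- *Convergence*: relative log-likelihood change below 1e−6 or 500
  iterations. The training log-likelihood is non-decreasing up to the
  (tiny) effect of the regulariser; tests allow 1e−6 slack.
- *Numerics*: forward–backward uses the scaled recursions (per-timepoint
  normalisation with a per-row shift of the emission log-densities), so
  likelihoods are stable for T ≥ 10⁴. The inner recursions are compiled
  with numba.

**Dual estimation** re-runs EM on a single subject's data initialised at
the group parameters, for at most 10 iterations at tolerance 1e−5. The
short, anchored schedule is deliberate: it keeps subject models in the
group model's basin so state identities are preserved without any
relabelling step. A state whose total posterior occupancy falls below
`min_occupancy` timepoints keeps the group values for its Gaussian (the
event is logged), rather than being dropped or collapsing.

## Fisher scores and kernels

The Fisher score of subject n is the gradient of their data
log-likelihood at the group parameters. For the Gaussian blocks the
closed forms in the forward–backward posteriors γ, ξ are

- ∂/∂μ_k = Σ_t γ_t(k) Σ_k⁻¹ (x_t − μ_k)
- ∂/∂Σ_k = ½ Σ_t γ_t(k) [Σ_k⁻¹ (x_t − μ_k)(x_t − μ_k)ᵀ Σ_k⁻¹ − Σ_k⁻¹]

with the full M×M gradient matrix stored per state (K·M² entries), so the
feature count matches the naive vectorisation.

For the probability blocks (π and the rows of A) the default gradients
are taken in the **natural (softmax) parameterisation**:

- g_π = γ₁ − π (summed over sessions)
- g_{A,jk} = Σ_t ξ_t(j,k) − A_jk Σ_{t,k'} ξ_t(j,k')

This is the classical Fisher-score form for HMM transition parameters.
The choice matters: gradients taken directly on the probability scale
divide by π_k and A_jk, so rare transitions contribute terms of order
1/A_jk whose across-subject sampling variance swamps the state-parameter
signal — in the mean-difference simulation below, probability-scale
transition gradients raise the SVM error from 0% to 10–45% depending on
conditioning. The probability-scale convention (entries floored at 1e−12,
optionally row-mean-centred onto the simplex tangent) remains available
via `transition_grad="probability"` / `tangent=True`; finite-difference
tests verify each convention in its own parameterisation.

The **practical Fisher kernel** is the plain Gram matrix of the scores;
the Fisher-information whitening of the invariant kernel is available
(`whiten=True`, computed in the span of the scores) but off by default.
Gaussian variants use exp(−d²/(2τ_eff²)). Because gradient norms are
data-scale dependent, τ is interpreted by default as a **multiplier of
the median pairwise training-set distance** (τ_eff = τ · median distance)
so that the search grid τ ∈ {1/5, 1/3, 1/2, 1, 2, 3, 5} is meaningful
across problems; `relative=False` restores the literal interpretation.
The same convention applies to the KL and log-Euclidean kernels.

The naive-normalised kernel's feature z-scoring defaults to statistics
over all subjects (the convention the kernel is named for);
`stats_from=<training rows>` gives the leakage-safe variant used inside
CV pipelines.

**KL divergence between subject HMMs** uses the weighted approximation
KL(n‖m) = Σ_k ν_k [KL(A_k^n‖A_k^m) + KL(G_k^n‖G_k^m)], where ν is the
stationary distribution of the first argument's transition matrix, the
transition terms use the categorical closed form on the point estimates,
and the Gaussian terms the multivariate-normal closed form. The kernel
symmetrises as D = ½KL(n‖m) + ½KL(m‖n) before the RBF embedding. On point
estimates the categorical closed form replaces the Dirichlet closed form
a fully Bayesian treatment would use; with MAP point parameters this is
the natural reading.

## Prediction pipeline

Kernel ridge regression solves (κ + λI)α = y by Cholesky factorisation
(never an explicit inverse); predictions are ŷ = hα. Hyperparameters are
selected by grid search in an inner 10-fold loop over
λ ∈ {0.0001, 0.001, 0.01, 0.1, 0.3, 0.5, 0.7, 0.9, 1} (and τ as above for
Gaussian kernels), maximising the mean inner-fold Pearson r with ties
broken toward larger λ. Folds are group-aware (family members are never
split across folds) and randomised per repetition under a single seed;
the same fold object is intended to be shared by all methods being
compared. Confounds are regressed out of the target with coefficients
estimated on the training fold only; r and R² are computed on the
deconfounded scale, while MAXAE/NMAXAE are computed in the original scale
after adding the confound model's prediction back. The NMAXAE denominator
is the target's full-sample range. Subjects with a missing target are
removed listwise per variable before fold construction. Method
comparisons use the repeated-k-fold corrected t-test
t = mean(x) / sqrt((1/(k·r) + n₂/n₁)σ²) with k·r − 1 degrees of freedom,
and Benjamini–Hochberg FDR correction across comparisons.

Primal ridge baselines (`ridge_on_features`, with and without
tangent-space projection) handle the intercept by centring features and
target with training-fold means, which makes them the exact primal twin
of kernel ridge with a linear kernel on centred features — a property the
tests exploit as a duality oracle.

## Time-averaged baselines

Per-subject time-averaged FC is the sample covariance with Ledoit–Wolf
shrinkage by default (the conditioning of empirical covariances on real
data is otherwise unspecified). The log-Euclidean kernel is an RBF on
Frobenius distances of matrix logarithms; the tangent-space features are
vec(logm(R^{−1/2} C R^{−1/2})) with √2 off-diagonal weighting, where the
reference R is the **affine-invariant Fréchet mean** of the training
covariances (fixed-point iteration, tolerance 1e−8, 200-step cap) — the
specific mean is a documented choice among tangent-space conventions. The
time-averaged KL model reuses the Gaussian KL closed form with means
fixed at zero (channels are z-scored), symmetrised and RBF-embedded like
the HMM KL kernel.

## Synthetic data: what it emulates and what it does not

`make_base_hmm` draws a generating model meant to resemble a group HMM of
z-scored parcel fMRI: unit-scale Gaussian state means; Wishart-style
covariances (2M degrees of freedom, blended 50/50 with the identity,
rescaled to trace M) whose condition numbers land in the single-to-double
digits, as observed for parcel-level covariances; a sticky transition
matrix (diagonal 0.9) with Dirichlet(5) off-diagonal rows so transition
probabilities vary but none vanish; and Dirichlet(5) initial
probabilities. Near-singular covariances or near-zero transition
probabilities — which unconstrained Wishart/Dirichlet draws readily
produce — inflate the Σ⁻¹- and occupancy-scaled score noise far beyond
anything seen in real parcel data, and were excluded deliberately.

The three experiment designs:

- **mean**: group 2 shifts one state's mean by a Gaussian vector rescaled
  to 0.8× the minimal inter-state mean distance — strictly below it, so
  the group difference remains a within-state shift rather than a new
  state. 0.8 is the package's declared default for a bound that is
  otherwise only one-sided.
- **transition**: group 2 permutes one state's off-diagonal transition
  probabilities (non-identity permutation, self-transition untouched);
  the `transition_no_state` readout excludes state features from the
  kernels.
- **heterogeneity**: test subjects' state-1 mean shifts by b·ε while every
  subject's state-2 mean carries a continuous target Y_s/10 plus noise
  c·φ_s, with b ∈ {0.1,…,0.9} and c ∈ {0.5,…,1.9}; 50 training and 50
  test subjects per cell by default, comparing "together" vs "separate"
  group-HMM training. The ridge penalty is fixed at λ = 0.1 for this
  design's readout (the grid-search machinery is available but the
  design's purpose is the together/separate contrast, not absolute
  accuracy).

Defaults are the study-scale conditions (100 subjects per group, T = 1200
timepoints, M = 50 channels, K = 6 states, 10 repetitions); the test
suite and the acceptance script run a scaled-down configuration
(30 + 30 subjects, T = 600, M = 20, 5 repetitions) chosen as the
package's desk-scale reference point. Every repetition randomises on
three levels — simulation noise, HMM initialisation, and CV fold
assignment — all derived from one master seed, and repeated runs are
bit-for-bit reproducible.

The SVM readout uses a precomputed-kernel SVC with C = 1 (sensitivity to
C ∈ {0.1, 1, 10} is covered by tests); kernels are shifted by a diagonal
load only if their minimum eigenvalue falls below −1e−8 of the largest.

What passing these simulations does *not* show: the generator produces
subjects that are exchangeable within group, with no within-group
individual differences, no autocorrelated noise, no scanner or motion
artefacts, and no family structure. Results on it demonstrate that the
estimators and kernels behave as designed, not that any particular
accuracy will be attained on real cohorts.

### A known edge of the linear Fisher kernel

At half-duration scans (T = 600) the linear Fisher kernel's
mean-difference recovery is occasionally imperfect: in a minority of
repetitions exactly one subject (1.7%) is misclassified, while at
T = 1200 recovery is 0% in every repetition tested. The misclassified
subjects are gradient-norm outliers — the exact weakness of linear Fisher
scores that motivates the Gaussian variant, which normalises the kernel.
The behaviour is documented rather than patched: the per-repetition-zero
property should be expected only at full scan durations.

## Limitations

- Point-estimate (MAP-EM) parameters stand in for the variational
  posteriors a fully Bayesian HMM toolbox would produce; dual-estimation
  schedules are a declared convention, not a reconstruction of any
  particular toolbox's numerics.
- K is fixed by the user; no model selection over the state count.
- No autoregressive observation models, semi-Markov durations, or
  frequency-resolved states.
- The KL "kernel" is an RBF of a symmetrised divergence and is not
  guaranteed positive semi-definite; the SVM/KRR consumers tolerate the
  tiny violations observed in practice.
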