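# Methods

## Generative models

Both candidate models are diagonal linear stochastic differential equations
over `n` regions. Order 1: `dx/dt = a x + c v(t) + ω(t)`; order 2:
`d²x/dt² = a x + c v(t) + ω(t)`. The Jacobian is restricted to
self-connections (diagonal `a`), reflecting the orthogonality of the
gradient coordinates the method is meant to operate on. The second-order
equation carries no damping term: with `a < 0` each region is an undamped
stochastic harmonic oscillator of angular frequency `√(-a)`. Over the finite
durations used here its variance grows slowly and the process is accepted
as-is; this is a deliberate consequence of taking the equation of motion
exactly as written. Orders above two are excluded (Ostrogradsky-type
instabilities make them physically implausible), as are hemodynamic
convolution and nonlinear or cross-coupled dynamics.

Observations are positions plus white Gaussian noise, `y = x + ε`, for
either order. Initial conditions `x0` (and `xdot0` for order 2) are free
model parameters; this is precisely how the second-order model acquires its
extra degrees of freedom (one initial velocity per region).

## Simulation

Second-order systems are reduced to companion form (`[[0, I], [diag(a), 0]]`
over positions and velocities, noise entering the velocity block) so both
orders share one integrator. Discretization is exact for the linear drift:
the one-step transition matrix is `expm(A·dt)` (with zero-order hold on the
input, computed from the same augmented exponential) and the process-noise
covariance is the Van Loan integrated covariance. This removes
discretization bias from the model comparison — an Euler scheme would
penalize whichever order the step-size error resembles less. Trajectories
are bit-reproducible given (model, duration, dt, input spec, seed).

## Likelihood and inversion

For a given order the observation likelihood `log p(y | θ, m)` is the exact
discrete-time linear-Gaussian state-space likelihood, computed by
prediction-error decomposition with a forward Kalman filter. Because the
dynamics are diagonal and the two noise precisions are shared across
regions, the filter runs independently per region with scalar (order 1) or
2×2 (order 2) state; the inner loop is numba-compiled, and the per-region
discretization uses closed forms (trigonometric/hyperbolic for order 2,
with series fallbacks near `a = 0`) that agree with the matrix-exponential
route to machine precision. The initial latent state equals the `(x0,
xdot0)` parameters with zero covariance. Driving inputs are treated as
known regressors — only their gain `c` is estimated, not the input's form;
this affects absolute free energies but not the order comparison on data
where the input is known.

Free parameters per order (n regions): `a` (n), `c` (n), `x0` (n), plus
`xdot0` (n, order 2 only), and two noise hyperparameters parameterized as
log-precisions (`σ² = exp(-λ)`) so the whole vector is unconstrained.
Priors are independent Gaussians: zero mean, variance 1 for all couplings,
gains and initial conditions (weakly informative, "forgetting" the
generating values), and standard-normal priors on the two log-precisions.

The posterior is approximated by variational Laplace: L-BFGS-B maximizes
`log p(y|θ) + log p(θ)` (multi-start: the prior mean plus, by default, 2
jittered starts at 0.5 prior SD, seeded; best objective wins), and the
posterior covariance is the inverse of the numerical negative Hessian at
the optimum (central differences, relative step 1e-3; non-positive-definite
Hessians are repaired by eigenvalue clipping with a logged warning).
Optimizer tolerances: projected-gradient norm 1e-6 or 500 iterations;
non-convergence is flagged on the result, never raised. Parameters may be
clamped via a `fixed` mapping (a log-precision of `+inf` encodes exactly
zero noise), which is how the conjugate-regression cross-check in the test
suite isolates a single linear parameter.

## Free energy

`F = accuracy − complexity`. Accuracy is the posterior *expectation* of the
log-likelihood, `⟨log p(y|θ,m)⟩_q`, evaluated by the Gaussian second-order
expansion around the posterior mean: `ll(θ̂) − ½·tr(Σ_q H_ll)`, with the
likelihood curvature obtained as posterior curvature minus prior precision.
For these linear-Gaussian models the expansion is exact, and in the
conjugate special case F reproduces the analytic log evidence to numerical
precision (verified in the tests). Complexity is the closed-form KL
divergence from the Gaussian posterior to the Gaussian prior, hence
non-negative; the identity `F = accuracy − complexity` holds to 1e-8 by
construction on every call.

Model probabilities are the two-model softmax `p_i = e^{F_i}/(e^{F_1} +
e^{F_2})`, computed via the logistic function for stability. Ties within
1e-9 nats are classified as order 1 (parsimony) and logged.

## Gradients, surrogates, autocorrelation

The diffusion-map embedding sparsifies each FC row (keeping the top 10% by
default, ties at the cutoff included), builds a cosine-similarity affinity
(clipped at zero), applies α-normalization (α = 0.5) and eigendecomposes
the symmetric normalized diffusion operator, whose eigenvectors are
orthonormal. The trivial stationary component is removed by deflating the
known stationary eigenvector (the square root of the degree vector) rather
than by dropping the leading eigenvector — the two coincide for connected
affinity graphs, but deflation also behaves correctly when sparsification
disconnects the graph and the leading eigenvalue becomes degenerate.
Variance-explained fractions are the normalized non-trivial eigenvalues.
Component signs are fixed by making each column's largest-magnitude entry
positive. Defaults (sparsity 0.9, cosine affinity, α = 0.5) are the
conventional settings of diffusion-embedding toolboxes; the embedding is
invariant to uniform positive rescaling of the FC matrix.

Projection onto gradients is the per-timepoint Pearson correlation across
regions between the spatial map and each (centered) loading column; frames
with zero spatial variance map to 0 with a warning instead of failing a
run. The circular-shift null rotates each region's time course by an
independent uniform offset in `[0, T)`: a pure sample permutation, so
per-region means, variances, periodograms and circular autocovariances are
preserved exactly while inter-regional temporal alignment is destroyed.
Autocorrelation uses the standard biased-normalized sample ACF
(statsmodels); group curves average the per-gradient ACF within subject,
then across subjects per winning order.

## Synthetic cohorts

The generator emulates the *structure* of parcellated rest/task fMRI at the
scale of the empirical protocol: 100 regions, 400 timepoints at TR = 0.72 s,
latent dynamics of known order living directly in gradient space
(matching the fact that the inversion operates on gradient-correlation
timeseries), projected onto random orthonormal zero-mean spatial maps and
corrupted by spatial Gaussian noise (default SD 0.2).

Randomized per-subject parameters, drawn once per subject from its derived
seed: self-couplings uniform on [-1.0, -0.2] s⁻¹ (order 1) or [-1.0, -0.1]
s⁻² (order 2) — negative for stability; input gains uniform on [0.2, 1.0];
state and observation noise SDs uniform on [0.05, 0.3]; initial conditions
uniform on [-1, 1]. The random driving input is an independent block train
per region (Poisson onsets at 0.02 events/s, 15 s blocks, unit amplitude) —
block length on the order of the slowest time constants, a handful of
events per run. The "task" condition replaces it with a shared n-back-like
block design (27.5 s blocks separated by 15 s baselines); "rest" has no
input. Latent positions are standardized per dimension before projection
(amplitude normalization, as is conventional before correlating with
gradient maps); consequently the expected time-correlation between
recovered and latent series under spatial noise σ has the closed form
`1/√(1+σ²)` (0.894 at σ = 0.5), which the test suite checks.

Cohorts assign `round(order_mix · n)` subjects to order 2 and share one
gradient set; every subject derives deterministically from (spec, seed)
via SeedSequence-based hashing (all derived seeds < 2³¹). The cohort
workflow defaults generate rest cohorts with 10% and task cohorts with 55%
second-order subjects, mirroring the regime the method is intended to
characterize.

What the generator does *not* emulate: hemodynamic smoothing, 1/f BOLD
spectra, physiological noise, motion, inter-subject gradient variability.
Passing tests therefore demonstrate correctness of the machinery and
recoverability under the stated generative assumptions, not performance on
real BOLD data.

## Problem sizes and numerics

The order-recovery experiment runs 100 series (50 per order) of 3 regions ×
400 samples — about a hundredth the subject-count-×-series budget of a full
empirical study, chosen so the complete experiment re-runs in minutes on
one CPU; the result (fraction correctly classified) is scale-free. Cohort
workflow defaults (20 subjects per cell) are similarly desk-scale and
configurable. Degenerate inputs are handled explicitly: zero observation
noise routes to a slow reference filter that tolerates singular innovation
(raising a degenerate-likelihood error only if the data contradict a
zero-variance prediction); constant series make the ACF undefined (an
error) and classify as order 1 via the tie rule.

## Known limitations

- The inversion is exact-likelihood discrete-time Kalman + variational
  Laplace, not a generalised-coordinates scheme with smooth noise; absolute
  F values are not comparable with SPM's, though the accuracy−complexity
  contract and the order comparison are preserved.
- The undamped second-order model is non-stationary over long horizons;
  durations beyond a few thousand samples may need damping extensions that
  are out of scope here.
- The form of the driving input is never estimated; unknown inputs must be
  treated as state noise by the user.
- Single-subject gradient sets are assumed shared across a cohort; no
  Procrustes alignment is provided.
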