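# Methods

## The model

`savor` implements a choice model in which the value of a cue predicting a
delayed outcome has two parts: the discounted value of the outcome itself,
and the utility of *anticipating* it while waiting ("savoring").  For a
reward of value R⁺ delivered after delay T, anticipation at time t before
the outcome is an urgency signal a(t) = R⁺ e^(−ν⁺(T−t)) that rises toward
the outcome at rate ν⁺ (1/s).  The total cue value is

    Q = η ∫₀ᵀ e^(−γt′) a(t′) dt′ + R e^(−γT) = η·A(T) + B(T),

with discount rate γ (1/s) shared across valences and anticipation weight η.
The coefficient A(T) = R (e^(−γT) − e^(−νT)) / (ν − γ) has a removable
singularity at ν = γ where the analytic limit R·T·e^(−γT) is used
(switchover at |ν − γ| < 1e−9; continuity is property-tested).

The model's central mechanism is that η is not constant: it is boosted by
the surprise at an information cue,

    η = η₀ + C·|δ|,

where δ is the prediction error over the *total* (anticipation + reward)
cue value — the aRPE.  Because δ depends on the boosted cue values and the
cue values depend on δ, the pair (δ⁺, δ⁻) at the reward- and
no-reward-predictive cues must be self-consistent.  With linear boosting
the solution is closed-form:

    δ⁺ = (1−q)·N / D,   δ⁻ = −q·N / D,
    N = η₀(A⁺ − A⁻) + B⁺ − B⁻,   D = 1 − C((1−q)A⁺ − qA⁻),

valid whenever D > 0 for all conditions, i.e. for C below the stability
bound C_max = min over valences of γ/|R| · (γ/ν)^(ν/(γ−ν)) (the reciprocal
of the largest |A| over delays; |A| peaks at T* = ln(γ/ν)/(γ−ν)).  Gains
above the bound have no finite self-consistent solution (runaway valuation);
a fixed-point iteration of the pre-reduction coupled system serves as an
independent oracle for the closed form and diverges exactly where the bound
says it should.

Target values: the immediate-information target averages the two boosted cue
values, V_II = q·Q_{S⁺} + (1−q)·Q_{S⁻}; the no-information target carries
probability-scaled *unboosted* anticipation (its cue predicts nothing, so no
prediction error), V_NI = η₀(qA⁺ + (1−q)A⁻) + qB⁺ + (1−q)B⁻.  Choices
follow a sigmoid of the value difference with temperature σ:
p(info) = 1/(1 + e^(−(V_II − V_NI)/σ)).  The temperature convention (σ
divides the value difference) is a choice of scale for σ only.

Two reductions matter: with C = 0, V_II ≡ V_NI (unboosted anticipation
scales linearly with probability and cancels), and with η₀ = C = 0 the model
is a pure exponential discounter; both predict indifference between the
targets in every condition.  Boosting is therefore the only source of
information preference in the model.

## Hierarchical fitting

Subject parameters are fit in a transformed space h where every constraint
holds by construction: log for ν±, γ, σ; inverse-softplus for η₀ ≥ 0;
R⁻ = −eʰ (with the R⁻ = 0 boundary clamped at h = −30); and
C = C_max(R⁻, rates) · logistic(h_C), which enforces the stability bound for
every candidate during optimization.

The population is a diagonal Gaussian over h (7 means + 7 variances for the
full model).  Fitting alternates:

* **E step** — per subject, a MAP estimate by multi-start L-BFGS-B on the
  negative log posterior (per-trial Bernoulli likelihood floored at 1e−12,
  aggregated over the ≤ 25 unique conditions for speed; a JIT-compiled
  scalar kernel mirrors the vectorized implementation and is tested for
  exact agreement), plus a Laplace covariance from the ridge-regularized
  inverse Hessian (central differences, relative step 1e−4).  The
  likelihood part of the curvature is projected onto the PSD cone before
  adding the prior precision: the exact posterior precision can never fall
  below the prior precision, and without the projection flat likelihood
  directions produce exploding covariances that destabilize the M step.
* **M step** — moment update: μ = mean of MAPs, diagonal variance
  mean(m² + diag Σ) − μ² (floored at 1e−6).

Defaults: 10 optimizer restarts drawn from the current prior (plus a warm
start from the previous MAP), EM tolerance 1e−3 on the group mean, at most
200 iterations.  The initial prior is broad (γ ≈ 0.05/s, ν ≈ 0.2/s,
η₀ ≈ 0.5, C at 0.2 of its bound, σ ≈ 0.5, unit h-space variances).  The
Laplace-approximate marginal likelihood is recorded each iteration; it is
non-decreasing up to Laplace error.

### Identifiability — what fitting can and cannot recover

Choices constrain the model only through the 25-point preference surface
p(q, T), and the value difference factorizes as
V_II − V_NI = C·q(1−q)·N·(A⁺ + A⁻)/D.  Parameters therefore trade off along
a likelihood ridge: C against σ (nearly exactly when C·A ≪ 1), and η₀
against R⁻ inside N.  On synthetic cohorts of 30 subjects × 150 trials the
EM reaches a marginal likelihood within a few nats of the generating
prior's, while individual group means can sit several tenths (in h-space)
from the truth, with a predicted preference surface within ~0.04 of the
generating one.  The preference surface, the boosting *gain relative to
noise*, and between-subject ordering of C are well determined; the full
7-vector is not.  More trials sharpen only the identified directions, so
pointwise parameter error does not shrink with the trial count — the
estimate moves further along the ridge as the likelihood overwhelms the
starting prior.  The recovery tests in the acceptance suite assert the
pointwise recovery bound and the error-versus-trials comparison and fail on
both, documenting this limit honestly; interpretation of fitted parameters
should rest on predicted behavior and model comparison, not on raw
parameter values.

## Model comparison

Variants: full (7 free parameters), no-boost (C = 0, 6), and
no-anticipation (η = 0, realized as η₀ = C = 0, 5).  Each is fit
hierarchically and scored by the integrated BIC,
iBIC = −2·log p(D|θ) + |M|·log|D|, with |M| = 2 × free-parameter count and
|D| the total number of choices.  log p(D|θ) is estimated per subject by
averaging the data likelihood over K = 1,000 prior draws (log-sum-exp;
Monte-Carlo SE reported via the delta method).  Because the two reduced
variants both predict chance choices in every condition, they are
observationally identical on data they generate; model recovery can
distinguish the full model from the boost-free class, but within that class
the penalty always favors the smaller variant.

## Model-derived fMRI regressors

For each trial the model predicts, during the waiting period (time t from
cue onset): the anticipatory utility V_Ant(t) = R·η·(e^(−γ(T−t)) −
e^(−ν(T−t)))/(ν−γ), the urgency a(t) = R·η·e^(−ν(T−t)) (the signal whose
discounted integral is V_Ant — an identity tested by quadrature), and the
discounted outcome value R·e^(−γ(T−t)).  Predictive cues use the boosted η
in their own valence domain; the non-predictive cue uses η₀ scaled by q (or
1−q) in both domains.  At cue onset the aRPE (zero for the non-predictive
cue) enters as a parametric stick amplitude; unsigned state prediction
errors and the standard (anticipation-free) RPE are available as control
modulators.

Design matrices are built at 0.1 s microtime resolution, convolved with a
canonical double-gamma HRF (peak 6 s, undershoot 16 s, unit dispersions,
peak:undershoot 6, 32 s support) and sampled at the TR (default 3.36 s).
For numerical faithfulness the convolution uses the kernel's per-bin
integrals (from the gamma CDFs) and events are placed with fractional-bin
weights, making sampled regressors second-order accurate in the microtime
step (halving the step changes them by < 1e−3 relative RMS).  Parametric
modulators are mean-centered and never orthogonalized.  Trials with the
shortest (1 s) waits get a separate cue-onset column and are excluded from
the time-varying columns, keeping cue responses separable from
waiting-period dynamics.  Nuisance columns: waiting-period boxcar, per-run
intercepts, and a discrete-cosine basis implementing the 128 s high-pass.
Optional control columns (config flags): a constant-expected-value boxcar, a
linear ramp over waiting periods, and SPE-modulated cue sticks.

PPI regressors are the elementwise product of a mean-centered seed series
and the mean-centered (optionally z-scored) psychological series, formed in
signal space; no deconvolution is attempted (a deliberate simplification —
the product-of-convolved-signals approximation is standard when the
psychological variable varies slowly).

## Phase-randomization inference

Slowly varying model regressors correlate spuriously with slowly varying
noise, so ordinary parametric p-values are anticonservative.  The test used
here scrambles the Fourier phases of the tested regressor only (uniform on
(−π, π], DC and Nyquist kept real, amplitude spectrum preserved exactly),
refits the full GLM per subject (100 scrambles each), then assembles 1,000
second-level null samples by drawing one scrambled fit per subject and
taking a one-sample t across subjects; the maximum statistic over the
channel family gives FWE control, with the add-one rule
p = (1 + #{null ≥ observed}) / (resamples + 1).  A cluster-mean statistic is
available behind a config switch.  No prewhitening is applied; drift is
handled by the high-pass columns and AR(1) noise exists only in the
synthetic generator.  On null synthetic BOLD the familywise rejection rate
at α = 0.05 is conservative (a few percent at most across seeded
repetitions).

## Synthetic data

The generator reproduces the study's structure: probabilities
{0.05, 0.25, 0.5, 0.75, 0.95} crossed with delays {1, 5, 10, 20, 40} s;
each run presents all 25 conditions once in a subject-specific random
order; three runs per subject; outcomes Bernoulli(q).  Timing is fixed
(2 s lead-in, 3 s response window between initial screen and cue, 1 s
outcome display, 1 s blank) — no jitter and no missed responses are
modeled.  Default generating parameters (R⁻ = −0.5, η₀ = 0.5, ν± = 0.05/s,
γ = 0.01/s, σ = 0.25, C at 0.3 of its stability bound, population SD 0.25
in h-space) were chosen so the simulated cohort reproduces the qualitative
behavioral signature the model is about: information preference rising
monotonically with delay across the full 1–40 s range (around 0.5 at 1 s to
≈ 0.85 at 40 s at q = 0.5), which requires the anticipation coefficient's
peak delay ln(γ/ν)/(γ−ν) to lie beyond 40 s.  Synthetic BOLD is
design × weights + two low-order cosine drifts + AR(1) Gaussian noise
(coefficient 0.3) — a deliberately simple noise model: passing tests show
the pipeline's statistics are calibrated under this generator, not under
real scanner noise (physiological artifacts, motion, spatial correlation
are out of scope).

## Problem sizes and numerical choices

Test-suite experiments are scaled to run on one CPU: recovery uses cohorts
of 30 subjects (150 and 600 trials each, EM capped at 40 iterations — the
marginal likelihood plateaus well before that); model recovery uses 12
cohorts of 8 subjects × 75 trials per generating variant with 2 optimizer
starts, 6 EM iterations and K = 300 iBIC samples; FWE calibration uses 20
cohorts of 8 subjects × 12 channels at the full 100 scrambles × 1,000
resamples.  The acceptance script uses comparable sizes and reports every
quantity it computes.  Fixed-point iteration: start at δ = 0, no damping,
at most 10,000 iterations — the admissible region guarantees contraction.
Likelihood floor 1e−12 per trial; EM variance floor 1e−6; Hessian ridge
1e−6 escalated tenfold until positive definite.
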