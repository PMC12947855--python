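# Methods

This note documents the models implemented in `reachvigor`, the choices made
where the underlying experimental protocol leaves room, and what the
synthetic cohorts do and do not establish.

## Task and design

Four targets sit on a 10 cm ring at 45°, 135°, 225° and 315°; the 135° and
315° directions lie along the arm's high-inertia axis and are coded
high-effort. Within a block of 180 trials each target carries one of the
reward probabilities {0, 1/3, 2/3, 1} (a bijection, reshuffled between the
four blocks). Schedules are pseudorandomized in sets of 36 single-target
trials: every target is cued exactly 9 times per set and rewarded exactly
round(9p) times — 9, 6, 3, 0. Two consequences are exact, not statistical:
realized reward frequency equals the nominal probability within every
complete set, and the signed prediction errors sum to zero per target per
set. In the *learned* mode (probabilities hidden) the last 36 trials of a
block are two-alternative choice trials — each of the 6 unordered pairs 6
times, no reward feedback — used to read out what was learned.

Design decisions: trial order is shuffled independently within each 36-trial
set with a seeded generator, and rewards are assigned uniformly at random to
cue repetitions under the exact-count constraint (the protocol constrains
counts, not order). Familiarization trials (16 single, plus 8 choice in
learned mode) are generated, flagged, and excluded from every analysis. The
bonus normalizer is computed as 6 unique pairs × 4 blocks = 56/3 ≈ 18.667,
the only enumeration consistent with its printed two-decimal form 18.66
(which is a truncation; the alternative reading of 6 repetitions per pair
per block would give 112 and is rejected). Reward prediction error is always
`RPE = R − E[R]`, which makes the five achievable levels
{−2/3, −1/3, 0, +1/3, +2/3}; prose orderings that disagree with this formula
are treated as label swaps.

## Hierarchical value learning

Single-target trials update the cued target's value by a delta rule whose
prediction error includes the target effort cost ("VPE" model):

    V′ᵀ = Vᵀ + η_s (R + e_sᵀ − Vᵀ),   η_s = logistic(ζ_s),
    e_sᵀ = e_s  for T ∈ {135°, 315°},  0 otherwise.

Choice trials never update values (no feedback). Values reset to 0 at the
start of each block, since reward-target assignments change between blocks;
this is an assumption, exposed as a parameter. A single effort parameter per
subject is used because only one effort contrast (major vs minor inertial
axis) exists in the design. The alternative ("reward-only") model learns
`R̂′ = R̂ + η(R − R̂)` and adds effort at decision time, `V = R̂ + e`; the two
models share asymptotes (p + e) but differ in transient dynamics and in the
prediction error they expose.

Choices follow `P(A) = logistic(τ_s (V_A − V_B))` with A/B labels arbitrary
per trial. The population hierarchy and priors are

    ζ̄ ∼ N(0, 10),  ē ∼ N(0, 5),  τ̄ ∼ N(0, 5),
    σ_ζ, σ_e, σ_τ ∼ Gamma(shape 2, rate 0.01),
    ζ_s ∼ N(ζ̄, σ_ζ),  e_s ∼ N(ē, σ_e),  τ_s ∼ N(τ̄, σ_τ).

The Gamma prior is read as shape/rate (mean 200) — extremely diffuse, with
density vanishing at 0, which conveniently keeps the joint mode away from
the σ→0 collapse. τ is left unconstrained, as the stated normal prior
admits.

### Fitting

Three routes, all over the same posterior:

* **MAP** — L-BFGS with multiple restarts on a *non-centered*
  parameterization (subject values expressed as ζ̄ + σ_ζ z_s with z_s
  standard normal; σ on the log scale with the Jacobian included). The
  non-centered form removes the funnel coupling that otherwise drives the
  joint mode into σ→0 and badly biases the fit. Laplace standard errors are
  reported from a finite-difference Hessian.
* **Ensemble MCMC** (default, `method="mcmc"`) — affine-invariant ensemble
  (emcee) on the same non-centered posterior, initialized in a small ball
  around the MAP. This is the route used for the headline recoveries; two
  independent chains agree on the population means to well within one
  posterior SD.
* **Metropolis-within-Gibbs** (`method="gibbs"`) — per-subject 3-dim
  Metropolis blocks with conjugate draws for the population means and slice
  updates for the SDs, on the centered form. Kept as a cross-check; it mixes
  slowly along the learning-rate/temperature ridge (small η with inflated τ
  mimics large η with moderate τ, because end-of-block values scale almost
  proportionally) and needs far longer runs, so it is not the default.

The likelihood core (value recursions plus Bernoulli choice terms) is
numba-compiled (~30 µs per cohort evaluation), with a pure-Python fallback.
The analytic gradient of the single-subject likelihood (propagating dV/dη
and dV/de through the recursion) exists solely to validate the
implementation against finite differences.

Model comparison reports AICc (k = 3S + 6 parameters, n = total choices),
aggregate choice accuracy at a 0.5 threshold, ROC AUC of the predicted
choice probabilities, and a paired bootstrap of the AUC difference
(resampling choices, D = mean/SD of the bootstrap differences, two-sided
normal p).

Identifiability caveat: because choices are only observed at block ends and
η ≈ 0.18 converges within ~25 trials, η is informed mainly by the
fluctuation of end-of-block values around their asymptote — a weak signal.
Posterior SDs on the population learning rate of ±0.07–0.08 at 22 subjects
are therefore expected; recovery claims are always stated relative to the
posterior SD.

## Reward history

`R̄ᵢ₊₁ = αRᵢ + (1−α)R̄ᵢ` over the single-target reward stream, starting at
R̄₀ = 0.5 (the uninformative value for binary rewards) and carried across
blocks (no reset — none is suggested by the protocol). Excluded and
familiarization trials stay in the sequence but contribute R = 0; choice
trials, having no feedback, leave R̄ unchanged.

α is estimated by profile likelihood: for each grid value, recompute every
subject's R̄ series, fit log reaction time on block, R̄, direction repeat,
standardized trial, E[R], trial×E[R] and target factors with a subject
random intercept, and record the maximized ML log-likelihood; the estimate
is the grid argmax (default grid step 0.001 on [0, 1]; analyses in the test
suite and acceptance script use 0.005–0.05 grids, ample for the ±0.1
recovery claims). The random-intercept Gaussian ML is computed by a
concentrated closed-form solver (per-group shrinkage transform + GLS, scalar
search over the variance ratio), verified against statsmodels MixedLM to
1e-3; this makes a 1001-point profile affordable where a generic mixed-model
fitter is not. Modeling log RT with Gaussian errors stands in for the
log-link Gamma regression; for the multiplicative noise the generator uses,
the two have identical argmax behavior.

## Kinematics

1 kHz traces are filtered with a third-order Butterworth applied forward and
backward (zero phase); the single-pass cutoff is pre-warped by
(√2 − 1)^(−1/6) ≈ 1.158 so the double-pass −3 dB point lands at 10 Hz.
Radial velocity is the second-order centered difference (exact for quadratic
position), one-sided at the ends. Movement onset uses a relative-threshold
detector: first post-cue sample above 5% of the post-cue speed peak, backed
off to the nearest local minimum of |v| — a stand-in for accelerometric
onset detectors, scale-invariant by construction and accurate to ±10 ms on
minimum-jerk bursts. Metrics per trial: outgoing peak radial velocity
(onset → first 10 cm crossing), time to target, maximum excursion, return
peak (largest inward speed after maximum excursion), and unsigned angular
error at the ring crossing. Exclusions (flags, never row deletions): no
onset within 4 s ("failure"), no 10 cm crossing ("double-peak"), angular
error ≥ 22.5° ("miss").

Difference traces subtract, per participant, the mean curve of a baseline
condition (the zero-expectation targets, or all RPE = 0 trials for
feedback-aligned analyses) before averaging across participants.
Feedback-aligned windows span −150 to +300 ms, velocity normalized by the
trial's outgoing peak.

## 1D time-series inference

First level: per subject, the OLS slope of normalized velocity on the trial
regressor at each millisecond (subjects with <10 usable trials are dropped).
Second level: pointwise one-sample t across subjects; the family-wise
threshold over the window is the 95th percentile of the maximum |t| under
random sign flips of whole subject curves (1000 flips, seeded) — exact under
exchangeability, replacing random-field machinery with a simpler
permutation scheme. The reported onset is the first supra-threshold sample.
Null calibration (100 synthetic replicates) keeps the family-wise error at
or below the nominal 5% within binomial error.

## Vigor regressions

Gamma log-link mixed models are estimated two-stage: per-subject Gamma GLM
(statsmodels), then an exact sign-flip test of each coefficient's
across-subject mean (enumerated up to 12 subjects, Monte Carlo beyond; the
t statistic is reported alongside). This replaces a joint GLMM +
Satterthwaite stack with subject-level inference that is robust,
deterministic, and calibrated (type-I error for the expectation effect
≤ 7.5% at α = 0.05 over 400 null replicates at study scale). Velocity-difference models (return − outgoing peak), whose residuals
are approximately Gaussian, use statsmodels MixedLM with identity link. No
multiplicity correction is applied across the RPE/reward/interaction
triplet, matching common reporting practice; this is deliberate and noted.

## Synthetic cohorts

The generator exists to give every analysis a ground truth. Per trial:

* outgoing peak velocity = exp(log 0.60 + 0.0223·value + direction offset +
  0.0209·R̄ + subject offset) × Gamma(shape 100, mean 1) noise — the gains
  mirror the magnitudes of reported log-link coefficients; multiplicative
  Gamma noise (CV 10%) reproduces the heteroskedastic, right-skewed
  velocity distributions that motivate Gamma log-link modeling;
* reaction time = exp(log 300 ms − 0.08·drive − 0.10·R̄ + subject offset) ×
  Gamma(shape 150) noise, with R̄ integrated at α = 0.647 by default;
* the velocity drive is the learned value in hidden-probability mode and
  E[R] + effort in instructed mode;
* optional 1 kHz traces: minimum-jerk excursion to 10.5 cm (so the 10 cm
  ring is crossed), 80 ms dwell, minimum-jerk return at 0.9× the outgoing
  peak, with the return phase scaled by 1 + 0.04·RPE from 212 ms after the
  ring crossing, ramped over 50 ms. The trace family is an artifact choice —
  only peaks, timing and the post-feedback modulation matter downstream.

Default cohort sizes are 42 (instructed) and 22 (learned), configurable.
What the generator does **not** emulate: 2D path curvature, endpoint error
distributions beyond the angular-miss flag, biomechanically realistic
torques, trial-to-trial autocorrelation beyond the reward-history channel,
or any cue-delay effect (the 800–1000 ms jitter is generated but inert).
Passing recovery tests therefore demonstrates that the pipeline correctly
inverts its own generative assumptions at realistic noise levels — not that
those assumptions exhaust real reaching data.

## Numerical and scaling choices

All randomness flows from explicit seeds; pipeline stages derive their seeds
from a master seed and the stage name. Problem sizes in the test suite and
acceptance script (8–22 subjects for most checks, 42 for the α recovery,
2000-sweep reduced chains, 0.005–0.05 α grids, 300–1000 permutations) were
chosen so the full suite completes in minutes while keeping every recovery
claim comfortably inside its stated tolerance; all are parameters, not
constants. Ties in predicted choice (probability exactly 0.5) resolve toward
the first-listed option — a measure-zero event under continuous parameters.

## Known limitations

* The learning-rate/temperature ridge makes η weakly identified from
  end-of-block choices alone; posterior SDs, not point estimates, carry the
  uncertainty.
* Zero-phase filtering spreads sharp velocity changes symmetrically in time
  (up to ~80 ms for the 10 Hz third-order double pass), so detected
  modulation onsets in the 1D analysis scatter around — and with strong
  effects can precede — the true latency. The second-level test itself is
  calibrated; the onset estimate inherits the filter's temporal resolution.
* The onset detector is validated only against synthetic ground truth; real
  accelerometric detectors differ in edge behavior.
* The two-stage regression weights subjects equally rather than by
  precision; with balanced designs (as here) the difference is negligible.
* `fit_vigor_model` reports a documented two-stage estimate; it never
  attempts a joint Gamma GLMM, since no maintained Python implementation
  exists.
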