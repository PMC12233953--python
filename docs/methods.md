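# Methods

This note documents the models, the synthetic-data generators, the
numerical choices, and the known limits of what the test suite shows.

## Task model

The environment is a two-armed bandit with a hidden correct side
z ∈ {−1, +1}. Rewards are Bernoulli: P(r=1) = ρ₁ if the choice matches z,
else ρ₂. Defaults are the full-task contingencies: ρ₁ = 0.75, ρ₂ = 0.
Two switching regimes are implemented:

* **cumulative_rewards** (default): z flips exactly when the agent has
  earned a per-block target drawn uniformly from {7..23}; a new target is
  drawn at each switch. This is the regime behaving animals experience.
* **per_trial**: z flips independently each trial with probability q_env.
  This is the generative process the belief-state models *assume*.

The mismatch is deliberate and preserved: belief-state models fit a
per-trial hazard q as a free parameter against a cumulative-reward task,
so q is an effective, not mechanistic, parameter. The hidden state starts
at a fair coin; each session draws an independent rng stream from
(seed, session index).

## Agents

All agents emit P(c=+1) = σ(βD + φc_prev), dropping the stickiness term on
the first trial of a session; latent state resets at session boundaries
(sessions are separate behavioural days). Model-specific rules are in the
`agents` module docstrings. Choices made where the sources were open:

* **Q initialisation** is 0.5 per option (midpoint of the reward range)
  for every RL-family model; PearceHall's forgetting attractor Q₀ equals
  that initial value.
* **RLFQ3p's forgetting factor** is ζ = 1 − (α⁺+α⁻)/2. Two renderings of
  this formula circulate; this one makes the model exactly equivalent to
  RFLR in the symmetric-rate case (e^(−1/τ) = 1 − α), which is the stated
  relationship between the two models, and is exposed alongside the
  alternative reading (`zeta_convention="mean"`).
* **RLCF** applies the learning rate selected by the sign of the factual
  RPE to both the factual and counterfactual updates.
* **RL_meta update order** per trial: δ → ν = |δ| − ω → (if δ<0) adapt α⁻
  with mixing rate ψ, clamped at 0 → ω ← ω + α_ν·ν → value update →
  unchosen value decays multiplicatively by ζ. The baseline rate α⁰⁻ is
  bound to the fitted initial α⁻. ω starts at 0.
* **PearceHall** updates the associability before the value step
  (α_ν ← α_ν + ψ(|δ|−α_ν), then Q update with α_ν·α±), and includes β and
  ψ as free parameters so its policy has the same functional form as every
  other model (7 free parameters).
* **BIfp** uses D = 2b − 1. Its β therefore differs from the equivalent
  BRL parameterisation by the factor (w₁−w₂) = ρ₁−ρ₂; the equivalence
  tests apply that rescaling explicitly.
* **Belief filtering** runs in linear space (two states; ρ₂ is floored at
  10⁻⁴ on the model side so the normaliser cannot vanish), and the belief
  is stored as a single number b = P(z=+1).
* **Pseudo-RPEs**: observed minus expected reward under the agent's
  pre-update latents; RFLR carries no reward expectation and raises a
  dedicated error.

## Fitting

Per-trial log-likelihoods are computed by numba-compiled kernels that
mirror the pure-Python agents; the test suite asserts per-trial agreement
to 1e−10, so the fast path never drifts from the readable one. Trials
with a missing choice are skipped without a state update; choice
probabilities are floored at 1e−12 before the log.

Optimisation is multi-start bounded L-BFGS-B inside the native parameter
boxes (rates and unit-interval parameters in [0,1], q ∈ [0, 0.5],
β ∈ [0, 50], φ ∈ [0, 10] except RFLR's φ ∈ [−10, 10] with β ≡ 1,
τ ∈ [0.01, 100]). Initial points are sampled from per-model
distributions — rates Unif(0,1), φ ~ Γ(shape 2, scale 0.2), β ~ Exp(1),
q ~ Unif(0, 0.05), RFLR's α ~ Exp(1) and φ ~ N(0,1) — and clipped into
bounds; PearceHall reuses the same families for shared parameters since
no dedicated ones are documented. Start streams are nested in
(seed, start index), so increasing the number of starts can only improve
the returned optimum. Default 10 starts. We considered transforming
parameters to an unconstrained scale but found native box constraints
equally robust on these smooth objectives and simpler to audit.

AIC = 2k − 2 log L, reported relative to RL4p. The around-switch variant
runs latents over the full sequence but sums log-likelihood only over the
first 5 trials of each post-switch block, reusing the global fits (the
subset is too small to refit stably; k is unchanged).

## Model identification and recovery

The three-stage protocol (simulate from empirical-style uniform ranges →
cross-fit all candidates → row-normalised argmin-AIC counts) is run with
deterministic per-iteration rng streams and a deterministic AIC tie-break
(fewest parameters, then name). The shipped `DEFAULT_RANGES` are plausible
stand-ins for animal-fit ranges: learning rates high (mice in this task
are fast learners), hazard rates bracketing the true ~1/15-per-trial
switch frequency, β giving clearly value-driven but stochastic choice.
They are settings, not measurements.

Parameter recovery refits the generating model to its own simulations and
reports per-parameter Pearson r after masking estimates more than 6 SD
(of the true-parameter distribution) from the true-parameter mean.
Directly identified parameters recover well at 5 sessions × 500 trials
(Bayesian β and q, RL4p/RLCF/RLFQ3p learning rates: r ≈ 0.8–0.98).
RL_meta's adapted α⁻ and PearceHall's α⁺ are structurally confounded —
only the product with the associability / adaptation path is identified —
so their recovery correlations are reported but not treated as pass/fail
criteria; this mirrors the weak identifiability of the most complex
models in the confusion study, where misattribution stays within model
families.

## Synthetic data: what it emulates and what it does not

* **Behaviour**: agent-in-the-loop sessions reproduce block structure,
  reward stochasticity, and model-specific choice dynamics. They contain
  no missed trials, no motivation drift, and no cross-session learning,
  so passing tests speak to the algorithms, not to mouse idiosyncrasies.
* **Event timing**: log-normal/exponential families sized so typical
  draws pass the trial-quality filters (center poke ≤ 0.8 s, port
  lingering ≤ 6 s, travel ≤ 3 s, side-out bout gap ≤ 1 s, all inclusive);
  rewarded trials linger longer at the port. An `outlier_frac` knob
  pushes that fraction of trials outside at least one filter.
* **Dopamine summaries** (`synthesize_da`): da_pt is linear in RPE with
  separate gains by RPE sign (defaults 1.5/1.5), small port-duration
  modulations (±0.05 s⁻¹), and Gaussian noise (SD 0.5 by default; 0.3 in
  the attribution studies, a mid-range signal-to-noise choice).
* **dLight traces**: two channels at 20 Hz with exponential
  photobleaching, a shared smoothed random-walk motion artifact (scaled
  0.9 in the reference), transients with 0.1 s saturating rise and
  exponential decay (lengthening with port duration in the RPE-driven
  generator), and white noise. The default noise level is SNR 4, with
  SNR = SD(transient trace)/SD(noise), typical of usable dLight
  recordings. Note a ceiling: the correlation between the true transient
  trace and *any* corrected but unsmoothed trace cannot exceed
  (1 + SNR⁻²)^(−1/2) — 0.894 at SNR 2, 0.970 at SNR 4 — so the r ≥ 0.9
  recovery bar tests artifact and bleach removal, not denoising.

## Photometry numerics

airPLS uses a sparse second-difference Whittaker smoother, weight decay
exp(i·|d|/dssn) on below-baseline residuals, termination when the
negative-residual mass falls under 0.1% of total signal mass, λ = 10⁸ at
20 Hz, max 50 iterations. Isosbestic correction is a Huber-loss robust
regression (statsmodels RLM defaults) of signal on reference, subtracting
the fit; a zero-variance reference skips the step with a warning.
Z-scoring is per session by definition; alignment interpolates linearly
onto a ±window grid at the native 20 Hz spacing, with NaN outside the
recording span, and optionally subtracts the value at the event time
before DA-PT extraction (peak over [0, 1] s for rewarded trials, trough
for unrewarded).

The side-out bout latency filter threshold is 1 s. The duration filters
are inclusive (≤) at their thresholds.

## Linking regressions

The featurized RPE regression uses covariates rpe×sign indicators,
port_dur×the same indicators, ego action (±1 choice), session number, and
log movement/center durations floored at 10⁻³ s (natural log); Gaussian
MLE with σ² estimated on the 70% training split and held-out
log-likelihood on the remaining 30% (identical split across candidate
models; repeat-and-average option). The lagged design counts rewards at
the currently chosen vs opposite port over the past 4 trials (4 lags
capture most outcome history at negligible cost in explained variance),
interacted with switch/stay; fixed-effects OLS by default, an optional
mixed model with per-subject effects for multi-subject tables (the
synthetic default is single-subject, which falls back with a warning).
Covariate standardisation is available but off by default.

## Problem sizes

The test suite runs the studies at desk scale: recovery at 30 iterations
per model (5 × 500 trials each), identification at 20 iterations over
2 × 500-trial data sets with 2 optimizer starts per fit, attribution over
20 seeds per generating model. `scripts/acceptance.py` runs the
100-iteration versions of the recovery and identification studies. These
sizes give stable directions and correlations; confusion-matrix entries
at 20–100 iterations still carry binomial error of a few percent, which
is why tests assert orderings and masses, not individual cells.

## Known limitations

* The hazard parameter q is an effective parameter under model
  misspecification (cumulative-reward switching); its recovered values
  depend on block geometry.
* BRLwrp's fitted ρ₁/ρ₂ trade off against β and the weights; it is
  provided for completeness, not for parameter interpretation.
* The mixed-effects path delegates to statsmodels MixedLM with a random
  intercept; rich random-slope structures on small synthetic cohorts
  often fail to converge and are out of scope.
* No cross-validated or Bayes-factor model selection for the behavioural
  fits; AIC only, as the package's comparison currency.
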