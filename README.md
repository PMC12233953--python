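# beliefbandit

Cognitive modelling of two-armed-bandit (2ABT) reversal learning and its
link to mesolimbic dopamine, built for computational neuroscientists who
want to simulate the task, fit and compare trial-by-trial choice models,
and test whether model reward-prediction errors (RPEs) explain
photometry-style dopamine measurements.

## The problem and the models

In the probabilistic-switching 2ABT an animal chooses a left or right port
(c_t ∈ {−1, +1}); a hidden state z_t ∈ {−1, +1} names the currently correct
port. Correct choices are rewarded with probability ρ₁ = 0.75, incorrect
ones with ρ₂ = 0, and the correct side reverses un-cued after the animal
earns a uniformly drawn 7–23 rewards. Because reward omission is ambiguous
(it happens 25% of the time even at the correct port), doing well requires
weighing outcome sequences, not single outcomes.

All agents share one choice policy,

    P(c_t = +1) = σ(β·D_t + φ·c_{t−1}),

with inverse temperature β, stickiness φ, and a model-specific decision
variable D_t:

| model | decision variable | learning rule |
|---|---|---|
| RL4p | Q(+1) − Q(−1) | δ-rule with asymmetric rates α⁺/α⁻ |
| RLCF | same | plus counterfactual update of the unchosen Q |
| RLFQ3p | same | forgetting: unchosen Q decays by ζ = 1 − (α⁺+α⁻)/2 |
| RFLR | D itself | D ← e^(−1/τ)·D + α·r·c (β ≡ 1) |
| RL_meta | same as RL4p | α⁻ adapts to unexpected uncertainty ν = |δ| − ω |
| PearceHall | same | associability α_ν tracks recent |δ| and gates learning |
| BIfp | 2b − 1 | pure Bayesian filtering of the belief b = P(z = +1) |
| BRLfwr/fw/wrp | (w₁−w₂)(2b−1) | belief-weighted values with gradient-learned weights |

The belief-state models run the two-state HMM forward recursion
b_{t+1}(z) ∝ Σ_z̃ P(z|z̃) b_t(z̃) P(r_t|c_t, z̃) with a fitted per-trial
switch rate q. Models are fitted per subject by multi-start maximum
likelihood and compared with AIC = 2k − 2 log L relative to the RL4p
baseline. A simulate → cross-fit → confusion-matrix protocol quantifies
model identifiability, and a parameter-recovery study correlates true with
refitted parameters.

The photometry side preprocesses paired 470 nm (dLight) / 415 nm
(isosbestic) traces — airPLS baseline removal, robust isosbestic
regression, per-session z-scoring — aligns the result to outcome events,
and summarizes each trial as DA-PT (the post-outcome peak for rewarded
trials, trough for unrewarded). Regressions with featurized covariates
then arbitrate which model's RPE sequence best explains DA-PT by held-out
log-likelihood, alongside a lagged reward design (R_chosen / R_unchosen
counts over the past 4 trials, split by switch/stay).

All data are synthetic: the task simulator, event-timing generator, and an
RPE-driven dLight generator stand in for animal recordings.

## Worked example

```bash
python examples/01_simulate_and_fit.py
```

```
simulated 2500 trials; overall accuracy 0.808
true parameters:    {'beta': 3.0, 'phi': 0.5, 'q': 0.05}
recovered (BIfp):   {'beta': 3.0102, 'phi': 0.574, 'q': 0.0526}
model  k      loglik         aic   delta_aic
 BIfp  3 -681.679608 1369.359216 -158.297278
 RL4p  4 -759.828247 1527.656495    0.000000
```

Five 500-trial sessions are simulated from a Bayesian-inference agent;
maximum likelihood recovers its parameters closely, and the AIC comparison
(delta relative to RL4p; more negative = better) correctly prefers the
generating Bayesian model. The other examples cover model identification
(`02`), behavioural history statistics (`03`) — e.g. simulated agents stay
after a single unrewarded outcome (P(stay|RU) ≈ 0.89) but abandon the port
after two (P(stay|UU) ≈ 0.30) — the photometry chain (`04`), and
RPE-to-dopamine attribution (`05`).

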