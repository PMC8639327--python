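# riskval

Behavioral and neural model comparison for risky choice.

Competing theories of subjective valuation — expected utility (EU),
prospect theory (PT), and mean-variance-skewness (MVS) — often predict
nearly the same choices, which makes it hard to decide which computation a
decision-maker (or a brain region) actually performs. `riskval` implements
the full comparison pipeline for binary-lottery tasks: maximum-likelihood
fitting of the three models to choices, AICc-based classification and
random-effects Bayesian model selection (BMS), quantification of how
interchangeable the models' predictions are, a loss-aversion reanalysis for
50/50 mixed gambles, and a simulated-fMRI pathway that compares the models
on region-of-interest BOLD data via closed-form linear-model evidence. A
synthetic-data module generates every input the pipeline needs, so the
whole analysis is reproducible at desk scale.

## The models

A lottery `x = (x1, p; x2, 1-p)` pays `x1` points with probability `p` and
`x2` otherwise (`x1 ≥ x2 ≥ 0`):

- **EU**: `U(x) = p·x1^ρ + (1-p)·x2^ρ`, with curvature `ρ > 0`.
- **PT** (gains only): `U(x) = w(p)·x1^ρ + (1-w(p))·x2^ρ` with the
  Goldstein–Einhorn weighting `w(p) = δp^γ / (δp^γ + (1-p)^γ)`
  (elevation `δ`, curvature `γ`).
- **MVS**: `U(x) = β_μ·Mean(x) + β_σ·Variance(x) + β_γ·Skewness(x)`, with
  skewness set to 0 for sure outcomes.

Choices follow the Luce rule `P(left) = 1 / (1 + exp(V_R - V_L))` (a unit-
temperature softmax), which also serves as the likelihood for fitting.
Certainty equivalents put all three models on a common points scale for the
neural parametric modulators and the value-correlation analyses.

At the neural level, each model supplies two trialwise regressors — the
*state value* (sum of both options' certainty equivalents at option
presentation) and the *value difference* (|CE_L − CE_R| at the decision) —
which are HRF-convolved into a GLM. A conjugate Bayesian linear model gives
each model's log evidence on the same BOLD data, and random-effects BMS
over subjects yields expected model frequencies and exceedance
probabilities per region.

## Worked example

```bash
python examples/fit_behavior.py
```

simulates one probability-distorting agent (PT, `ρ=0.9, δ=0.8, γ=0.6`) on a
180-pair battery and refits all three models:

```
 EU: LL =   -27.18  AICc =   56.38  accuracy = 91.7%  params = EUParams(rho=0.8417...)
 PT: LL =   -12.22  AICc =   30.57  accuracy = 96.1%  params = PTParams(rho=1.1027, delta=0.5234, gamma=0.6251)
MVS: LL =   -26.01  AICc =   58.16  accuracy = 91.7%  params = MVSParams(beta_mu=0.6278, beta_sigma=-0.0057, beta_gamma=0.2598)

AICc classification (margin > 2 over both rivals): PT
```

PT wins the AICc comparison, as it should for a probability-distorting
agent — but note how close the three accuracies are: all three models
predict over 90% of the same agent's choices. That prediction similarity is
the phenomenon the package is built to quantify, and the reason model
comparison is extended to the neural level. The other scripts in
`examples/` walk through the similarity analysis, the mixed-gamble
loss-aversion link, group-level BMS, and the neural model comparison.

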