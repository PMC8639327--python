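# Methods

This note documents the models, the estimation and model-selection
procedures, the synthetic-data generators, and the numerical and design
choices made where the problem left the design open.

## Valuation models and choice rule

All three models assign a scalar subjective value to a two-outcome lottery
`x = (x1, p; x2, 1-p)` with nonnegative outcomes in task points (1 point =
0.25 CHF):

| Model | Value | Free parameters |
|---|---|---|
| EU  | `p·x1^ρ + (1-p)·x2^ρ` | `ρ > 0` (curvature) |
| PT  | `w(p)·x1^ρ + (1-w(p))·x2^ρ` | `ρ, δ, γ > 0` |
| MVS | `β_μ·m + β_σ·v + β_γ·s` over the moments `(m, v, s)` | `β_μ > 0`; `β_σ, β_γ` free |

The PT weighting is the two-parameter Goldstein–Einhorn form
`w(p) = δp^γ / (δp^γ + (1-p)^γ)`; the weight applies to the *high* outcome
and the low outcome receives `1 - w(p)`. PT nests EU at `δ = γ = 1`.
Gains only: the task has no losses, so no loss-domain value function or
loss-aversion parameter appears here (mixed gambles are handled
separately, below).

Lottery moments are `m = p·x1 + (1-p)·x2`, `v = p(1-p)(x1-x2)²`, and the
standardized skewness `s = (1-2p)/√(p(1-p))`. For sure outcomes the
standardized skewness is undefined and is assigned 0. An unstandardized
third-central-moment variant is available via `standardized=False`; the
standardized form is the default because it is the convention under which
the sure-outcome rule is actually needed. Degenerate lotteries with
`x1 = x2` and interior `p` are normalized to `p = 1` at construction to
avoid 0/0 in the skewness.

Choice is stochastic via the Luce rule, `P(left) = 1/(1 + exp(V_R - V_L))`
— a softmax with temperature fixed at 1, so the scale of the values is
itself behaviorally meaningful.

### Value scale in the likelihood

The likelihood feeds the raw model utilities into the Luce rule. The
alternative — certainty equivalents, which put all models on the points
scale — is available via `use_ce=True` everywhere, but it is *not* the
default for fitting because on the CE scale the MVS weights enter choice
probabilities only through the ratios `β_σ/β_μ` and `β_γ/β_μ`
(`CE = U/β_μ`), leaving the three weights unidentifiable. With raw
utilities `β_μ` doubles as an inverse temperature and all parameters are
identifiable. Certainty equivalents are used where a common scale is what
matters: the neural parametric modulators, the cardinal value
correlations, and the RT/value-difference analysis.

## Estimation

Per participant and model, the log likelihood
`LL = Σ_t [I_L·ln P_L + (1-I_L)·ln P_R]` is maximized with Nelder–Mead.
Positivity-constrained parameters (`ρ, δ, γ, β_μ`) are optimized through
the transform `ψ = e^θ`; `β_σ, β_γ` are unconstrained. Ten random starts
(log-uniform over `ρ ∈ [0.2, 2]`, `δ ∈ [0.2, 3]`, `γ ∈ [0.2, 2]`,
`β_μ ∈ [0.05, 2]`; uniform over `β_σ ∈ [-0.1, 0.1]`, `β_γ ∈ [-2, 2]`,
which span negative values and so cannot be log-uniform) guard against
local optima; the best-LL start wins. Simplex tolerances: `fatol = 1e-8`,
5,000 iterations per start. Choice probabilities are clipped at 1e-12 so
the likelihood stays finite under complete separation (an agent who always
picks a dominant option). Missed trials are excluded from likelihoods and
accuracy denominators. Utilities with extreme curvature are evaluated in
log space and capped at e^500, which only matters where the logistic is
already fully saturated.

Model comparison per participant uses the small-sample-corrected AICc
`= -2LL + 2k + 2k(k+1)/(n-k-1)` with `k = 1` (EU) or `3` (PT, MVS).
A participant is classified as a model's "type" only when both rival AICc
values exceed the winner's by more than 2; otherwise unclassified.
Group-level comparison converts AICc to approximate log evidence
`L = -AICc/2` and runs random-effects BMS (below). Deterministic choice
predictions pick the side with `P > 0.5`; exact ties are broken by a
seeded coin flip and reported.

## Random-effects BMS

Given a subjects × models matrix of log evidences, the generating model is
treated as varying across subjects with frequencies `r ~ Dirichlet(α)`,
prior `α₀ = 1` per model. The variational fixed point iterates
responsibilities `g_nk ∝ exp(L_nk + ψ(α_k) - ψ(Σα))` (rows shifted by
their max first, making the result invariant to row-constant offsets) and
counts `α_k = α₀ + Σ_n g_nk`, to tolerance 1e-8 on α within 10,000
iterations. Expected frequencies are `r_k = α_k/Σα`; exceedance
probabilities `φ_k = P(r_k > r_j ∀ j)` are Monte Carlo estimates from
Dirichlet draws (default 1e6, seeded; each draw names exactly one winner
so Σφ = 1). For two models φ has the closed form `P(Beta(α₁,α₂) > ½)`,
which the tests use as an oracle. Protected exceedance probabilities and
family inference are out of scope.

## Neural pathway

**Design.** Per run: a constant; a boxcar from lottery onset to response
for valid trials with a state-value parametric modulator (CE_L + CE_R,
mean-centered within run — the SPM convention, decorrelating the modulator
from the onset regressor); a zero-duration decision event with a
value-difference modulator (|CE_L − CE_R|, mean-centered); null-trial
onsets; 5-s missed-trial boxcars with their own state-value modulator.
Regressors are built on a 16-bins-per-TR microtime grid, convolved with
the canonical double-gamma HRF (peak ≈ 6 s, undershoot ≈ 16 s, 1:6 ratio,
32-s support; peak-normalized; optional temporal and dispersion
derivatives), and downsampled at scan onsets. TR = 2.5 s, three runs.
Column groups without events are omitted.

**GLM.** Ordinary least squares with optional AR(1) prewhitening
(coefficient estimated from residual lag-1 autocorrelation within runs,
Cochrane–Orcutt transform restarted at run boundaries), contrast
t-statistics for any weight vector, and rank checking that names collinear
columns.

**Model evidence.** Instead of a spatial-prior variational scheme, the
package uses an exactly testable conjugate form: nuisance columns
(onsets, nulls, missed trials, derivatives, constants) carry a flat prior
and are projected out; the model-specific modulator columns carry a
Zellner g-prior with `g = n_scans` (unit information), and the noise
variance a Jeffreys prior. The resulting closed-form log marginal
likelihood is comparable across models because the data and the common
partition are identical; its additive constant cancels in all
comparisons. The closed form assumes white noise, so the series and all
columns are prewhitened with a single AR(1) coefficient estimated from
the *union* design's residuals — using one transform for all models keeps
the evidences comparable, and without it autocorrelated noise can
systematically favor whichever model's modulators absorb more
low-frequency variance. The modulators enter as one combined
model-specific partition (state value and value difference together); the
two-separate-models configuration can be had by passing single-column
modulator sets.

**ROI BMS and conjunction.** Per-voxel log evidences are averaged within
an ROI per subject and model before random-effects BMS. Group conjunction
masks intersect the three models' thresholded one-sample t-maps
(one-sided voxel p < 0.001, 6-connected clusters of at least a configurable
extent, default 165 voxels at full scale); cluster-level random-field
correction is deliberately replaced by this fixed-extent rule.

## Synthetic data

The generators emulate the structure of the study the pipeline targets:
27 participants; 180 binary-lottery trials over 3 runs with magnitudes in
{0, 5, 7, …, 50} and probabilities in {0, 0.05, …, 1}; 45 interspersed
5.5-s null trials; a 5-s response window; TR 2.5 s. The exact published
lottery pairs are not bundled; batteries are drawn randomly from the
printed stimulus sets under coverage constraints (positive and negative
skew, high and low variance, no identical pairs), and a user-supplied
pair table can be loaded instead.

Agent parameters are drawn from documented population distributions —
`ρ ~ LogN(ln 0.85, 0.25)`, `δ ~ LogN(ln 0.9, 0.3)`,
`γ ~ LogN(ln 0.7, 0.3)`, `β_μ ~ LogN(ln 0.5, 0.3)`,
`β_σ ~ N(-0.02, 0.01)`, `β_γ ~ N(0.3, 0.3)` — implementation choices
spanning empirically plausible ranges for recovery testing, not estimates
from data. Choices are Bernoulli draws from the Luce probability on the
same value scale the likelihood uses. RTs are
`rt = 2.5 s − 0.04 s/point · |ΔCE| + N(0, 0.4 s)`, truncated to
(0.2, 5] s — the simplest mechanism consistent with a negative
RT/value-difference correlation; it is not a process (drift-diffusion)
model. Trial onsets follow a jittered schedule (ITI uniform 1–3 s after
the 5-s window) since the original jitter schedule is not public.

ROI BOLD is `100 + Σ effect·z(modulator) + AR(1) noise` per voxel, where
`z(·)` standardizes the HRF-convolved mean-centered modulator columns of a
designated true model. Effects default to 0.8% signal change per modulator
SD with AR(1) noise of marginal SD 1% and lag-1 coefficient 0.3 —
ROI-scale values at which recovery is reliable without being trivial.
Mixed-gamble agents accept with probability
`logistic(0.2·(0.5·gain − 0.5·λ·loss))`, λ log-uniform on [1, 4], on a
16×16 grid of gains {10, 12, …, 40} × losses {5, …, 20}.

What the generators do *not* emulate: scanner drift and motion,
physiological noise, spatial correlation between voxels, learning or
fatigue across trials, and RT dynamics beyond the linear rule. Passing
recovery tests therefore shows the estimators and the selection machinery
are correct and well-calibrated under the stated generative assumptions —
not that real data meet those assumptions.

## Desk-scale choices

- **ROI size 64 voxels** for the neural recovery experiments. Real ROIs in
  this design are clusters of ≥165 voxels; ROI averaging of per-voxel log
  evidences is what washes out noise-driven evidence differences between
  models. With very small ROIs (a few voxels), ±1–2-nat noise differences
  per subject survive averaging and random-effects BMS amplifies them, so
  a no-signal control would not return uniform frequencies. 64 voxels
  preserves the mechanism at a fraction of the cost.
- **Conjunction tests** run on 12³ grids with a cluster extent of 20
  voxels (scaled down from 165 with the grid).
- Recovery experiments use 27 agents × 180 trials (behavioral), 30 × 256
  (mixed gambles), matching the study sizes.

## Known limitations

- The behavioral likelihood's value scale (raw utility vs. CE) changes the
  interpretation of the fitted parameters; both are supported but results
  are reported for the identifiable raw-utility default.
- The conjugate evidence is a deliberate replacement for spatial-prior
  first-level Bayesian estimation, not a reconstruction of it.
- Exceedance probabilities only rank the models in the comparison set;
  they cannot certify that the true generator is among them.
- The AICc→log-evidence conversion (−AICc/2) is the standard
  approximation and inherits AICc's small-sample behavior.
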