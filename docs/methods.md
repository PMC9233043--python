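# Methods

## Setting and model

Data are i.i.d. records `(x_i, d_i, E_i, T_i)` for `i = 1..N`: a
Q-dimensional covariate vector, a continuous dose standardized to
`[−1, 1]`, and binary efficacy and toxicity outcomes.  Both marginal
probabilities `pE(d, x)` and `pT(d, x)` are assumed nondecreasing in dose.
The decision object is the joint distribution
`p(d, x) = (p00, p10, p01, p11)` over the four (E, T) cells.

A clinician-elicited 2×2 utility matrix assigns 1 to (E=1, T=0), 0 to
(E=0, T=1), and free values ω₁ = u(0,0), ω₂ = u(1,1), both in (0, 1).  Its
expectation

    Ū(p, ω) = ω₁ p00 + p10 + ω₂ p11
            = ω₁ + (1−ω₁) pE − ω₁ pT + (ω₁+ω₂−1) p11

defines the utility of dose `d` for a patient.  The legacy one-parameter
trade-off `pE − θ pT` is the matrix `(0, 1, −θ, 1−θ)` and is available via
an alternate constructor.  When ω₁+ω₂ = 1 the `p11` term cancels, so only
when ω₁+ω₂ ≠ 1 does the E–T dependence matter.

Two modified utilities address clinical concerns:

- **toxicity cap**: subtract `m·ω₁·pT` when `pT ≥ c` (defaults m = 2,
  c = 0.3, i.e. a tripling of the toxicity weight above the cap;
  the indicator is inclusive at the threshold);
- **dose penalty**: subtract `δ (d − d_fix)²` (default δ = 0.1), shrinking
  recommendations toward a population fixed dose.

Three selection rules are implemented over a dose grid:

1. **pointwise**: argmax of the plug-in utility curve;
2. **posterior mean**: argmax of the across-draw average utility, for
   models producing posterior draws of `p(d, x)`;
3. **posterior probability**: argmax over `d` of
   `P(Ū(p(d,x)) > Ū(p(d_fix,x)) | data)`.  The inequality is strict, so
   the probability at `d_fix` itself is 0; this rule refuses small
   expected gains that come with large uncertainty.

Numerical conventions (the underlying sources are silent on all of
these): the default grid is 201 equally spaced doses on `[−1, 1]`
(resolution 0.01, configurable); argmax ties are broken toward the lowest
dose, the clinically conservative choice; `d_fix` off the grid is snapped
to the nearest grid point; utilities are kept on [0, 1] internally and
reported ×100.

## Joint distribution via Gaussian copula

Marginals are linked by a Gaussian copula with correlation α:

    p00 = Φ₂( Φ⁻¹(1−pE), Φ⁻¹(1−pT) | α ),

and the remaining cells follow by complement algebra, which reproduces the
marginals exactly and keeps `p11` inside its Fréchet interval
`[max(0, pE+pT−1), min(pE, pT)]`.  Φ₂ is evaluated through Owen's T
function (vectorized, ~1e−14 accurate; checked in tests against an
independent numerical CDF).  |α| is capped at 0.99 for numerical
stability, and marginals are clipped to `[1e−10, 1−1e−10]` before the
probit transform.

α is estimated by **two-stage pseudo-likelihood**: marginal models are
fitted first, each subject's fitted `(p̂E, p̂T)` is plugged into the
copula cell probability selected by the observed `(E, T)`, and the summed
log-likelihood is maximized over α ∈ [−0.99, 0.99] (41-point grid bracket
plus bounded 1-D refinement).  When the training set itself is scored the
out-of-bag probabilities are used, which avoids optimism but — because the
plug-in marginals are noisy — attenuates α̂ toward 0 in small samples.
This attenuation has little practical effect: correlation barely moves
the selected doses.

## Outcome models

**Marginal random forests** (`ForestJointModel`).  Separate probability
forests for E and T on `(x, d)`; predictions are the ensemble class-1
fractions, clipped to `[1e−6, 1−1e−6]` so copula transforms stay finite.
The optional monotone variant constrains the dose feature to a
nondecreasing effect inside the tree learner (a per-feature monotonic
split constraint; the contract is nondecreasing predicted curves, and the
tests assert zero violations over dose grids).  Defaults: 500 trees,
`sqrt` feature subsampling, seed required for reproducibility.  A constant
training outcome degenerates to the constant rate with a warning.

**Categorical random forest** (`CategoricalForestModel`).  One forest on
the 4-level outcome `E + 2T`.  Monotonicity cannot be imposed on the four
cells directly, so it is restored post hoc: the implied marginal curves
are projected onto nondecreasing sequences by PAVA (per patient along the
dose grid, unit weights), then `p11` is re-chosen inside the Fréchet
interval of the projected marginals.  Variant `p11_only` clips the
predicted `p11` (minimizing |p11* − p̂11|); variant `total_deviation`
minimizes the 4-term L1 deviation, which is piecewise linear in `p11*`
once the other cells are expressed through `(p11*, pE*, pT*)` — the exact
minimizer is found by evaluating the interval endpoints and the four kink
points, ties toward the smallest `p11*` (the more conservative joint
response).  Remaining cells follow sequentially; cells are floored at 0
only against floating error (tolerance −1e−12).

**Gaussian-process probit models** (`GPJointModel`).  Latent functions
`fE ~ GP(0, K_E)`, `fT ~ GP(0, K_T)` on standardized inputs `z = (x, d)`
with probit links `Pr(E=0) = Φ(fE + a)`, `Pr(T=0) = Φ(fT + b)` and a
multinomial likelihood over the four cells (independence by default; a
copula variant sampling α = tanh(γ) is available — the two give very
similar dose selections, so independence is the default).  The kernel is
Gaussian ARD:

    k(z, z′) = η² exp(−½ Σ_q ρ_q² (z_q − z′_q)²).

ρ_q multiplies the squared distance, i.e. acts as an inverse
length-scale: ρ_q → 0 removes input q from the covariance.  Priors:
ρ_q ~ N(0, λ_q² τ²) with λ_q, τ ~ half-Cauchy(0, 1) (horseshoe: the global
scale shrinks all weights, the heavy-tailed local scales let relevant
inputs escape), a, b ~ N(0, 1), η ~ half-normal(0, 1) (the positive-scale
reading of a standard-normal prior).  Each outcome has its own horseshoe.

Inference is blocked MCMC, built in-package: latents are whitened
(`f = L u`, `K = L Lᵀ + 1e−6 I`, `u ~ N(0, I)`) and updated by elliptical
slice sampling; η, ρ, λ, τ, a, b, γ get per-coordinate random-walk
Metropolis on unconstrained scales (log for positives, with Jacobians),
with Robbins–Monro step adaptation toward 0.44 acceptance during warmup
only.  λ and τ updates touch only the prior, so they need no kernel
rebuild; η and ρ updates re-factor the kernel.  Defaults are 2 chains of
500 warmup + 500 kept draws (test-scale; use 4×1000+1000 for studies);
R-hat and effective sample sizes of the scalar hyperparameters are
computed with arviz and a warning is raised above R-hat 1.2.  Dense kernel
algebra limits n to ≤ 500.

Posterior predictive curves draw the latent at `(x_new, grid)` from the
full Gaussian conditional given each draw's training latents and
hyperparameters (a draw, not just the conditional mean, so that posterior
uncertainty reaches the posterior-probability rule); Cholesky jitter
escalates from 1e−6 to 1e−4 before failing.  The batch variant reuses the
per-draw training factorization across patients.

**Fixed-dose baseline** (`FixedDoseModel`).  A 4-category multinomial
logistic regression on dose alone, fitted with a very weak L2 penalty
(C = 1e6, effectively the MLE while immune to quasi-separation); `d_fix`
is the grid dose maximizing the expected utility of its fitted cells.

## Synthetic data and the simulation study

The generator emulates a dose-individualization cohort: probit marginals
that are linear in `(x, d, d·x)`, a Gaussian copula (α = 0.8) linking the
outcomes, dose Uniform(−1, 1), and rejection of any covariate vector whose
dose derivative of either linear index is non-positive — so every retained
patient truly has nondecreasing dose-efficacy and dose-toxicity curves.
The reference scenario (S1) uses 5 i.i.d. N(0, 1) covariates and the fixed
coefficient vectors hard-coded in `simulate.py`; its rejection step
discards ≈ 44% of proposals and yields efficacy rates near 50% and
toxicity rates near 27%.  Scenario variants (S0 dose-only, S2 no
interactions, S3 correlated covariates at 0.6, S4/S5 with 15/195 noise
covariates, S6 n = 400, S7 binary covariates, S8 covariate–covariate
interactions, S9 exp(x₄), S10 I(x₄ > 0)) are supported as configurable
deviations; only S0 and S1 have fully pinned-down coefficients, the others
keep the S1 coefficients and change the stated ingredient (the S8
interaction term defaults to `0.5·x₁x₂` for efficacy and `0.3·x₁x₂` for
toxicity — package defaults, not externally fixed).  Binary covariates are
Bernoulli(1/2) on {0, 1}.

What the generator does **not** emulate: measurement error or missingness
in covariates, informative dose assignment (dose is independent of `x`),
non-monotone or plateauing dose-response, model misspecification of the
probit-linear form, and censoring or competing risks in outcome
ascertainment.  Passing tests therefore demonstrate correct recovery of
this data-generating process, not robustness on messy real cohorts.

The study loop replicates five steps: generate a training set (default
n = 200), fit the configured methods, generate a validation set of the
same size (the common convention when the validation size is otherwise
unspecified), recommend one dose per validation patient, and score under
the truth.  Metrics per method × utility: mean dose, SD of dose within
each validation set averaged over replicates, mean true pE and pT at the
recommended doses, mean true expected utility ×100 (the scoreboard always
uses the plain expected utility, also for methods that *select* with a
modified utility), and the percent improvement
`100·(Ū_method − Ū_fixed)/(Ū_oracle − Ū_fixed)` computed on
replicate-averaged utilities — 100 for the oracle and 0 for fixed dosing
by construction.  Mean utility is the true expected utility at the
recommended dose (not a realized-outcome average), matching the scoring of
step five.  Replication seeds are spawned from a single root seed so runs
are reproducible and replicates independent.

## Problem sizes and numerical choices

The bundled reference computation (`scripts/acceptance.py`) uses 200
replicates of 200 validation patients per utility for the oracle rule and
200 train/validate replicate pairs for the fixed-dose baseline — sizes at
which the Monte Carlo standard error of the mean utility is ≈ 0.17 on the
×100 scale, comfortably inside the comparisons made of it, while the whole
script runs in well under a minute.  Test-scale GP fits use 1–2 chains of
150–250 warmup/kept draws at n ≤ 200, enough for the calibration and
recovery properties asserted; study-scale GP work should raise these.
Joint-probability validation uses a 1e−9 tolerance on cell sums and
marginal reconstruction; copula cell probabilities are floored at 1e−12
inside log-likelihoods.

## Known limitations

- The GP sampler is a random-walk/slice hybrid, not a gradient-based
  sampler; mixing for the horseshoe scales is adequate at test scale but
  slow for large Q — expect to raise chain lengths well beyond the
  defaults for high-dimensional studies.
- GP monotonicity in dose is not enforced (virtual derivative points are
  out of scope); only the forest models offer hard monotone constraints.
- The two-stage copula α̂ is attenuated when plug-in marginals are noisy;
  it should be read as a working dependence parameter, not an unbiased
  estimate of the outcome correlation.
- Per-patient PAVA does not enforce coherence across patients or
  covariates.
- `Rborist`-style split-level monotone forests and the exact tree
  hyperparameters behind the reference study are unknown; equivalence is
  at the contract level (nondecreasing curves), so forest-dependent rows
  of study tables reproduce only qualitatively.
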