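# optidose

Utility-based individualized optimal dose selection for a binary efficacy
outcome E and a binary toxicity outcome T.

Given an existing dataset of treated patients — covariates `x`, a
continuous (standardized) dose `d ∈ [−1, 1]`, and observed outcomes
`(E, T)` — the package estimates the joint outcome distribution
`p(d, x) = (p00, p10, p01, p11)` as a function of dose and covariates, and
recommends for each new patient the dose maximizing the expectation of an
elicited 2×2 utility matrix

|        | E = 0 | E = 1 |
|--------|-------|-------|
| T = 0  | ω₁    | 1     |
| T = 1  | 0     | ω₂    |

so that

```
Ū(p(d,x), ω) = ω₁ p00 + p10 + ω₂ p11
             = ω₁ + (1−ω₁) pE − ω₁ pT + (ω₁+ω₂−1) p11 ,
d_opt(x) = argmax_d Ū(p(d,x), ω).
```

When ω₁+ω₂ = 1 the `p11` term cancels and only the marginals matter;
otherwise the E–T correlation enters through `p11`, which the package
models with a Gaussian copula.  Intended users are biostatisticians
designing or analyzing dose-individualization studies (for example
radiation-oncology dose selection) and methodologists benchmarking
dose-finding rules in simulation.

## What is in the box

- **Models of `p(d, x)`** (scikit-learn-style estimators):
  - `ForestJointModel` — random forests for the E and T marginals,
    optionally constrained to be nondecreasing in dose, linked by a
    Gaussian copula (correlation estimated by pseudo-likelihood from
    out-of-bag probabilities) or by conditional independence;
  - `CategoricalForestModel` — one forest on the 4-level outcome
    (E,T), with optional post-hoc PAVA monotonization of the implied
    marginal curves under Fréchet constraints on `p11`;
  - `GPJointModel` — Bayesian Gaussian-process probit models with a
    Gaussian ARD kernel and horseshoe priors on the relevance weights,
    sampled by MCMC, giving full posterior uncertainty;
  - `FixedDoseModel` — the dose-only 4-category multinomial baseline that
    anchors the fixed dose `d_fix`.
- **Three utility functions**: the plain expected utility; a
  toxicity-capped variant subtracting `2ω₁ pT` whenever `pT ≥ 0.3`; and a
  dose-penalized variant subtracting `δ (d − d_fix)²`.
- **Three selection rules**: pointwise argmax of a plug-in utility curve;
  argmax of the posterior mean utility; and argmax of the posterior
  probability that a dose's utility beats the utility at `d_fix`.
- **A simulation engine** (`scenario_spec`, `generate_dataset`,
  `run_study`) reproducing the probit/copula generative scenarios with
  monotonicity rejection constraints, plus oracle and fixed-dose reference
  rules and the population metrics (mean dose, SD dose, mean E, mean T,
  mean utility ×100, percent improvement).
- **A CLI**: `optidose simulate | fit | recommend | study`.

## Worked example

```python
import numpy as np
from optidose import (ForestJointModel, UtilityConfig, UtilityMatrix,
                      default_grid, generate_dataset, scenario_spec,
                      select_dose_pointwise)
from optidose.simulate import split_table

spec = scenario_spec("S1")                     # reference generative model
table, rej = generate_dataset(spec, 400, np.random.default_rng(7))
design, y, cov = split_table(table)

model = ForestJointModel(joint="copula", monotone=True, random_state=0)
model.fit(design, y)
print(f"rejection rate {rej:.3f}  copula alpha {model.alpha_:.3f}")

grid = default_grid(201)                       # 201 doses on [-1, 1]
cfg = UtilityConfig(matrix=UtilityMatrix.from_omegas(0.3, 0.5))
curves = model.predict_joint_curves(cov[:3], grid)
doses, profiles = select_dose_pointwise(curves, grid, cfg)
for i, d in enumerate(doses):
    print(f"patient {i+1}: d_opt = {d:+.2f}, utility {100*profiles[i].max():.1f}")
```

Output:

```
rejection rate 0.461  copula alpha 0.171
patient 1: d_opt = -0.11, utility 55.6
patient 2: d_opt = -0.08, utility 44.1
patient 3: d_opt = -0.14, utility 36.5
```

About 46% of proposed covariate vectors were rejected by the monotonicity
constraints.  The printed utilities are estimated expected utilities
(×100) at each patient's selected dose.  The fitted copula correlation
(0.17) is attenuated relative to the generative value 0.8 because it is
estimated through noisy out-of-bag marginal probabilities rather than the
true marginals — with the true marginals plugged in, the pseudo-likelihood
recovers α ≈ 0.8 (this is exercised in the test suite); modeling the
correlation has little effect on which dose is selected.

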