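# Methods

This document describes the statistical machinery implemented in `ownbias`:
the decision model and its likelihood, the hierarchical Bayesian estimation
scheme, the psychometric pipeline, the synthetic-data generator, and the
evaluation tooling. Default settings that are the package's own choices (as
opposed to standard conventions) are flagged as such, with rationale.

## 1. Task and data model

The task is a two-alternative morph classification: on each trial a stimulus
drawn from an 8-level morph continuum (0, 20, 35, 45, 55, 65, 80, 100 percent
"self" object) is classified as *self* or *friend*. A trial record carries
`participant`, `condition` (a between-subject factor), `morph_pct_self`,
`response` and `rt_s`. Responses are **response coded**: the upper diffusion
boundary is always the self response, the lower boundary the friend response.

## 2. Drift-diffusion model

Evidence `x(t)` accumulates as a Wiener process with drift `v`, diffusion
coefficient fixed at 1 (the scaling convention), between absorbing boundaries
at 0 and `a`, starting at `z·a` with relative starting point `z ∈ (0, 1)`.
Observed RT is the first-passage time plus a nondecision constant `t0`.

### 2.1 First-passage density

The density of hitting the **lower** boundary at decision time `t` is the
classic infinite-series expression, evaluated per Navarro & Fuss (2009) with
both the small-time and large-time expansions and an adaptive switch: for each
normalized time `tt = t/a²` the expansion needing fewer terms for a truncation
error below `1e-7` is used, with the number of terms chosen by the
corresponding error bounds. Upper-boundary densities use the exact reflection
`f_upper(t | v, z) = f_lower(t | −v, 1−z)`.

The absorption (choice) probability has the closed form
`P(lower) = (e^{−2vaz} − 1)/(e^{−2va} − 1)` (limit `1 − z` as `v → 0`),
implemented with `expm1` for numerical stability.

### 2.2 Contaminant mixture

Following standard practice for hierarchical DDM fitting, every likelihood is
a two-component mixture: with probability `1 − p_out` the trial comes from the
diffusion process, with probability `p_out = 0.05` from a uniform outlier
distribution on `(0, t_max]` with both responses equally likely, i.e. density
`p_out / (2 t_max)`. `t_max` is set to the 99th percentile of the observed RTs
in the dataset being fitted. The mixture keeps single fast or slow outliers
from dominating subject-level estimates.

### 2.3 Simulation

`simulate_trials` samples choices from the closed-form absorption probability
and decision times by inverse-CDF sampling: the conditional first-passage CDFs
for both boundaries are tabulated by trapezoidal integration of the series
density on a square-root-spaced grid (2048 points, extended until at least
`1 − 1e−5` of the mass is covered), then inverted by linear interpolation.
Contaminant trials are drawn uniformly as in the mixture. The test-suite
cross-checks this sampler against an independent Euler–Maruyama simulator
(dt = 1e−4) with the Broadie–Glasserman–Kou boundary correction.

## 3. Model variants

Three nested hierarchical variants are compared:

| Variant | drift v | starting point z | boundary a |
|---|---|---|---|
| M1 | condition × morph | fixed at 0.5 | one per population |
| M2 | condition × morph | free, per condition | one per population |
| M3 | condition × morph | free, per condition | free, per condition |

`t0` is always one per subject with a single population hierarchy. When the
data hold a single condition, per-condition cells collapse (M3 ≡ M2).

## 4. Hierarchical estimation

### 4.1 Parameterization and priors

Subject parameters live on unconstrained scales: `v` natural, `log a`,
`logit z`, `log t0`, each with a normal population hierarchy, e.g.
`logit z_s ~ N(μ_z, σ_z²)`; drift has one `(μ, σ)` pair per condition × morph
cell (shared σ).

Group means have vague conjugate normal priors (variance 25 for drift means
and regression coefficients, 1 for the log/logit-scale means, centered at
`log 1.5`, 0, and `log 0.3` for `a`, `z`, `t0`); group variances have
inverse-gamma(2, ·) priors (scale 0.5 for drift, 0.05 on the transformed
scales). **These priors are the package's own plumbing** — chosen to be weakly
informative on the transformed scales and to admit exact conjugate Gibbs
updates — and are deliberately vague relative to the likelihood at the trial
counts used here. The lognormal/logit-normal hierarchies replace truncated
normals for the same reason.

### 4.2 Sampler

A Metropolis-within-Gibbs scheme (compiled with numba):

* group means and variances: exact conjugate updates (normal / inverse-gamma);
* subject-level parameters: random-walk Metropolis, one coordinate at a time,
  with per-parameter step sizes adapted during burn-in toward a 0.44
  acceptance rate (adaptation every 25 iterations, frozen afterwards, so the
  post-burn chain is a valid Markov chain);
* per-cell log-likelihood caching so only the touched cells are re-evaluated.

Defaults: 1 chain, 2,000 samples / 500 burn in fast mode, 10,000 / 1,000 in
full mode; chain `k` uses `seed + 1000k`. Convergence is monitored with
split-R̂ (via ArviZ) on every group parameter; values above 1.05 trigger a
warning, never silent failure.

### 4.3 Model comparison

DIC with the classic effective-parameter count:
`p_D = D̄ − D(θ̄)` where `D̄` is the posterior mean deviance and `D(θ̄)` the
deviance at the posterior mean of the subject-level parameters taken on their
unconstrained scales; `DIC = D(θ̄) + 2 p_D`. Lower is better.

### 4.4 Directional evidence

For a directional hypothesis `θ_A > θ_B`, `p_Bayes` is the fraction of
posterior draws violating the inequality, and the directional Bayes factor is
`BF₁₀ = (1 − p_Bayes)/p_Bayes`, printed rounded to the nearest integer
(`>999` beyond that).

### 4.5 Starting point ~ PSE regression

The individual-differences linkage replaces the z hierarchy with
`logit z_s ~ N(b0 + b1·PSE_std_s, σ²)` where `PSE_std` is the standardized
per-participant PSE; `(b0, b1)` get a conjugate bivariate normal update. A
negative `b1` means PSE reductions go with starting-point increases.

## 5. Psychometric pipeline

1. **Fast-response filter:** trials with RT < 200 ms are removed.
2. **Curve fitting:** per participant (and condition), a cumulative logistic
   `P(self) = 1/(1 + exp(−β(m − α)))` is fitted by maximum likelihood
   (L-BFGS-B, multi-start over location/slope grids plus a negative-slope
   start; slopes at the box bound raise a separation warning). `α` is the
   point of subjective equality (PSE).
3. **Random-responder exclusion:** a participant is excluded if a
   likelihood-ratio test of their logistic against a constant-probability
   model is non-significant at α = 0.01, **or** their accuracy on the
   unambiguous anchors (morph 0/100) is below 60%. The criterion is calibrated
   so a 560-trial coin flipper is caught in ≥ 95% of replicates.
4. **Group tests:** one-sample t vs the 50% midpoint per condition and
   two-sample t between conditions, with Cohen's d and 95% CIs.

## 6. Synthetic-data generator

`generate_experiment` emulates two experiments — judgment type (ownership vs
identity) and exposure duration (short vs long), both between-subject — with
7 blocks × 80 trials per participant (10 per morph level per block, shuffled
within block), counterbalanced object assignment and key mapping.

Each subject draws `(a, t0, z, v_max)` from truncated normals around group
means; the drift at morph `m` is the antisymmetric linear map
`v = v_max (2m/100 − 1)` (zero at maximal ambiguity). Group means: z = 0.52 vs
0.50 (ownership/identity) and 0.53 vs 0.52 (short/long); `v_max` = 1.74/1.90
and 2.10/1.98, chosen so the folded per-condition mean drift over the grid
(which equals `0.5·v_max` under the linear map) lands at 0.87/0.95 and
1.05/0.99. Boundary 1.6 and nondecision time 0.35 s are realistic conventions
for speeded binary classification (package choice). Between-subject SDs
default to 10% of each mean. Contaminants — fast guesses (~1%, RT
U(0.05, 0.2) s) and slow uniform outliers (2%, RT U(0.2, 5) s; package
choice) — are injected with coin-flip responses to exercise the exclusion and
mixture machinery.

`logistic_cohort` generates Bernoulli choice data directly from per-participant
logistic curves (slope 0.15 per percentage point, 70 trials per level) for
estimator-recovery studies where the diffusion layer is irrelevant.

## 7. Recovery harnesses (desk scale)

`ownbias.harness` packages the validation studies run by the test-suite and
`scripts/acceptance.py`. Sizes are deliberately scaled down to minutes on one
CPU; all scale choices were fixed before the studies were run:

* **Unbiased null:** 20 subjects × 560 trials at z = 0.5 with contaminants;
  the group PSE must be statistically indistinguishable from 50%.
* **Starting-point recovery:** 12 subjects at z = 0.52, M2 fast fit; the
  between-subject z SD is set to 0.03 (below the generator's 10% default) so
  the cohort mean is a stable estimand at n = 12 and the ±0.02 pass mark tests
  estimation error rather than cohort sampling error.
* **PSE recovery:** cohorts drawn at the reported condition means/SDs/ns
  (45/12/35 and 52/12/39; 43/6/36 and 47/7/32), 20 replicate seeds, recovering
  the means and the between-condition differences (≈ 7 and ≈ 4 points).
* **Model recovery:** 2-condition cohorts generated from M2 with z = 0.56 vs
  0.50 (bias doubled relative to full scale to offset the reduced trial counts
  of the 4-per-cell, 2-block desk cohorts), fit by all three variants; DIC
  should prefer M2 over M1 with M3 tying at best.
* **Regression:** 16 subjects with dispersed z (SD 0.05); because a larger
  starting point mechanically shifts the PSE leftward in the generator, the
  z ~ PSE slope must carry > 0.95 posterior mass below zero.

## 8. Evaluation

* **Posterior predictive checks:** complete datasets are simulated from
  randomly chosen post-burn joint draws (one draw per dataset, so bands carry
  parameter uncertainty), refitted with the psychometric pipeline, and
  compared with the empirical group PSE and per-morph choice rates against
  the simulated 95% bands.
* **Drift-based psychometric functions:** posterior mean and 95% interval of
  each condition × morph drift cell, with an adjacent-inversion count as a
  monotonicity diagnostic.

## 9. Limitations

* Single-chain defaults favor runtime; R̂ is computed on split halves and
  multi-chain runs are one keyword away, but production inference should use
  several chains.
* DIC is reported because it is the conventional criterion for this model
  class; it is known to under-penalize hierarchical complexity relative to
  WAIC/LOO, which are not implemented.
* The generator's boundary separation, nondecision time, between-subject SDs
  and outlier rate are package conventions, not fitted quantities; recovery
  studies therefore test self-consistency of the pipeline, not external
  ground truth.
* The desk-scale harness sizes trade statistical tightness for runtime; the
  quoted tolerances (±0.02 on z, ±2 points on PSE means) were chosen to be
  attainable at those sizes without being trivially loose.
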