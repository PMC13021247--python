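# ownbias

Psychophysical and hierarchical drift-diffusion decomposition of
ownership-based self-prioritization in perceptual decisions.

## The scientific problem

When people classify ambiguous morphs between a self-associated and a
friend-associated object, ownership shifts the psychometric function: the
point of subjective equality (PSE) moves below the objective 50% midpoint, so
ambiguous stimuli are more readily called "self". Two process-level accounts
could explain this: faster evidence uptake for self-related stimuli (a drift
effect) or a pre-stimulus bias toward the self response (a starting-point
effect). This package implements the full analysis that separates the two:

1. **Psychometrics** — per-participant cumulative-logistic fits, PSE
   extraction, exclusion rules, group tests;
2. **Hierarchical drift-diffusion modeling** — three nested variants fit by
   MCMC and compared by DIC, asking whether the self-bias lives in the
   starting point (M2/M3) or not at all (M1);
3. **Linkage** — a hierarchical regression of each participant's starting
   point on their PSE, testing whether the behavioral and process-level biases
   are the same thing;
4. **Validation** — a synthetic-experiment generator, posterior predictive
   checks, and parameter/model-recovery harnesses.

There is no bundled empirical dataset: everything runs on simulated data whose
generative truths are the published condition-level summaries, so the package
validates the *pipeline* (does it recover what generated the data?) rather
than re-deriving numbers from raw data.

## Package layout

| Where | What |
|---|---|
| `src/ownbias/ddm.py` | Wiener first-passage density (adaptive truncated series), choice probabilities, inverse-CDF trial simulator, contaminant-mixture likelihood |
| `src/ownbias/models.py` | model variants M1/M2/M3 and the trial → parameter-cell design map |
| `src/ownbias/inference.py` | Metropolis-within-Gibbs hierarchical sampler, DIC, directional Bayes factors, z ~ PSE regression |
| `src/ownbias/psychometrics.py` | RT filter, logistic fits, PSE, exclusion rules, group tests |
| `src/ownbias/synth.py` | synthetic experiment generator and logistic cohorts |
| `src/ownbias/evaluation.py` | posterior predictive checks, drift-based psychometric curves |
| `src/ownbias/harness.py` | scaled-down recovery studies used by the tests and acceptance script |
| `src/ownbias/cli.py`, `io.py` | `ownbias` command-line pipeline and table I/O |
| `analysis/01…06_*.py` | numbered end-to-end analysis drivers |
| `scripts/acceptance.py` | writes the headline validation targets as JSON |

## Worked example

Run the numbered drivers in order (defaults: 12 participants per condition
cell, fast MCMC = 2,000 draws / 500 burn; a few minutes total on one CPU):

```bash
python analysis/01_simulate.py          # synthetic Experiments 1 and 2
python analysis/02_psychometrics.py     # filter, fit curves, group PSE tests
python analysis/03_fit_models.py        # fit M1/M2/M3, DIC comparison
python analysis/04_ppc_and_drift.py     # posterior predictive checks
python analysis/05_regression.py        # starting point ~ PSE linkage
python analysis/06_model_recovery.py    # DIC model-recovery study
```

Representative output from a complete run at the defaults (`results/` holds
the tables):

```
experiment 1 M1: DIC=20891 p_D=172.6
experiment 1 M2: DIC=20598 p_D=178.8
experiment 1 M3: DIC=20595 p_D=174.9
experiment 1: PPC misfit=False; drift inversions=0
experiment 1: slope mean=-0.193 P(slope<0)=1.000 BF10=>999
...
M2 preferred outright in 2/5 replicates; M2 < M1 in 5/5
```

The signature pattern: the no-bias model M1 loses clearly; freeing the
starting point (M2) absorbs the self-bias; the extra boundary freedom of M3
buys nothing beyond Monte-Carlo noise; and the z ~ PSE regression slope is
negative with essentially all posterior mass — participants whose PSE sits
further below 50% carry larger starting-point biases.

The same pipeline is available as a console script
(`ownbias simulate|psychometrics|fit|compare|ppc|regress|report`), e.g.

```bash
ownbias report --experiment 1 --n-per-cell 12 --fast --seed 7 --out-dir results
```

### Library example

```python
from ownbias import DDMParams, simulate_trials
from ownbias.models import ModelSpec, build_design
from ownbias.inference import sample_posterior, directional_prob, bayes_factor
from ownbias.synth import generate_experiment, recovery_config

trials, truth = generate_experiment(recovery_config(n_subjects=12, z=0.52, seed=7))
design = build_design(trials, ModelSpec.from_variant("M2"))
post = sample_posterior(design, n_samples=2000, n_burn=500, seed=8)
print(post.get("z").mean())                     # ≈ 0.52
p = directional_prob(post, "z", 0.5)            # P(z <= 0.5)
print(bayes_factor(p))                          # directional BF10
```

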