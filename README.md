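# phylospan

Bayesian estimation of species life expectancy from individual census
records, and phylogenetic structural-equation models (SEM) linking life
expectancy to relative brain size and life-history covariates. The package
targets comparative analyses of longevity in long-lived vertebrates —
the motivating system is captive parrot populations, where zoo census
records give observation windows for hundreds of species — and ships a
synthetic-data generator that produces trees, traits and census records
under the exact generative assumptions of the models, with known ground
truth for recovery testing.

## The models

**Survival stage.** Each species' age-specific mortality follows the
five-parameter Siler bathtub hazard

```
mu(x) = exp(a0 - a1 x) + c + exp(b0 + b1 x),     a1, c, b1 > 0
```

combining declining juvenile mortality, constant adult mortality and
exponentially rising senescent mortality. Cumulative survival has the
closed form `S(x) = exp(-∫ mu)` and life expectancy at birth is
`e0 = ∫ S(x) dx`. Census records are left-truncated at the age of entry
and right-censored at last sighting; unknown birth dates are treated as
latent parameters with a survival-weighted prior and sampled by
Metropolis–Hastings alongside the mortality parameters. Convergence is
judged with the split-chain Gelman–Rubin statistic, with one automatic
rerun at doubled length, and a posterior-predictive Kolmogorov–Smirnov
gate flags species whose records the model cannot fit.

**Comparative stage.** Species-level (standardized log) life expectancy is
modelled as

```
LE ~ I + BO + RB + LA + D          (model 1)
LE ~ ... + DT + CS                 (model 2)
LE ~ ... + AFR                     (model 3, AFR complete-case)
```

where I is insularity, BO body mass, RB relative brain size, LA maximum
latitudinal range, D an ordinal protein-content diet class, DT
developmental time, CS clutch size and AFR age at first reproduction.
Relative brain size is the latent residual `BR - pBR` of an allometric
submodel `pBR ~ BO` fitted *simultaneously* with the outcome model, so
measurement error flows in both directions. All three error-carrying
variables (LE, BO, BR) carry per-species standard errors; between-species
covariance follows the L2-norm phylogenetic kernel
`K_ij = eta^2 exp(-rho d_ij^2)` on patristic distances; missing values are
imputed from their conditional multinormal given the observed data, the
kernel and the structural means. The direct-vs-indirect brain-size
question is answered by comparing the RB coefficient across the three
models.

## Worked example

```python
from phylospan import (SamplerConfig, SilerParams, fit_siler,
                       life_expectancy, simulate_census)

params = SilerParams(a0=-1.0, a1=1.0, c=0.02, b0=-6.0, b1=0.15)
e0 = life_expectancy(params)            # 13.213 years
records = simulate_census(params, 1000, study_window=5 * e0,
                          unknown_birth_fraction=0.2, seed=104)
post = fit_siler(records, SamplerConfig(n_chains=4, n_iter=10_000), seed=4)
print(round(post.e0_mean, 2), round(post.e0_se, 2), post.converged)
```

prints `13.64 0.43 True`: from 1000 individuals (about a fifth censored,
a fifth with unknown birth dates) the sampler recovers the generating life
expectancy of 13.21 years within one posterior standard error, and all
split-chain Rhat values are below 1.05.

The full pipeline — simulate, per-species survival fits, trait assembly,
SEM, report — runs from the shell:

```
phylospan run-all --outdir myrun --seed 1 --models 1
```

which writes `siler_summary.csv` (per-species e0 with uncertainty and
diagnostic flags), `sem_model1_coefficients.csv` (posterior mean, sd, 89%
interval and overlap-with-zero per predictor), imputation summaries,
per-stage JSON manifests recording seeds and a config hash, and a
markdown report.

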