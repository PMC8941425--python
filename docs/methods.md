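# Methods

This note documents the models, the estimation machinery, the synthetic-data
generator and the numerical choices made where the design was genuinely
open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Survival stage

### Model

Age-specific mortality per species follows the Siler bathtub hazard
`mu(x) = exp(a0 - a1 x) + c + exp(b0 + b1 x)` with `a1, c, b1 > 0` and
`a0, b0` unconstrained. The cumulative hazard integrates in closed form,
giving

```
log S(x) = (e^a0/a1)(e^(-a1 x) - 1) - c x - (e^b0/b1)(e^(b1 x) - 1)
```

and life expectancy `e0 = ∫ S`. `life_expectancy` integrates the closed
form by adaptive quadrature with the upper limit at the age where S drops
below 1e-10, capped at 200 years; a dense-trapezoid oracle in the tests
agrees to well below the posterior uncertainty of any realistic fit.

### Likelihood and latent birth times

A census record is (entry time, last-seen time, death flag), plus either a
birth date or an unknown-birth marker with a lower bound on the age at
entry. Known-birth individuals contribute the standard left-truncated,
right-censored likelihood
`d·log mu(x_end) + log S(x_end) - log S(x_entry)`.

Unknown birth dates are latent parameters. Their prior is
survival-weighted: a flat calendar birth flow times the probability of
surviving to the observed entry, which is the stationary-population
distribution of a randomly encountered animal. Two consequences follow.
First, the survival weight cancels the truncation term, so unknown-birth
individuals effectively contribute the untruncated density of their
observation. Second, the prior's normalization — the probability that a
random individual is alive with age above the recorded entry-age lower
bound, i.e. the tail integral of S (equal to e0 when the bound is zero) —
depends on the mortality parameters and must enter the target; omitting it
rewards parameter values that inflate survival. Both terms are implemented
exactly (`post_terms` and `inclusion_penalty` in `siler.py`); the public
`census_log_likelihood` operation exposes the plain truncated form.

Latent-birth bounds are `[end - 200 yr, entry - min_age_at_entry]`.
The recorded lower bound in the synthetic generator is a coarse life-stage
classification (adult = entered at age >= 1 year), deliberately a step
function of age so that conditioning on it is exactly the hard constraint
the sampler applies, with no extra likelihood factor.

### Sampler

Four chains by default, each alternating (a) a joint adaptive random-walk
Metropolis update of the five parameters, with positives on the log scale,
proposal covariance learned Haario-style during burn-in with exponential
forgetting (weight floor 2e-3) and frozen afterwards, acceptance targeted
into 0.25–0.45; and (b) elementwise latent-birth updates (the latents are
conditionally independent given parameters), alternating local random-walk
and uniform independence proposals. Priors: Normal(-2, 1) on a0 and b0,
Exponential(1) on a1, c, b1; all configurable in `SamplerConfig`.

Defaults are 10 000 iterations with the first half as burn-in. Convergence
requires split-chain Gelman–Rubin below 1.05 for the five parameters and
derived e0; a non-converged fit is rerun once at doubled length. Posterior
e0 draws come from vectorized trapezoid integration of S on a 4001-point
grid over [0, 200] years for thinned parameter draws.

### Fit-adequacy gate

Species whose records the model cannot fit are flagged rather than
dropped silently: for known-birth deaths, the probability-integral
transform conditional on entry age and on death before the study end
(taken as the latest end time in the cohort) is Uniform(0, 1) under a
well-specified model; a Kolmogorov–Smirnov test at alpha = 0.01 on these
PIT values sets `fit_adequate`. Flagged species keep a missing life
expectancy and are imputed by the comparative stage.

## Comparative stage (SEM)

### Structure

With all continuous variables standardized (life expectancy, body and
brain mass on the natural-log scale first):

```
BO_true ~ MVN(mu_BO·1, S_BO)
BR_true = alpha + beta_allo·BO_true + u_BR,   u_BR ~ MVN(0, S_BR)
LE_true = c0 + b_I·I + b_BO·BO_true + b_RB·u_BR + b_LA·LA + b_D·D(k)
          [+ b_DT·DT + b_CS·CS + b_AFR·AFR] + u_LE,  u_LE ~ MVN(0, S_LE)
observed = true + Normal(0, SE)  for LE, BO, BR
S_v = eta_v^2·E + sigma_v^2·I,   E_ij = exp(-rho·d_ij^2)
```

Relative brain size is the latent allometric residual `u_BR`; it is never a
stored datum and is recomputed per draw, so the allometry and the outcome
model inform each other. The phylogenetic correlation E uses squared
patristic distances rescaled to a maximum of 1 (tree depth is arbitrary
across sources); each of the three error-carrying variables has its own
amplitude `eta_v^2` and independent variance over a shared decay rate rho.
The ordinal diet predictor uses a monotonic ordered effect: b_D times the
cumulative sum of simplex-constrained increments (softmax of K-1 free
parameters; 4 levels by default), with dummy coding available.

### Estimation: analytic marginalization

Conditional on the coefficients and scales, everything latent —
BO_true, u_BR, LE_true, and any missing LE/BO/BR cell — is jointly
Gaussian, so it is integrated out analytically. The observed cells of the
stacked vector [BO; BR; LE] then follow a single multivariate normal whose
mean and covariance are explicit in ~20 hyperparameters, and MCMC runs on
those alone. This is dramatically better conditioned than sampling
hundreds of latent values: the sampler is Metropolis-within-Gibbs with
three adaptive blocks — covariance-affecting parameters (beta_allo,
beta_BO, beta_RB, kernel parameters; fresh Cholesky per proposal),
mean-only parameters (cached factor, triangular solves only), and missing
continuous-covariate cells. Latent values and missing-cell imputations are
recovered exactly per stored posterior draw from the Gaussian conditional
given the observed data — which is precisely a multinormal imputation
conditioned on observed data, phylogenetic covariance and structural
means.

Priors: Normal(0, 1) on all standardized coefficients and intercepts,
Exponential(1) on eta^2, rho and the sigma scales (log-scale sampling with
Jacobians). Two chains of 4000 iterations (half burn-in) by default, with
the same Rhat-1.05/doubled-rerun policy; the marginal posterior of the
structural coefficients mixes fast, while the kernel hyperparameters are
weakly identified and dominate any residual Rhat excess.

### Reporting scale of the brain-size effect

The coefficient b_RB applies to the latent residual u_BR, whose *marginal
prior* sd (sqrt(eta_BR^2 + sigma_BR^2)) is weakly identified: a slow decay
rate makes the phylogenetic term nearly a shared intercept that inflates
the marginal variance without changing the realized spread across species.
Reported relative-brain-size effects are therefore per sd of the
*realized* residual: each stored draw of b_RB is multiplied by the sample
sd of its latent u_BR draw. This matches the data-level standardization
used for every other predictor. All other coefficients are per sd of their
standardized observed covariate.

`overlap_with_zero` is the posterior mass on the opposite side of zero
from the posterior mean; intervals are equal-tailed 89%.

### Missing data

Species with at least one observed variable enter the design; all-missing
species are dropped with a logged count. Missing LE/BO/BR cells are part of
the marginalized Gaussian and get exact conditional draws. Missing
continuous covariates (latitude range, developmental time, clutch size)
are sampled as parameters with an empirical-Bayes phylogenetic Gaussian
prior (signal fraction and decay chosen by grid marginal likelihood on the
observed cells). Binary insularity and ordinal diet are not imputed —
their sources (literature and expert elicitation) are near-complete in the
motivating data — and missing cells are filled with the modal level under
a logged warning. Model 3 is complete-case in AFR only.

### Measurement-error behaviour

Doubling observation SEs widens the brain-size posterior interval in the
regular regime (SE below the residual spread). When measurement error
reaches the scale of the allometric residual itself, the model infers that
relative brain size barely varies and the per-sd effect attenuates toward
zero with a narrow interval — correct behaviour for an unidentifiable
contrast, but worth knowing when interpreting fits to noisy brain-mass
compilations.

## Synthetic-data generator

The generator inverts the analysis: a pure-birth (Yule) tree rescaled to
unit crown depth; unit-variance phylogenetically correlated draws from the
same L2-norm kernel for body mass, the brain residual, latitude, diet (by
quantile-thresholding a latent), developmental time, clutch size and AFR
(the last three correlated with body size); standardized log life
expectancy as the structural linear predictor plus a kernel-distributed
noise term; and per-species Siler parameters solved (by hazard
proportionality, which preserves the Siler form) so e0 equals the species'
generated life expectancy. Census records draw death ages by inverse
transform from S (vectorized bisection), censor at the study window end,
and hide a fraction of birth dates; unknown-birth animals are transfers
whose entry ages are drawn independently of death, with inclusion enforced
by rejection — exactly the left-truncation the likelihood conditions on.

Default conditions mirror the motivating study: 360 candidate species with
life expectancy observed for ~60% and AFR for ~25%; structural
coefficients use the study's printed values where printed (developmental
time 0.01, clutch size -0.08, AFR -0.11; relative brain size 0.2, within
the printed 0.16–0.22 range across models) and field-plausible values for
the rest (body 0.40 — strongly positive; insularity -0.10; latitude and
diet 0.05); allometric slope 0.6 on log-log scale with residual sd 0.2
log-units; kernel eta^2 = 0.3, rho = 3, independent sd 0.45 on the
standardized scale; measurement sds 0.10/0.05/0.10 log-units for
LE/body/brain; size-biased missingness logistic in standardized log body
mass with strength 1 (smaller species more likely missing, as in zoo
collections). Body masses span roughly 12 g to 3 kg and life expectancies
roughly 4 to 40 years, the realistic parrot range.

What the generator does **not** emulate: institution transfer histories,
record-cleaning artifacts, heaped or misrecorded dates, diet/insularity
missingness, and any directional feedback of longevity on brain size.
Passing recovery tests therefore demonstrates correctness of the
estimation machinery under the stated model, not robustness to the messier
failure modes of real census compilations.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale, chosen as the
smallest sizes at which the statistical checks have useful power:
survival recovery uses cohorts of 1000 individuals (20 cohorts in the test
suite, 10 in the acceptance script); SEM recovery uses 200 species;
null-model calibration and smaller fits use 60–100 species. Kernel jitter
is 1e-9; the SEM's conditional-draw Cholesky adds 1e-8. Exponentiated
parameters are clipped at +/-30 on the log scale before matrix assembly.
Ties in the diet quantile thresholds resolve by `searchsorted` (left).
Degenerate inputs — empty record lists, single-measurement species,
zero-variance standardization, trees with fewer than two tips — raise
errors rather than warnings, except the no-death-record cohort, which
warns and proceeds prior-dominated.

## Known limitations

- The survival sampler's inclusion penalty assumes a diffuse entry-age
  process; strongly informative entry processes (e.g. all animals acquired
  as chicks) would need the entry-age density modelled explicitly.
- The SEM treats diet as monotonic in protein class and does not impute
  binary/ordinal covariates.
- Kernel hyperparameters (amplitude vs decay) are weakly identified on
  small trees; coefficient inference is insensitive to this, but the
  hyperparameters themselves should not be interpreted.
- Model comparison across models 1–3 is descriptive (coefficient
  stability), not a formal causal identification.
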