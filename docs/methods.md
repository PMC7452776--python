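# Methods

This package implements a linked set of Bayesian models for the reproductive
demography of eastern wild turkey (*Meleagris gallopavo silvestris*) hens
monitored by VHF telemetry over two breeding seasons, together with a
synthetic-study generator that carries exactly the statistical structure the
models assume. This note documents the models, their assumptions, the
numerical choices, and the properties and limitations we have measured.

## Data model

Four delimited tables describe a study: hen-years (age class, body mass,
availability on 1 April), nest attempts (incubation onset and fate dates,
cover type, visual obstruction, total cover, distance to road, coordinates),
brood series (initial poult count, censuses at 7/14/28 days posthatch, hen
death day), and station-level daily weather. Ordinal dates are day-of-year
integers; coordinates are planar meters. Daily precipitation and temperature
are assigned to each nest and brood from the Euclidean-nearest monitoring
station, with exact distance ties broken by the smallest station identifier
so the assignment is independent of file ordering.

Nest encounter histories are absorbing binary vectors reconstructed from
onset and fate dates: a failed attempt is all ones followed by a terminal
zero, a hatched attempt is all ones over the incubation window. Attempts
censored for investigator interference or site access are excluded from
survival analysis; the death of an incubating hen is a nest failure (and
removes her from renesting availability).

## The six models

**Nesting rate** — logistic regression for the probability that a hen alive
on 1 April initiates a nest, with hen age class, season, and centered body
mass. Intercept prior N(0.9, 0.2) and adult log-odds-ratio prior N(1.6, 0.8)
on the logit scale (elicited from published rates); logistic(0, 1) on other
slopes.

**Daily nest survival** — survival of nest *i* on exposure day *t* is
Bernoulli with p_it = logit⁻¹(x_itᵀ β_i). Covariates: hen age, daily
precipitation (mm), daily mean temperature (°C), their interaction, cover
type contrasts against grassland, mean VOR (Robel-pole increments), mean
total cover, and distance to road (m). Every coefficient is a nest-level
Gaussian random variable, β_ji ~ N(μ_j, 1/τ_j); population means carry
N(3.2, 0.3) (intercept) and N(0.3, 0.4) (adult) priors, other means
logistic(0, 1), and precisions gamma(shape = 1, rate = 1). A switch
restricts random variation to the intercept or disables it (fixed-effects
logistic) because per-nest slopes on nest-constant covariates are weakly
identified from a single fate sequence; the default keeps all coefficients
random. Cumulative survival over a 28-day incubation horizon is the per-draw
power of the daily probability at the population-mean coefficients (a
"typical new nest": random effects at their logit-scale mean), at a stated
cover type and age class with continuous covariates at sample means.

**Covariate imputation** — VOR and total cover may be missing only for
failed nests (vegetation removed by haying before measurement), which makes
the missingness ignorable given fate. Each such covariate gets a Gaussian
population model on the centered scale (mean ~ N(0, 10), sd ~ Uniform(0, 10))
and the missing values are latent parameters updated jointly in the MCMC.

**Renesting rate** — logistic regression over hens whose first attempt
failed and who survived it, on age, season, ordinal failure date, previous
incubation duration (onset to failure), and mass. Intercept N(−0.7, 0.6),
adult N(0.6, 0.7). Only first-to-second transitions are modeled; third
attempts re-enter other models through the attempt covariate coded
"second-or-later".

**Clutch size** — Poisson log-link regression over nests with a reliable egg
count, on age, season, mass, and attempt. Intercept N(2.4, 0.4), adult
N(0.0, 0.6), other slopes N(0, 1) on the log scale.

**Hatchability** — binomial logistic regression of eggs hatched out of eggs
laid per successful nest, on age, season, and mass. Intercept N(1.3, 0.9),
adult N(−0.2, 1.1).

**Poult survival** — the number of poults alive in brood *i* at day index
*t* (hatch day t = 1) is N_it ~ Binomial(N_i,t−1, φ_it), with
logit-linear φ in brood age (centered days posthatch), hen age, season,
daily weather and the precipitation×temperature interaction. Counts are
observed only at t = 8, 15, 29; other days are latent. Because a composition
of binomial thinnings is a binomial thinning with the product probability,
the latent days marginalize exactly: each census interval contributes one
binomial term with the product of its daily survival probabilities. We fit
this marginal likelihood (identical to the data-augmented formulation, far
better mixing); a forward-summation evaluation over latent counts is kept
behind `method="enumerate"` and is verified to agree to 10⁻¹⁰. If the hen
died on day *a*, censuses at or after *a* are structural zeros and carry no
binomial term (marginally, a death-truncated partial interval contributes
exactly 1). Intercept prior N(3.4, 0.1); the adult contrast gets
logistic(0, 1) because published poult survival rarely distinguishes hen age.

**Centering.** All continuous covariates are mean-centered before fitting so
that intercept priors elicited from overall published rates apply at average
conditions (an uncentered intercept — survival of a 0 kg hen at 0 °C — would
make those priors meaningless). Centering constants are stored on each model
for back-transforming effect curves to natural scales. Reference levels:
yearling hens, grassland cover, first study year, first attempt.

## Prior elicitation

`elicit_gaussian_prior` pools published point estimates by transforming them
to the link scale (logit or log) and returning the unweighted mean and
sample standard deviation (a configurable floor, default 1.0, for a single
estimate). It is provided as a utility; the canonical priors used by every
fitter are the fixed constants in `default_priors()` listed above, so the
pooling rule cannot affect results. Meta-analytic weighting by published
standard errors is deliberately out of scope.

## Posterior computation

No probabilistic-programming backend is used; the sampler is part of the
package. `run_mcmc` runs several independent chains of component-wise
adaptive random-walk Metropolis: each scalar parameter has its own proposal
scale, tuned in warmup batches of 50 toward a 0.44 acceptance rate and
frozen for sampling. Chains start from independent prior draws. Convergence
is the split-chain potential scale reduction factor (R-hat, degenerate
chains return exactly 1); if any monitored R-hat exceeds 1.1, warmup and
sampling double and the run repeats, up to `max_doublings` times, after
which a non-convergence flag is set on the results — never silently passed.
Defaults are 3 chains × 2,000 warmup + 2,000 draws. Equal-tailed credible
intervals use the linear-interpolation empirical quantile definition.

The hierarchical nest model has its own blocked Metropolis-within-Gibbs
sampler: per-nest coefficient columns are updated with vectorized Metropolis
steps across nests (nests are conditionally independent; proposal sd scales
with the current population sd); nests whose design column is identically
zero (e.g. cover contrasts of other cover types) get exact conjugate draws;
population means use conjugate Gaussian draws under Gaussian priors and
near-independence proposals under logistic priors; precisions are exact
conjugate gamma draws; and a joint translation move shifts a population mean
together with its whole coefficient column to break the slow tandem walk of
the centered parameterization. Imputed covariates are Metropolis-updated
with their population model, whose mean is conjugate and whose sd is a
log-scale random walk. With no data every update collapses to an exact prior
draw, so the no-data posterior is the prior by construction of each
conditional (and is verified by Kolmogorov–Smirnov tests).

A trapezoid-rule grid-integration oracle over one- or two-parameter models
provides an independent check: intercept-only fits of the nest, poult,
nesting-rate and hatchability samplers are required to match the oracle's
posterior mean within three Monte-Carlo standard errors.

## Synthetic-study generator

The generator emulates the monitored study design end to end: hen-years with
an age mixture (default 50% adult) and age-specific body mass
(yearling 4.3 kg, adult 5.1 kg, sd 0.45 — typical eastern wild turkey hen
masses); ten weather stations on a grid over a 60 km extent, each with
temperature = seasonal sinusoid + AR(1) noise (mean 15 °C, amplitude 10 °C,
lag-1 correlation 0.6, noise sd 3 °C) and precipitation = Bernoulli wet day
(p = 0.35) × exponential amount (mean 5 mm); Bernoulli nesting; absorbing
daily nest survival with per-nest Gaussian random coefficients (default sd
0.1) and nearest-station weather; multinomial failure causes in proportions
0.09/0.12/0.16/0.58/0.05 (abandonment, hen death, haying, predation,
trampling); VOR/total-cover deletion for hayed (p = 0.9) and other failed
(p = 0.05) nests; renesting conditional on failure date; truncated-Poisson
clutches; binomial hatching; and a latent binomial-thinning poult chain with
a small daily hen mortality hazard (0.003) recorded only at the three
censuses. About 7% of attempts are censored (half interference, half site
access), mirroring the monitored study's censoring fraction.

Default true coefficients are chosen so the implied rates match the
monitored study's estimates: nesting 0.70/0.80 (yearling/adult), daily nest
survival logit 3.4 (28-day survival ≈ 0.40) with agriculture strongly
negative, renesting 0.26/0.59, mean clutch 10.5, hatchability 0.87/0.88, and
28-day poult survival 0.16/0.33 with a +0.08/day brood-age slope (the poult
intercept and adult contrast are solved numerically from those targets).
The generator centers covariates at fixed configured constants while fitters
center at sample means; the truth record stores the generator's constants so
recovery tests translate the true intercept into the fitter's
parameterization (slopes are unaffected by centering).

What the generator does **not** emulate: spatially correlated weather
fields, predator communities, hen movement, brood mixing (crèches),
nest-detection failure during laying, or hens carrying over between years.
Passing recovery tests therefore demonstrate that the fitters estimate the
models' own parameters under the models' own assumptions — not that those
assumptions hold in field data.

## Measured properties and known limitations

Two genuine properties of the published model formulation surfaced in
recovery experiments and are documented here deliberately; during
development both were cross-checked against an independent JAGS (rjags)
implementation of the identical model, which reproduced the same posteriors,
so they are properties of the model, not of this sampler. The coverage
numbers below are the ones `tests/test_acceptance.py` recomputes.

1. **Variance inflation in the random-coefficients nest model.** The
   gamma(1, 1) precision priors place substantial mass on very small
   precisions, and nests that hatch (an all-ones fate sequence) reward
   unboundedly large intercepts. On synthetic data with tiny true nest-level
   variation, the posterior nest-level intercept sd inflates to several
   logit units. The population-mean intercept remains well behaved (largely
   pinned by its informative prior), and cover, VOR, total-cover,
   distance-to-road and adult means recover their truths, but the weather
   coefficients do not: failure always falls on the last exposure day, and
   temperature rises within an incubation window, so inflated per-nest
   temperature slopes that are negative can "explain" every failure,
   dragging the population mean negative and the interaction with it,
   regardless of the true values. Consequently 95% intervals for the
   temperature, precipitation and interaction means do not reliably cover
   generator truth at study scale, and the hierarchical fit does not
   converge to the fixed-effects fit even when the generator's
   random-coefficient sds are zero. Inferences about weather effects from
   this model formulation should be treated with corresponding caution; the
   `random_effects="none"` switch recovers all coefficients correctly.

2. **Prior–truth tension in the poult intercept.** The informative
   intercept prior N(3.4, 0.1) encodes published daily poult survival,
   while the generator (matching the monitored study's low estimates)
   implies a true intercept near 2.97 — more than four prior sd away. At
   200 broods the posterior compromises between prior and likelihood, so
   the intercept interval typically excludes the generator truth (the
   brood-age slope absorbs part of the conflict). All other poult
   coefficients recover.

Other numerical choices: day-level Bernoulli terms are computed as
−softplus(±η), so extreme linear predictors underflow gracefully and a
probability of exactly 0/1 contradicting an observation yields −∞ rather
than an exception; binomial interval terms with interval survival exactly 1
are handled as point masses; clutch simulation truncates Poisson draws at 1
(eggs are counted only for initiated clutches; at mean 10.5 the truncation
is negligible); the adaptive proposal scales freeze after warmup so the
chains are valid Markov chains during sampling.

## Problem sizes used in the validation suite

Recovery experiments run 20 seeded replicates per model at 5,000 hen-years
(nesting), ~300 retained nests (nest survival) and ~200 broods (poult
survival), with 2 chains × 500 warmup + 500 draws and one automatic
doubling; oracle-equivalence and prior-recovery checks use 2–3 chains and
1,500–2,500 draws. The acceptance script simulates a study at the monitored
study's own scale (~155 hen-years over two seasons) and fits all six models
with 2 chains × 800 warmup + 800 draws.
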