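# Methods

## Scope and model structure

`cjsage` estimates age- and sex-specific annual survival and breeding success
from multi-population ringing studies of short-lived passerines, and
quantifies actuarial and reproductive senescence as the posterior distribution
of the slope of each rate against age.

### Survival: hierarchical Cormack–Jolly–Seber

Encounter histories are left-truncated at the first adult observation, so all
inference conditions on first adult capture.  Apparent survival φ confounds
mortality with permanent emigration, as in any CJS analysis; emigration is not
modelled separately.

Two variants are fitted to the joint data from all populations:

* **Model 1 (`sex_specific_age`)** — known-age adults:
  `logit φ_ijt = α[age_it, sex_i] + ε_pop_j + ε_ind_i`,
  allowing sex-specific senescence rates.
* **Model 2 (`common_age_sex_intercept`)** — known-age adults:
  `logit φ_ijt = α[age_it] + β_{j,sex_i} + ε_pop_j + ε_ind_i`,
  a common age pattern with an additive sex contrast.

Unknown-age adults are analyzed jointly under both variants through
`logit φ = γ + β_{j,sex} + ε_pop + ε_ind`, where γ is the mean logit survival
of females.  They share ε_pop, ε_ind and the variance components with the
known-age submodel; this joint analysis is what makes the sparse known-age
data usable, because most observed adults (roughly two thirds under the
default generator, matching real multi-site ringing studies) are of unknown
age.  The sex contrast is hierarchical across populations,
`β_{j,male} ~ N(d, σ_d²)` with `β_{j,female} ≡ 0`, so `d` is the mean
male–female survival difference on the logit scale and `p(d > 0)` measures
the evidence for higher male survival.

Recapture is population- and sex-specific with annual random effects:
`logit p_ijt = η_{j,sex} + ε_{t,j}`, `ε_{t,j} ~ N(0, σ_p[j]²)`.  The terminal
φ·p confounding of any CJS model is accepted; because the annual recapture
effects are random (shrunk towards η), the terminal parameters remain proper,
they are simply informed mostly by the hierarchy.

Age is categorical with classes `1..cap` and ages above the cap pooled into
the terminal class.  The default cap is 5: in short-lived chats very few
individuals live beyond five years, so higher classes would be empty.

### Likelihood

The latent alive/dead process is marginalized analytically per individual
with a forward pass over the absorbing two-state chain, conditional on first
capture.  No latent survival states are ever sampled; the MCMC sees only
coefficients and random effects.  This keeps the sampler dimension at
(number of individuals + coefficients) rather than (individual × year), and
makes the likelihood exactly testable: the test suite verifies the forward
pass against brute-force enumeration of all latent sequences to 1e-12 for
every detection pattern up to length 6, and verifies that pattern
probabilities sum to one.

### Breeding success: Bernoulli GLMM

Annual breeding success (≥ 1 fledgling, one collapsed record per
individual-year) is modelled as
`BS ~ Bern(ω)`, `logit ω = α_bs[age] + γ_pop + γ_year + γ_ind` for known-age
records and `logit ω = μ + γ_pop + γ_year + γ_ind` for unknown-age records,
with independent variance components for population, calendar year and
individual.  Year effects are indexed by calendar year, so populations with
overlapping windows share them.  An optional sex-stratified variant replaces
`α_bs[age]` with `α_bs[age, sex]`; the unknown-age mean μ is not stratified,
since those records' role is to sharpen the random effects.  The breeding
variance components are separate from the survival ones.

### Senescence slopes

For every retained posterior draw, the age-class rate is evaluated at the
reference level (population effect 0 — the population average — or a named
population's effect; individual effect 0), and regressed on age class by
unweighted OLS.  The slope draws form the posterior of the senescence slope;
reported are its mean, central 95% credible interval and `p(slope < 0)`.
Exact zero slopes split evenly between the negative and positive tallies, so
a degenerate constant trajectory reports `p(slope<0) = 0.5`.

The default scale is probability: a slope of −0.05 means the annual rate
declines by five percentage points per age class, which is the natural scale
for rates near 0.5 and the scale on which a "roughly 10% per year" decline in
survival near 0.5 reads directly.  The logit scale is available.  For
`sex="both"` the two sexes' predictors are averaged on the probability scale
before regression.  Slope summaries default to 12,000 posterior replicates
obtained by uniform thinning of the retained draws (configurable; when fewer
draws were retained, all are used).

## Priors and MCMC

Priors are vague: `N(0, 10²)` for all logit-scale coefficients
(α, γ, d, η, μ), `Uniform(0, 5)` for every random-effect SD.  The constants
are package choices (recorded in fit metadata) — on the logit scale an SD of
5 already spans essentially degenerate rate heterogeneity, and coefficient
values beyond ±20 are numerically saturated.

The sampler is a blocked adaptive Metropolis-within-Gibbs scan, chosen
because the marginalized CJS likelihood is non-conjugate and
gradient-unfriendly at the individual level:

* age coefficients are updated one age class at a time with per-coordinate
  adapted scales (under model 1 the two sexes of a class touch disjoint
  individuals and are accepted in parallel within one proposal);
* every random-effect family whose levels touch disjoint likelihood terms
  (individual effects, population effects, sex contrasts, recapture means,
  breeding factor levels) is proposed element-wise and accepted level-wise in
  parallel — valid because the likelihood factorizes over individuals
  (survival) or records (breeding);
* annual recapture effects are updated jointly per population;
* each SD is coupled to its effects by two extra moves that are essential for
  mixing in these models: a *rescaling* move (σ and its centered effects
  scaled by a common `exp(δ)`; the effects-prior change and the
  transformation Jacobian cancel up to +δ) and a prior-only *translation*
  move along the intercept/effects ridge (all effects +δ, all intercept cells
  −δ; the likelihood is invariant).  Without these, σ_ind and the intercepts
  show classic R-hat > 1.5 pathologies;
* `d` is updated by its exact Normal Gibbs conditional; SDs additionally get
  cheap prior-only Metropolis moves.

Scale adaptation is diminishing (Robbins–Monro on the log scale, target
acceptance 0.44 scalar / 0.234 block).  Initialization: coefficients
`N(0, 0.1)`, SDs `Uniform(0.1, 1)`, random effects `N(0, 0.1)`, jittered per
chain.  Convergence is monitored with the classic between/within-chain
Gelman–Rubin statistic; fits flag any parameter with R-hat ≥ 1.1, and the
pipeline exits non-zero on non-convergence unless explicitly allowed.  A
zero-variance parameter reports R-hat = 1 by convention.

Default desk-scale protocol: 3 chains × 4,000 iterations, burn-in 1,000,
thinning 2.  The full-length protocol (3 × 100,000, burn-in 20,000, thinning
10) is a config choice for full reproductions.  Tests and the acceptance
script use 2–3 chains of 1,200–3,500 iterations; at those lengths every
quantity they assert on has R-hat comfortably below 1.1 on the problem sizes
used.

The generic `sample_posterior` (whole-vector adaptive random-walk Metropolis)
serves arbitrary log-posteriors and is validated on analytic targets (Normal
moments, ρ=0.9 correlated Normal, Beta via logit transform with Jacobian).

## Goodness of fit

Transience (TEST3.SR) and trap-dependence (TEST2.CT) are computed natively
from per-occasion 2×2 contingency tables with summed Pearson chi-squares,
per population or pooled.  TEST3.SR classifies animals encountered at an
occasion as newly vs previously marked against ever-seen-again; TEST2.CT
conditions on animals known alive at an occasion and seen later, and
cross-classifies detection there against whether the next detection is
immediate.  Tables with any expected count below 2 are accumulated into the
following occasion's table; terminally degenerate tables are dropped from the
degrees of freedom, and a study with no informative table reports an explicit
"untestable" result.  A signed z (positive = transience excess /
trap-happiness) accompanies each component.  The chi-square reference
distribution is asymptotic: at a few hundred histories the tests run
slightly anticonservative, which the calibration tests account for by using
adequate sample sizes.

## Synthetic-data generator

`simulate_study` is an individual-based mirror of the fitted models plus the
observation process of a real multi-site ringing study:

* seven default populations with windows of 5–16 years and annual inputs
  scaled to a real whinchat study design (~1,500 observed adults at scale 1);
* nestlings ringed at age 0, unsexed, recruiting locally as 1-year-olds with
  probability `juvenile_return_prob` (default 0.09, set so that ~6% of ringed
  nestlings are ever recaptured as adults — the observed attrition in
  grassland passerines); recaptured recruits are known-age;
* unknown-age adult immigrants entering every year with true ages drawn from
  the stationary age distribution implied by the survival truth (cumulative
  survival products, truncated at the cap); 1-year-old immigrants are
  plumage-aged with probability 0.3, entering as known-age yearlings;
* survival, detection and breeding generated from the logit-linear predictors
  with population, individual, annual and year effects drawn from the
  configured SDs;
* breeding outcomes are recorded only for detected adult-years and only in
  populations with nest monitoring (one default population has none);
* default truth: female survival (.47, .42, .37, .32, .27) by age class —
  a 0.05/year decline on the probability scale; d = 0.53; detection means
  .49 (F) / .66 (M) with among-population spread 0.3; breeding success .79,
  flat in age; SDs 0.25–0.5 on the logit scale.

What the generator does **not** emulate: real dispersal distance structure
(emigration is absorbed into apparent survival), density dependence,
environmental covariates (mowing dates, predation pressure), observer effort
changes, and any age structure in the unknown-age immigrants' detectability.
Passing recovery tests therefore show that the estimator inverts its own
generative assumptions at realistic sample sizes — not that those assumptions
hold in any particular field system.

## Numerical choices and degenerate inputs

* Probabilities are produced only through the inverse logit, so they cannot
  leave (0,1); a likelihood of exactly zero returns −inf rather than raising.
* SD values outside their uniform support make the log-posterior −inf
  (rejection), not an exception.
* A history entering at the final occasion contributes likelihood 1 (no
  post-entry data) but still carries its individual effect's prior.
* A population with zero breeding records contributes to the breeding model
  only through priors; a study with a single age class refuses slope
  regression ("at least 2 distinct ages").
* OLS slopes use the closed form Σ(x−x̄)y / Σ(x−x̄)²; ties in p(slope<0)
  split evenly.
* Empty m-arrays are all-zero; recaptured birds re-enter release cohorts.

## Problem sizes used by tests and the acceptance script

The test suite fits reduced studies (1–3 populations, 6–10 occasions,
~250–450 adults; 2 chains × 1,200–3,000 iterations), sized so the full suite
completes on a laptop-class single core.  Parameter-recovery coverage uses 20
replicates at 3 populations × 8 occasions (~370–400 adults); slope
calibration uses 20 replicate breeding fits plus one high-n power fit; GOF
calibration uses 200 homogeneous simulations of 500 histories and 30 power
replicates of 1,000.  The acceptance script simulates the full seven-
population design (~1,400–1,500 adults) and fits all four model variants with
2 chains × 3,500 iterations.

## Known limitations

* γ (unknown-age mean survival) absorbs an age mixture; if the true age
  distribution of immigrants shifts over time the shared random effects can
  be biased.  This mirrors the fitted model's own assumption.
* σ_ind (individual frailty SD) is weakly identified in binary data with few
  repeat observations per individual; its posterior is prior-sensitive, and
  intercepts should be read as conditional on ε_ind = 0, not as marginal
  (population-mean) rates.
* Upper age classes in desk-scale data hold a handful of individuals;
  their intercept posteriors are wide and prior-influenced, and small-sample
  95% CrIs for such parameters do not carry exact frequentist coverage at a
  fixed truth.
* The GOF chi-squares use asymptotic reference distributions and are
  anticonservative for very sparse tables despite pooling.
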