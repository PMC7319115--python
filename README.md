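# cjsage

Bayesian age- and sex-specific survival and breeding-success analysis for
multi-population mark–recapture studies of short-lived birds.

## The problem

Detecting senescence — the within-individual decline of fitness components
with age — in a short-lived wild passerine is hard: almost all individuals of
known age were ringed as nestlings, only a few percent of ringed nestlings
are ever recaptured as adults, and many breeding adults enter the marked
sample at an unknown age.  `cjsage` implements the joint modelling strategy
that makes such data usable: several demographically independent populations
(with different monitoring windows) analyzed together, known-age and
unknown-age adults fitted jointly so they share random effects, and
senescence quantified as a posterior distribution of the slope of
age-specific rates — not as a point estimate.

It is aimed at population ecologists with individual-based ringing/resighting
data (annual detections of colour-ringed adults plus binary breeding
outcomes) who want age trajectories of apparent survival φ and breeding
success, sex differences, and defensible evidence measures for senescence.

## The models

**Survival** is a hierarchical Cormack–Jolly–Seber model on left-truncated
adult encounter histories (entry at first adult observation).  For known-age
adults, either

* model 1: `logit φ_ijt = α_{age,sex} + ε_pop_j + ε_ind_i` (sex-specific
  senescence), or
* model 2: `logit φ_ijt = α_age + β_{j,sex} + ε_pop_j + ε_ind_i` (common age
  pattern, sex-specific intercept),

with unknown-age adults jointly modelled as
`logit φ = γ + β_{j,sex} + ε_pop + ε_ind` under both variants, sharing the
random effects.  The sex contrast is hierarchical across populations,
`β_{j,male} ~ N(d, σ_d²)`, female reference.  Recapture:
`logit p = η_{j,sex} + ε_{t,j}`.  The latent alive/dead process is
marginalized exactly (forward algorithm), so MCMC runs only over
coefficients and random effects.

**Breeding success** (≥ 1 fledgling, one record per individual-year) is a
Bernoulli GLMM: `logit ω = α_age + γ_pop + γ_year + γ_ind` (known age) and
`logit ω = μ + γ_pop + γ_year + γ_ind` (unknown age), optionally
sex-stratified.

**Senescence** is summarized per posterior draw: the age-class rates (at the
population-average random-effect level) are regressed on age by OLS, giving
the slope's posterior mean, 95% credible interval and `p(slope < 0)`.

Goodness-of-fit diagnostics (transience TEST3.SR, trap-dependence TEST2.CT)
are computed natively from per-occasion contingency tables, and an
individual-based simulator generates whole multi-population studies with
known truth — every stage of the pipeline is testable without field data.

See `docs/methods.md` for priors, the blocked adaptive MCMC scheme, numerical
choices and limitations.

## Worked example

Simulate a seven-population study shaped like a real multi-site whinchat
ringing programme (windows of 5–16 years, ~1,500 observed adults, ~6% of
ringed nestlings recaptured), fit survival model 2 and the breeding model,
and summarize senescence:

```python
from cjsage import (default_config, simulate_study,
                    CJSSurvivalModel, BreedingSuccessModel)

dataset, truth = simulate_study(default_config(seed=1))
print(len(dataset.histories), dataset.n_known_age)   # 1140 357

surv = CJSSurvivalModel(dataset, variant="model2").fit(
    chains=2, iterations=3500, burnin=1500, thinning=1, seed=2)
print(surv.slope_summary(sex="both"))
# SlopeSummary(mean=-0.0492, cri=[-0.0954, -0.0026], p_negative=0.982, scale=probability)
print(surv.sex_effect())
# {'mean': 0.376, 'cri': (-0.184, 0.843), 'p_positive': 0.934}
print(surv.recapture_means())
# {'female': {'mean': 0.441, 'range': (0.198, 0.768)},
#  'male':   {'mean': 0.674, 'range': (0.519, 0.890)}}

breed = BreedingSuccessModel(dataset).fit(
    chains=2, iterations=3500, burnin=1500, thinning=1, seed=3)
print(breed.mean_success())      # {'mean': 0.700, 'cri': (0.679, 0.721)}
print(breed.slope_summary())
# SlopeSummary(mean=-0.0162, cri=[-0.0623, 0.0221], p_negative=0.774, scale=probability)
```

Read: annual adult survival declines by about five percentage points per age
class (posterior probability of a negative slope 0.98 — actuarial
senescence, matching the generating decline of 0.05/year), males survive
better than females (d ≈ 0.38 on the logit scale, p(d>0) = 0.93; the
generating d is 0.53), females are detected less often than males (0.44 vs
0.67, truth 0.49/0.66), and breeding success shows no credible age trend.
The fitted mean success of 0.70 against a generating mean of 0.79 is this
realization's draw: the largest simulated population happened to receive a
strongly negative population effect, and the model follows the data.

The same pipeline runs from the shell on CSV data
(`encounters.csv`, `breeding.csv`, `populations.yaml`):

```bash
cjsage simulate      --out run/ --seed 1
cjsage fit-survival  --data run/ --variant model2 --seed 2
cjsage fit-breeding  --data run/ --seed 3
cjsage slopes        --data run/          # writes run/slopes.csv
cjsage gof           --data run/          # transience / trap-dependence report
```

MARK-style `.inp` encounter files are supported via
`read_encounters(..., format="inp")`.

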