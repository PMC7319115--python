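"""Bernoulli mixed model for annual breeding success.

Breeding success of a marked adult in a given year is whether it produced at
least one fledgling.  Known-age records get an age-class intercept on the
logit scale, unknown-age records a common mean, and both share crossed random
effects for population, calendar year and individual:

    BS ~ Bernoulli(omega)
    logit omega = alpha[age]  + g_pop + g_year + g_ind      (known age)
    logit omega = mu          + g_pop + g_year + g_ind      (unknown age)

with g_pop ~ N(0, sigma_pop^2), g_year ~ N(0, sigma_year^2) and
g_ind ~ N(0, sigma_ind^2).  An optional sex-stratified variant replaces
alpha[age] with alpha[age, sex] (the common mean mu for unknown-age adults is
retained, since those records' role is to sharpen the random effects).
Repeat attempts within a year are collapsed upstream to one record per
individual-year.  Year effects are indexed by calendar year, so populations
with overlapping monitoring windows share them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .data import BreedingRecord, StudyDataset, age_class
from .mcmc import AdaptiveScale, PosteriorDraws, PriorSpec, gelman_rubin, summarize_draws
from .survival import _normal_logpdf

__all__ = [
    "BreedingParams",
    "BreedingSuccessModel",
    "BreedingSuccessResults",
    "breeding_predictor",
    "breeding_logposterior",
]


@dataclass
class BreedingParams:
    """Named parameter values for predictor-level evaluation."""

    alpha_bs: dict = field(default_factory=dict)  # age class -> logit success
    alpha_bs_sex: dict = field(default_factory=dict)  # (age class, sex) -> logit success
    mu: float = 0.0
    sigma_bs_pop: float = 0.5
    sigma_bs_year: float = 0.5
    sigma_bs_ind: float = 0.5
    g_pop: dict = field(default_factory=dict)
    g_year: dict = field(default_factory=dict)  # calendar year -> effect
    g_ind: dict = field(default_factory=dict)


def breeding_predictor(
    params: BreedingParams,
    record: BreedingRecord,
    stratify_by_sex: bool = False,
    age_class_cap: int = 5,
    calendar_year: int | None = None,
) -> float:
    """Success probability for one record under the named parameter values."""
    if record.age is None:
        lp = params.mu
    else:
        a = age_class(record.age, age_class_cap)
        if stratify_by_sex:
            if record.sex is None:
                raise ValueError(f"{record.individual_id}: sex needed for stratified variant")
            lp = params.alpha_bs_sex.get((a, record.sex), 0.0)
        else:
            lp = params.alpha_bs.get(a, 0.0)
    yr = calendar_year if calendar_year is not None else record.year
    lp += (params.g_pop.get(record.population_id, 0.0)
           + params.g_year.get(yr, 0.0)
           + params.g_ind.get(record.individual_id, 0.0))
    return float(expit(lp))


class BreedingSuccessModel:
    """Hierarchical Bernoulli GLMM over all breeding records of a study."""

    def __init__(
        self,
        dataset: StudyDataset,
        stratify_by_sex: bool = False,
        age_cap: int | None = None,
        priors: PriorSpec | None = None,
    ):
        self.dataset = dataset
        self.stratify = stratify_by_sex
        self.age_cap = age_cap if age_cap is not None else dataset.age_class_cap
        if self.age_cap < 2:
            raise ValueError("age_cap must be >= 2")
        self.priors = priors or PriorSpec()
        self.pop_ids = sorted(dataset.populations)
        self._build_design()
        self._build_layout()

    def _build_design(self) -> None:
        recs = self.dataset.breeding
        pops = self.dataset.populations
        self.n_rec = len(recs)
        pop_index = {p: j for j, p in enumerate(self.pop_ids)}
        self.n_pop = len(self.pop_ids)
        years = sorted({pops[r.population_id].first_year + r.year - 1 for r in recs})
        self.year_levels = years
        year_index = {y: t for t, y in enumerate(years)}
        inds = sorted({r.individual_id for r in recs})
        self.ind_levels = inds
        ind_index = {i: k for k, i in enumerate(inds)}
        self.n_year = len(years)
        self.n_bind = len(inds)
        self.y = np.array([r.success for r in recs], dtype=float)
        self.rec_pop = np.array([pop_index[r.population_id] for r in recs], dtype=int)
        self.rec_year = np.array(
            [year_index[pops[r.population_id].first_year + r.year - 1] for r in recs], dtype=int)
        self.rec_ind = np.array([ind_index[r.individual_id] for r in recs], dtype=int)
        # fixed-effect cell per record: unknown-age records share the mu cell
        cells: list[int] = []
        for r in recs:
            if r.age is None:
                cells.append(self._n_alpha)
            else:
                a = age_class(r.age, self.age_cap)
                if self.stratify:
                    if r.sex is None:
                        raise ValueError(
                            f"{r.individual_id}: sex required for the stratified variant")
                    cells.append((a - 1) * 2 + (0 if r.sex == "female" else 1))
                else:
                    cells.append(a - 1)
        self.rec_cell = np.array(cells, dtype=int)

    @property
    def _n_alpha(self) -> int:
        return self.age_cap * 2 if self.stratify else self.age_cap

    def _build_layout(self) -> None:
        labels: list[str] = []
        slices: dict[str, slice] = {}

        def add(name, labs):
            slices[name] = slice(len(labels), len(labels) + len(labs))
            labels.extend(labs)

        ages = range(1, self.age_cap + 1)
        if self.stratify:
            add("alpha_bs", [f"alpha_bs[{a},{s}]" for a in ages for s in ("female", "male")])
        else:
            add("alpha_bs", [f"alpha_bs[{a}]" for a in ages])
        add("mu", ["mu"])
        add("sigma_bs_pop", ["sigma_bs_pop"])
        add("sigma_bs_year", ["sigma_bs_year"])
        add("sigma_bs_ind", ["sigma_bs_ind"])
        add("g_pop", [f"g_pop[{p}]" for p in self.pop_ids])
        add("g_year", [f"g_year[{y}]" for y in self.year_levels])
        add("g_ind", [f"g_ind[{i}]" for i in self.ind_levels])
        self.labels = labels
        self.slices = slices
        self.n_params = len(labels)

    # -- likelihood ----------------------------------------------------------
    def _linpred(self, x: np.ndarray) -> np.ndarray:
        s = self.slices
        coef = np.concatenate([x[s["alpha_bs"]], x[s["mu"]]])
        return (coef[self.rec_cell] + x[s["g_pop"]][self.rec_pop]
                + x[s["g_year"]][self.rec_year] + x[s["g_ind"]][self.rec_ind])

    def loglik_vector(self, x: np.ndarray) -> np.ndarray:
        """Bernoulli log-likelihood per record."""
        if self.n_rec == 0:
            return np.zeros(0)
        lp = self._linpred(x)
        return np.where(self.y == 1, -np.logaddexp(0.0, -lp), -np.logaddexp(0.0, lp))

    def logprior(self, x: np.ndarray) -> float:
        s, pr = self.slices, self.priors
        sds = np.array([x[s["sigma_bs_pop"]][0], x[s["sigma_bs_year"]][0],
                        x[s["sigma_bs_ind"]][0]])
        if (sds < 0).any() or (sds > pr.sd_upper).any():
            return -math.inf
        lp = _normal_logpdf(np.concatenate([x[s["alpha_bs"]], x[s["mu"]]]),
                            0.0, pr.coef_prior_sd).sum()
        lp += _normal_logpdf(x[s["g_pop"]], 0.0, sds[0]).sum()
        lp += _normal_logpdf(x[s["g_year"]], 0.0, sds[1]).sum()
        lp += _normal_logpdf(x[s["g_ind"]], 0.0, sds[2]).sum()
        return float(lp)

    def logposterior(self, x: np.ndarray) -> float:
        lp = self.logprior(x)
        if not np.isfinite(lp):
            return -math.inf
        return float(self.loglik_vector(x).sum()) + lp

    def pack(self, params: BreedingParams) -> np.ndarray:
        x = np.zeros(self.n_params)
        s = self.slices
        ages = range(1, self.age_cap + 1)
        if self.stratify:
            x[s["alpha_bs"]] = [params.alpha_bs_sex.get((a, sx), 0.0)
                                for a in ages for sx in ("female", "male")]
        else:
            x[s["alpha_bs"]] = [params.alpha_bs.get(a, 0.0) for a in ages]
        x[s["mu"]] = params.mu
        x[s["sigma_bs_pop"]] = params.sigma_bs_pop
        x[s["sigma_bs_year"]] = params.sigma_bs_year
        x[s["sigma_bs_ind"]] = params.sigma_bs_ind
        x[s["g_pop"]] = [params.g_pop.get(p, 0.0) for p in self.pop_ids]
        x[s["g_year"]] = [params.g_year.get(y, 0.0) for y in self.year_levels]
        x[s["g_ind"]] = [params.g_ind.get(i, 0.0) for i in self.ind_levels]
        return x

    # -- sampling ------------------------------------------------------------
    def _init_vector(self, rng: np.random.Generator) -> np.ndarray:
        x = np.zeros(self.n_params)
        s = self.slices
        for name in ("alpha_bs", "mu", "g_pop", "g_year", "g_ind"):
            sl = s[name]
            x[sl] = 0.1 * rng.standard_normal(sl.stop - sl.start)
        for name in ("sigma_bs_pop", "sigma_bs_year", "sigma_bs_ind"):
            x[s[name]] = rng.uniform(0.1, 1.0)
        return x

    def fit(self, chains: int = 3, iterations: int = 4000, burnin: int = 1000,
            thinning: int = 2, seed: int = 0) -> "BreedingSuccessResults":
        """Blocked adaptive Metropolis-within-Gibbs sampling of the posterior.

        Every fixed-effect cell and every random-effect level touches a
        disjoint set of records within its factor, so each factor is updated
        element-wise in parallel with per-level acceptance.
        """
        if iterations <= burnin:
            raise ValueError("iterations must exceed burnin")
        root = np.random.SeedSequence(seed)
        all_draws, all_chain = [], []
        for c, ss in enumerate(root.spawn(chains)):
            rng = np.random.default_rng(ss)
            kept = self._run_chain(rng, iterations, burnin, thinning)
            all_draws.append(kept)
            all_chain.append(np.full(len(kept), c))
        draws = PosteriorDraws(
            draws=np.concatenate(all_draws),
            labels=list(self.labels),
            chain_id=np.concatenate(all_chain),
            meta={"iterations": iterations, "burnin": burnin, "thinning": thinning,
                  "chains": chains, "seed": seed, "stratify_by_sex": self.stratify,
                  "age_cap": self.age_cap},
        )
        return BreedingSuccessResults(self, draws)

    def _run_chain(self, rng, iterations, burnin, thinning):
        s, pr = self.slices, self.priors
        x = self._init_vector(rng)
        llv = self.loglik_vector(x)
        n_coef = self._n_alpha + 1
        coef_idx = self.rec_cell  # already spans alpha cells + mu cell
        ad_coef = AdaptiveScale(n_coef, 0.2)
        ad_pop = AdaptiveScale(self.n_pop, 0.2)
        ad_year = AdaptiveScale(max(self.n_year, 1), 0.2)
        ad_ind = AdaptiveScale(max(self.n_bind, 1), 0.5)
        ad_sd = AdaptiveScale(3, 0.2)
        ad_resc = [AdaptiveScale(1, 0.3) for _ in range(3)]
        ad_tr = [AdaptiveScale(1, 0.2) for _ in range(3)]
        coef_sl = slice(s["alpha_bs"].start, s["mu"].stop)
        kept = []
        for it in range(iterations):
            self._factor_update(x, llv, rng, coef_sl, coef_idx, n_coef, ad_coef,
                                mu=0.0, sd=pr.coef_prior_sd)
            self._factor_update(x, llv, rng, s["g_pop"], self.rec_pop, self.n_pop,
                                ad_pop, mu=0.0, sd=x[s["sigma_bs_pop"]][0])
            if self.n_year:
                self._factor_update(x, llv, rng, s["g_year"], self.rec_year, self.n_year,
                                    ad_year, mu=0.0, sd=x[s["sigma_bs_year"]][0])
            if self.n_bind:
                self._factor_update(x, llv, rng, s["g_ind"], self.rec_ind, self.n_bind,
                                    ad_ind, mu=0.0, sd=x[s["sigma_bs_ind"]][0])
            # joint (SD, effects) rescaling moves break the slow coupling
            # between each variance component and its shrunken effects
            self._rescale_move(x, llv, rng, "sigma_bs_pop", s["g_pop"], ad_resc[0])
            if self.n_year:
                self._rescale_move(x, llv, rng, "sigma_bs_year", s["g_year"], ad_resc[1])
            if self.n_bind:
                self._rescale_move(x, llv, rng, "sigma_bs_ind", s["g_ind"], ad_resc[2])
            # prior-only translation moves along the intercept/effects ridge
            # (effects + delta, all fixed-effect cells - delta; likelihood
            # invariant, so only prior terms enter the acceptance)
            self._translate_move(x, rng, s["g_pop"], "sigma_bs_pop", coef_sl, ad_tr[0])
            if self.n_year:
                self._translate_move(x, rng, s["g_year"], "sigma_bs_year", coef_sl, ad_tr[1])
            if self.n_bind:
                self._translate_move(x, rng, s["g_ind"], "sigma_bs_ind", coef_sl, ad_tr[2])
            self._update_sds(x, rng, ad_sd)
            if it >= burnin and (it - burnin) % thinning == 0:
                kept.append(x.copy())
        return np.asarray(kept)

    def _factor_update(self, x, llv, rng, sl, level_idx, n_levels, adapt, mu, sd):
        xp = x.copy()
        xp[sl] = x[sl] + adapt.scale * rng.standard_normal(n_levels)
        llv_p = self.loglik_vector(xp)
        if self.n_rec:
            dll = np.bincount(level_idx, weights=llv_p - llv, minlength=n_levels)
        else:
            dll = np.zeros(n_levels)
        dpri = _normal_logpdf(xp[sl], mu, sd) - _normal_logpdf(x[sl], mu, sd)
        acc = np.log(rng.uniform(size=n_levels)) < dll + dpri
        xs = x[sl]
        xs[acc] = xp[sl][acc]
        x[sl] = xs
        if self.n_rec:
            rec_acc = acc[level_idx]
            llv[rec_acc] = llv_p[rec_acc]
        adapt.update(acc)

    def _rescale_move(self, x, llv, rng, sd_name, eff_slice, adapt):
        """Joint log-scale move of one SD with its effects; the effects-prior
        change and the transformation Jacobian cancel up to +delta."""
        import math as _math

        s, pr = self.slices, self.priors
        delta = adapt.scale[0] * rng.standard_normal()
        cur = x[s[sd_name]][0]
        prop_sd = cur * _math.exp(delta)
        if not (0 < prop_sd <= pr.sd_upper):
            adapt.update(False)
            return
        xp = x.copy()
        xp[s[sd_name]] = prop_sd
        xp[eff_slice] = x[eff_slice] * _math.exp(delta)
        llv_p = self.loglik_vector(xp)
        if np.log(rng.uniform()) < (llv_p.sum() - llv.sum() + delta):
            x[s[sd_name]] = prop_sd
            x[eff_slice] = xp[eff_slice]
            llv[:] = llv_p
            adapt.update(True)
        else:
            adapt.update(False)

    def _translate_move(self, x, rng, eff_slice, sd_name, coef_slice, adapt):
        """Shift one random-effect vector by delta and all fixed-effect cells
        by -delta; the likelihood is unchanged, only the priors decide."""
        s, pr = self.slices, self.priors
        delta = adapt.scale[0] * rng.standard_normal()
        sd = x[s[sd_name]][0]
        eff, coef = x[eff_slice], x[coef_slice]
        dlp = (_normal_logpdf(eff + delta, 0, sd).sum()
               - _normal_logpdf(eff, 0, sd).sum()
               + _normal_logpdf(coef - delta, 0, pr.coef_prior_sd).sum()
               - _normal_logpdf(coef, 0, pr.coef_prior_sd).sum())
        if np.log(rng.uniform()) < dlp:
            x[eff_slice] = eff + delta
            x[coef_slice] = coef - delta
            adapt.update(True)
        else:
            adapt.update(False)

    def _update_sds(self, x, rng, ad_sd):
        s, pr = self.slices, self.priors
        groups = [("sigma_bs_pop", "g_pop"), ("sigma_bs_year", "g_year"),
                  ("sigma_bs_ind", "g_ind")]
        acc = np.zeros(3, dtype=bool)
        for k, (sd_name, eff_name) in enumerate(groups):
            eff = x[s[eff_name]]
            cur = x[s[sd_name]][0]
            prop = cur + ad_sd.scale[k] * rng.standard_normal()
            if 0 < prop <= pr.sd_upper:
                delta = (_normal_logpdf(eff, 0, prop).sum()
                         - _normal_logpdf(eff, 0, cur).sum())
                if np.log(rng.uniform()) < delta:
                    x[s[sd_name]] = prop
                    acc[k] = True
        ad_sd.update(acc)


class BreedingSuccessResults:
    """Posterior draws from a fitted breeding-success model plus summaries."""

    def __init__(self, model: BreedingSuccessModel, draws: PosteriorDraws):
        self.model = model
        self.draws = draws

    @property
    def stratified(self) -> bool:
        return self.model.stratify

    def rhat(self):
        return gelman_rubin(self.draws)

    @property
    def converged(self) -> bool:
        return bool((self.rhat() < 1.1).all())

    def summary(self, include_random_effects: bool = False):
        tab = summarize_draws(self.draws)
        if not include_random_effects:
            keep = [l for l in self.draws.labels if not l.startswith("g_")]
            tab = tab.loc[keep]
        return tab

    def mean_success(self) -> dict:
        """Posterior of the average success probability across all records."""
        m = self.model
        if m.n_rec == 0:
            raise ValueError("no breeding records")
        per_draw = np.array([expit(m._linpred(x)).mean() for x in self.draws.draws])
        return {"mean": float(per_draw.mean()),
                "cri": (float(np.percentile(per_draw, 2.5)),
                        float(np.percentile(per_draw, 97.5)))}

    def age_trajectory(self, sex: str = "both", scale: str = "probability",
                       n_draws: int | None = None):
        from .slopes import age_trajectory
        return age_trajectory(self, which="breeding", sex=sex, scale=scale,
                              n_draws=n_draws)

    def slope_summary(self, sex: str = "both", scale: str = "probability",
                      n_draws: int | None = 12000):
        from .slopes import age_trajectory, slope_distribution
        traj = age_trajectory(self, which="breeding", sex=sex, scale=scale,
                              n_draws=n_draws)
        ages = np.arange(1, self.model.age_cap + 1)
        return slope_distribution(traj, ages, scale=scale)


def breeding_logposterior(
    params: BreedingParams,
    dataset: StudyDataset,
    priors: PriorSpec | None = None,
    stratify_by_sex: bool = False,
    age_cap: int | None = None,
) -> float:
    """Log-posterior of named parameter values for a dataset (op-level API)."""
    model = BreedingSuccessModel(dataset, stratify_by_sex=stratify_by_sex,
                                 age_cap=age_cap, priors=priors)
    return model.logposterior(model.pack(params))
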