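"""Hierarchical Cormack-Jolly-Seber survival model with age and sex structure.

Two model variants are fitted to the joint data from all populations:

* ``sex_specific_age`` (model 1): known-age adults get an age-by-sex survival
  intercept, logit phi = alpha[age, sex] + eps_pop + eps_ind, allowing
  sex-specific senescence rates.
* ``common_age_sex_intercept`` (model 2): a common age pattern with an
  additive sex contrast, logit phi = alpha[age] + beta[pop, sex] + eps_pop +
  eps_ind.

Unknown-age adults are analyzed jointly under both variants through
logit phi = gamma + beta[pop, sex] + eps_pop + eps_ind, sharing the
population and individual random effects (and their SDs) with the known-age
submodel; this is what lets sparse known-age data borrow strength.  The sex
contrast is hierarchical across populations, beta[pop, male] ~ N(d, sigma_d^2)
with females as the reference, so ``d`` is the mean male-female survival
difference on the logit scale.  Recapture is population- and sex-specific
with annual random effects: logit p = eta[pop, sex] + eps_time[pop, t],
eps_time ~ N(0, sigma_p[pop]^2).

The latent alive/dead process is marginalized analytically per individual
(forward algorithm over the absorbing two-state chain, conditional on first
capture), so the sampler only ever sees the random effects and coefficients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit

from .data import EncounterHistory, StudyDataset, interval_age_classes
from .mcmc import AdaptiveScale, PosteriorDraws, PriorSpec, gelman_rubin, summarize_draws

__all__ = [
    "ModelVariant",
    "SurvivalParams",
    "CJSSurvivalModel",
    "CJSSurvivalResults",
    "survival_predictor",
    "recapture_predictor",
    "history_loglik",
    "survival_logposterior",
]

MODEL1 = "sex_specific_age"
MODEL2 = "common_age_sex_intercept"
_VARIANT_ALIASES = {"model1": MODEL1, "model2": MODEL2, MODEL1: MODEL1, MODEL2: MODEL2}
_SEX_IDX = {"female": 0, "male": 1}


def _canon_variant(variant: str) -> str:
    try:
        return _VARIANT_ALIASES[variant]
    except KeyError:
        raise ValueError(f"unknown model variant {variant!r}") from None


@dataclass(frozen=True)
class ModelVariant:
    """Which survival structure is fitted; see the module docstring."""

    tag: str = MODEL2

    def __post_init__(self) -> None:
        object.__setattr__(self, "tag", _canon_variant(self.tag))


@dataclass
class SurvivalParams:
    """Named parameter values for predictor-level evaluation.

    ``alpha`` maps (age_class, sex) -> logit survival (model 1);
    ``alpha_common`` maps age_class -> logit survival (model 2);
    ``beta`` maps (population, sex) -> sex contrast, female entries 0 and
    missing male entries defaulting to ``d_mean``; ``eta`` maps
    (population, sex) -> logit recapture; ``eps_time`` maps
    (population, occasion) -> annual recapture deviation.
    """

    alpha: dict = field(default_factory=dict)
    alpha_common: dict = field(default_factory=dict)
    gamma_mean: float = 0.0
    d_mean: float = 0.0
    sigma_d: float = 0.5
    beta: dict = field(default_factory=dict)
    sigma_pop: float = 0.5
    sigma_ind: float = 0.5
    eps_pop: dict = field(default_factory=dict)
    eps_ind: dict = field(default_factory=dict)
    eta: dict = field(default_factory=dict)
    sigma_p: dict = field(default_factory=dict)
    eps_time: dict = field(default_factory=dict)

    def beta_of(self, population_id: str, sex: str) -> float:
        if sex == "female":
            return float(self.beta.get((population_id, "female"), 0.0))
        return float(self.beta.get((population_id, "male"), self.d_mean))


def survival_predictor(
    params: SurvivalParams,
    variant: ModelVariant | str,
    individual: EncounterHistory,
    interval: int,
    age_class_cap: int = 5,
) -> float:
    """Annual survival probability for one individual over one interval.

    ``interval`` is the occasion index at which the interval starts and must
    lie within the individual's exposure.  Unknown-age individuals use the
    gamma + beta predictor under both variants.
    """
    tag = variant.tag if isinstance(variant, ModelVariant) else _canon_variant(variant)
    k = interval - individual.entry_occasion
    if not (0 <= k < len(individual.detections) - 1):
        raise ValueError("interval outside the individual's exposure")
    shared = (params.eps_pop.get(individual.population_id, 0.0)
              + params.eps_ind.get(individual.individual_id, 0.0))
    if individual.age_at_entry is None:
        lp = params.gamma_mean + params.beta_of(individual.population_id, individual.sex)
    else:
        a = min(individual.age_at_entry + k, age_class_cap)
        if tag == MODEL1:
            key = (a, individual.sex)
            if key not in params.alpha:
                raise KeyError(f"missing alpha for age class {a}, sex {individual.sex}")
            lp = params.alpha[key]
        else:
            if a not in params.alpha_common:
                raise KeyError(f"missing alpha_common for age class {a}")
            lp = params.alpha_common[a] + params.beta_of(individual.population_id,
                                                         individual.sex)
    return float(expit(lp + shared))


def recapture_predictor(
    params: SurvivalParams, individual: EncounterHistory, occasion: int
) -> float:
    """Recapture probability at an occasion after entry."""
    if occasion <= individual.entry_occasion:
        raise ValueError("recapture applies only to occasions after entry")
    lp = (params.eta.get((individual.population_id, individual.sex), 0.0)
          + params.eps_time.get((individual.population_id, occasion), 0.0))
    return float(expit(lp))


def history_loglik(detections: Sequence[int], phi: Sequence[float], p: Sequence[float]) -> float:
    """Exact CJS log-likelihood of one post-entry detection pattern.

    Marginalizes the latent alive/dead sequence with a forward pass over the
    absorbing chain, conditional on the first capture: ``f`` carries the
    probability of the data so far with the bird alive, ``g`` with the bird
    dead.  ``phi[t]`` and ``p[t]`` govern the step to occasion t+1.
    """
    y = np.asarray(detections, dtype=int)
    phi = np.asarray(phi, dtype=float)
    p = np.asarray(p, dtype=float)
    if y[0] != 1:
        raise ValueError("detections must start with 1 (conditioning on first capture)")
    if len(phi) != len(y) - 1 or len(p) != len(y) - 1:
        raise ValueError("need one phi and one p per interval after entry")
    if ((phi < 0) | (phi > 1)).any() or ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    f, g = 1.0, 0.0
    for t in range(len(y) - 1):
        if y[t + 1] == 1:
            f, g = f * phi[t] * p[t], 0.0
        else:
            f, g = f * phi[t] * (1.0 - p[t]), g + f * (1.0 - phi[t])
    total = f + g
    return math.log(total) if total > 0 else -math.inf


# ---------------------------------------------------------------------------

class CJSSurvivalModel:
    """Joint hierarchical CJS model over all populations of a study.

    Parameters are handled as one flat labeled vector; ``logposterior``
    evaluates the exact marginal likelihood (forward algorithm, vectorized
    across individuals) plus the log-priors, and ``fit`` runs a blocked
    adaptive Metropolis-within-Gibbs sampler over it.
    """

    def __init__(
        self,
        dataset: StudyDataset,
        variant: ModelVariant | str = MODEL2,
        age_cap: int | None = None,
        priors: PriorSpec | None = None,
    ):
        self.dataset = dataset
        self.variant = variant.tag if isinstance(variant, ModelVariant) else _canon_variant(variant)
        self.age_cap = age_cap if age_cap is not None else dataset.age_class_cap
        if self.age_cap < 2:
            raise ValueError("age_cap must be >= 2")
        self.priors = priors or PriorSpec()
        self.pop_ids = sorted(dataset.populations)
        self._build_design()
        self._build_layout()

    # -- design matrices ----------------------------------------------------
    def _build_design(self) -> None:
        ds, cap = self.dataset, self.age_cap
        hists = ds.histories
        self.n_ind = len(hists)
        self.individual_ids = [h.individual_id for h in hists]
        pop_index = {p: j for j, p in enumerate(self.pop_ids)}
        self.n_pop = len(self.pop_ids)
        self.K = np.array([ds.populations[p].n_occasions for p in self.pop_ids])
        # eps_time flat layout: per pop, occasions 2..K_j
        self.time_offsets = np.concatenate([[0], np.cumsum(self.K - 1)])[:-1]
        self.n_time = int((self.K - 1).sum())

        M = max((len(h.detections) - 1 for h in hists), default=1)
        M = max(M, 1)
        n = self.n_ind
        self.M = M
        self.ind_pop = np.array([pop_index[h.population_id] for h in hists], dtype=int)
        self.ind_sex = np.array([_SEX_IDX[h.sex] for h in hists], dtype=int)
        self.ind_known = np.array([h.known_age for h in hists], dtype=bool)
        self.det = np.zeros((n, M), dtype=bool)
        self.mask = np.zeros((n, M), dtype=bool)
        self.alpha_idx = np.zeros((n, M), dtype=int)
        self.time_idx = np.zeros((n, M), dtype=int)
        for i, h in enumerate(hists):
            L = len(h.detections) - 1
            if L == 0:
                continue
            self.det[i, :L] = np.asarray(h.detections[1:], dtype=bool)
            self.mask[i, :L] = True
            j = self.ind_pop[i]
            occs = h.entry_occasion + 1 + np.arange(L)  # occasions 2..K with recapture
            self.time_idx[i, :L] = self.time_offsets[j] + occs - 2
            if h.known_age:
                classes = interval_age_classes(h, cap)
                if self.variant == MODEL1:
                    self.alpha_idx[i, :L] = [(a - 1) * 2 + self.ind_sex[i] for a in classes]
                else:
                    self.alpha_idx[i, :L] = [a - 1 for a in classes]
        # multiplier on b[pop] in the survival predictor: males always for the
        # unknown-age submodel; known-age birds only under model 2
        bm = self.ind_sex.astype(float)
        if self.variant == MODEL1:
            bm = np.where(self.ind_known, 0.0, bm)
        self.b_mult = bm
        self.eta_idx = self.ind_pop * 2 + self.ind_sex

    # -- flat parameter layout ----------------------------------------------
    def _build_layout(self) -> None:
        labels: list[str] = []
        slices: dict[str, slice] = {}

        def add(name: str, labs: list[str]) -> None:
            slices[name] = slice(len(labels), len(labels) + len(labs))
            labels.extend(labs)

        ages = range(1, self.age_cap + 1)
        if self.variant == MODEL1:
            add("alpha", [f"alpha[{a},{s}]" for a in ages for s in ("female", "male")])
        else:
            add("alpha", [f"alpha[{a}]" for a in ages])
        add("gamma", ["gamma"])
        add("b", [f"b[{p}]" for p in self.pop_ids])
        add("d", ["d"])
        add("eta", [f"eta[{p},{s}]" for p in self.pop_ids for s in ("female", "male")])
        add("sigma_d", ["sigma_d"])
        add("sigma_pop", ["sigma_pop"])
        add("sigma_ind", ["sigma_ind"])
        add("sigma_p", [f"sigma_p[{p}]" for p in self.pop_ids])
        add("eps_pop", [f"eps_pop[{p}]" for p in self.pop_ids])
        tlabs = []
        for j, p in enumerate(self.pop_ids):
            tlabs += [f"eps_time[{p},{t}]" for t in range(2, self.K[j] + 1)]
        add("eps_time", tlabs)
        add("eps_ind", [f"eps_ind[{i}]" for i in self.individual_ids])
        self.labels = labels
        self.slices = slices
        self.n_params = len(labels)

    # -- likelihood ----------------------------------------------------------
    def loglik_vector(self, x: np.ndarray) -> np.ndarray:
        """Exact marginal CJS log-likelihood per individual (forward pass)."""
        s = self.slices
        alpha = x[s["alpha"]]
        gamma = x[s["gamma"]][0]
        b = x[s["b"]]
        eta = x[s["eta"]]
        eps_pop = x[s["eps_pop"]]
        eps_time = x[s["eps_time"]]
        eps_ind = x[s["eps_ind"]]

        base = np.where(self.ind_known, 0.0, gamma)
        shared = base + self.b_mult * b[self.ind_pop] + eps_pop[self.ind_pop] + eps_ind
        lp_phi = np.where(self.ind_known[:, None], alpha[self.alpha_idx], 0.0) + shared[:, None]
        phi = expit(lp_phi)
        p = expit(eta[self.eta_idx][:, None] + eps_time[self.time_idx])

        f = np.ones(self.n_ind)
        g = np.zeros(self.n_ind)
        for t in range(self.M):
            valid = self.mask[:, t]
            y = self.det[:, t]
            phit = phi[:, t]
            pt = p[:, t]
            f_new = f * phit * np.where(y, pt, 1.0 - pt)
            g_new = np.where(y, 0.0, g + f * (1.0 - phit))
            f = np.where(valid, f_new, f)
            g = np.where(valid, g_new, g)
        with np.errstate(divide="ignore"):
            return np.log(f + g)

    def logprior(self, x: np.ndarray) -> float:
        s, pr = self.slices, self.priors
        sds = np.concatenate([x[s["sigma_d"]], x[s["sigma_pop"]], x[s["sigma_ind"]],
                              x[s["sigma_p"]]])
        if (sds < 0).any() or (sds > pr.sd_upper).any():
            return -math.inf
        sigma_d = x[s["sigma_d"]][0]
        sigma_pop = x[s["sigma_pop"]][0]
        sigma_ind = x[s["sigma_ind"]][0]
        sigma_p = x[s["sigma_p"]]
        d = x[s["d"]][0]
        lp = 0.0
        coefs = np.concatenate([x[s["alpha"]], x[s["gamma"]], x[s["eta"]], [d]])
        lp += _normal_logpdf(coefs, 0.0, pr.coef_prior_sd).sum()
        lp += _normal_logpdf(x[s["b"]], d, sigma_d).sum()
        lp += _normal_logpdf(x[s["eps_pop"]], 0.0, sigma_pop).sum()
        lp += _normal_logpdf(x[s["eps_ind"]], 0.0, sigma_ind).sum()
        et = x[s["eps_time"]]
        for j in range(self.n_pop):
            sl = slice(self.time_offsets[j], self.time_offsets[j] + self.K[j] - 1)
            lp += _normal_logpdf(et[sl], 0.0, sigma_p[j]).sum()
        return float(lp)

    def logposterior(self, x: np.ndarray) -> float:
        lp = self.logprior(x)
        if not np.isfinite(lp):
            return -math.inf
        return float(self.loglik_vector(x).sum()) + lp

    # -- packing the op-level parameter object -------------------------------
    def pack(self, params: SurvivalParams) -> np.ndarray:
        x = np.zeros(self.n_params)
        s = self.slices
        ages = range(1, self.age_cap + 1)
        if self.variant == MODEL1:
            vals = [params.alpha.get((a, sx), 0.0) for a in ages for sx in ("female", "male")]
        else:
            vals = [params.alpha_common.get(a, 0.0) for a in ages]
        x[s["alpha"]] = vals
        x[s["gamma"]] = params.gamma_mean
        x[s["b"]] = [params.beta_of(p, "male") for p in self.pop_ids]
        x[s["d"]] = params.d_mean
        x[s["eta"]] = [params.eta.get((p, sx), 0.0)
                       for p in self.pop_ids for sx in ("female", "male")]
        x[s["sigma_d"]] = params.sigma_d
        x[s["sigma_pop"]] = params.sigma_pop
        x[s["sigma_ind"]] = params.sigma_ind
        x[s["sigma_p"]] = [params.sigma_p.get(p, 0.5) for p in self.pop_ids]
        x[s["eps_pop"]] = [params.eps_pop.get(p, 0.0) for p in self.pop_ids]
        et = np.zeros(self.n_time)
        for j, p in enumerate(self.pop_ids):
            for t in range(2, self.K[j] + 1):
                et[self.time_offsets[j] + t - 2] = params.eps_time.get((p, t), 0.0)
        x[s["eps_time"]] = et
        x[s["eps_ind"]] = [params.eps_ind.get(i, 0.0) for i in self.individual_ids]
        return x

    # -- sampling ------------------------------------------------------------
    def _init_vector(self, rng: np.random.Generator) -> np.ndarray:
        x = np.zeros(self.n_params)
        s = self.slices
        for name in ("alpha", "gamma", "b", "d", "eta"):
            sl = s[name]
            x[sl] = 0.1 * rng.standard_normal(sl.stop - sl.start)
        for name in ("sigma_d", "sigma_pop", "sigma_ind", "sigma_p"):
            sl = s[name]
            x[sl] = rng.uniform(0.1, 1.0, sl.stop - sl.start)
        for name in ("eps_pop", "eps_time", "eps_ind"):
            sl = s[name]
            x[sl] = 0.1 * rng.standard_normal(sl.stop - sl.start)
        return x

    def fit(
        self,
        chains: int = 3,
        iterations: int = 4000,
        burnin: int = 1000,
        thinning: int = 2,
        seed: int = 0,
    ) -> "CJSSurvivalResults":
        """Sample the posterior and return a results object.

        The scan updates, per iteration: the age coefficients jointly (with
        gamma in parallel, their likelihood terms being disjoint), the sex
        contrasts b per population, the recapture means eta per
        population-sex cell, the annual recapture effects per population, the
        population effects, the individual effects (all element-wise with
        per-unit Metropolis acceptance, valid because the likelihood
        factorizes over individuals), then the hyperparameters d (Gibbs) and
        the four SD groups (cheap prior-only Metropolis).
        """
        if iterations <= burnin:
            raise ValueError("iterations must exceed burnin")
        root = np.random.SeedSequence(seed)
        all_draws, all_chain, acc_log = [], [], []
        for c, ss in enumerate(root.spawn(chains)):
            rng = np.random.default_rng(ss)
            kept, acc = self._run_chain(rng, iterations, burnin, thinning)
            all_draws.append(kept)
            all_chain.append(np.full(len(kept), c))
            acc_log.append(acc)
        draws = PosteriorDraws(
            draws=np.concatenate(all_draws),
            labels=list(self.labels),
            chain_id=np.concatenate(all_chain),
            meta={"iterations": iterations, "burnin": burnin, "thinning": thinning,
                  "chains": chains, "seed": seed, "variant": self.variant,
                  "age_cap": self.age_cap, "acceptance": acc_log,
                  "priors": {"coef_prior_sd": self.priors.coef_prior_sd,
                             "sd_upper": self.priors.sd_upper}},
        )
        return CJSSurvivalResults(self, draws)

    def _run_chain(self, rng, iterations, burnin, thinning):
        s = self.slices
        x = self._init_vector(rng)
        llv = self.loglik_vector(x)
        pop_members = [np.flatnonzero(self.ind_pop == j) for j in range(self.n_pop)]
        eta_members = [np.flatnonzero(self.eta_idx == k) for k in range(2 * self.n_pop)]
        known = self.ind_known
        unknown = ~known
        # alpha coordinates grouped by age class; under model 1 the female and
        # male coefficients of an age class touch disjoint individuals and are
        # accepted in parallel within one proposal
        alpha0 = s["alpha"].start
        if self.variant == MODEL1:
            kf = known & (self.ind_sex == 0)
            km = known & (self.ind_sex == 1)
            alpha_groups = [
                [(alpha0 + (a - 1) * 2, kf), (alpha0 + (a - 1) * 2 + 1, km)]
                for a in range(1, self.age_cap + 1)
            ]
        else:
            alpha_groups = [[(alpha0 + a - 1, known)] for a in range(1, self.age_cap + 1)]
        n_alpha = s["alpha"].stop - s["alpha"].start
        ad_alpha = AdaptiveScale(n_alpha, 0.2)
        ad_gamma = AdaptiveScale(1, 0.1)
        ad_b = AdaptiveScale(self.n_pop, 0.1)
        ad_eta = AdaptiveScale(2 * self.n_pop, 0.1)
        ad_time = AdaptiveScale(self.n_pop, 0.2, target=0.234)
        ad_pop = AdaptiveScale(self.n_pop, 0.1)
        ad_ind = AdaptiveScale(self.n_ind, 0.3)
        ad_sd = AdaptiveScale(3 + self.n_pop, 0.2)
        ad_resc_ind = AdaptiveScale(1, 0.3)
        ad_resc_pop = AdaptiveScale(1, 0.3)
        ad_resc_d = AdaptiveScale(1, 0.3)
        ad_resc_time = AdaptiveScale(1, 0.3)
        ad_tr_pop = AdaptiveScale(1, 0.2)
        ad_tr_ind = AdaptiveScale(1, 0.2)
        ad_tr_time = AdaptiveScale(1, 0.2)
        pr = self.priors
        kept = []
        for it in range(iterations):
            # -- age coefficients, one age class at a time (gamma rides along
            #    with the first class; its likelihood terms are disjoint)
            acc_alpha = np.zeros(n_alpha, dtype=bool)
            for g, grp in enumerate(alpha_groups):
                xp = x.copy()
                for coord, _ in grp:
                    xp[coord] += ad_alpha.scale[coord - alpha0] * rng.standard_normal()
                with_gamma = g == 0
                if with_gamma:
                    xp[s["gamma"]] += ad_gamma.scale[0] * rng.standard_normal(1)
                llv_p = self.loglik_vector(xp)
                for coord, mask in grp:
                    dpri = (_normal_logpdf(xp[coord], 0, pr.coef_prior_sd)
                            - _normal_logpdf(x[coord], 0, pr.coef_prior_sd))
                    if np.log(rng.uniform()) < (llv_p[mask].sum() - llv[mask].sum() + dpri):
                        acc_alpha[coord - alpha0] = True
                        x[coord] = xp[coord]
                        llv[mask] = llv_p[mask]
                if with_gamma:
                    dpri = (_normal_logpdf(xp[s["gamma"]], 0, pr.coef_prior_sd).sum()
                            - _normal_logpdf(x[s["gamma"]], 0, pr.coef_prior_sd).sum())
                    acc_g = np.log(rng.uniform()) < (llv_p[unknown].sum()
                                                     - llv[unknown].sum() + dpri)
                    if acc_g:
                        x[s["gamma"]] = xp[s["gamma"]]
                        llv[unknown] = llv_p[unknown]
                    ad_gamma.update(acc_g)
            ad_alpha.update(acc_alpha)

            # -- sex contrasts b[pop], element-wise parallel across populations
            d_now = x[s["d"]][0]
            sigma_d = x[s["sigma_d"]][0]
            self._parallel_update(
                x, llv, rng, s["b"], ad_b, pop_members,
                prior=lambda v: _normal_logpdf(v, d_now, sigma_d))

            # -- recapture means eta, parallel across (pop, sex) cells
            self._parallel_update(
                x, llv, rng, s["eta"], ad_eta, eta_members,
                prior=lambda v: _normal_logpdf(v, 0.0, pr.coef_prior_sd))

            # -- annual recapture effects, joint per population
            sigma_p = x[s["sigma_p"]]
            xp = x.copy()
            et0 = s["eps_time"].start
            step = rng.standard_normal(self.n_time)
            pri_old = np.zeros(self.n_pop)
            pri_new = np.zeros(self.n_pop)
            for j in range(self.n_pop):
                sl = slice(et0 + self.time_offsets[j], et0 + self.time_offsets[j] + self.K[j] - 1)
                xp[sl] = x[sl] + ad_time.scale[j] * step[self.time_offsets[j]:
                                                         self.time_offsets[j] + self.K[j] - 1]
                pri_old[j] = _normal_logpdf(x[sl], 0, sigma_p[j]).sum()
                pri_new[j] = _normal_logpdf(xp[sl], 0, sigma_p[j]).sum()
            llv_p = self.loglik_vector(xp)
            logu = np.log(rng.uniform(size=self.n_pop))
            acc_t = np.zeros(self.n_pop, dtype=bool)
            for j in range(self.n_pop):
                mem = pop_members[j]
                if logu[j] < (llv_p[mem].sum() - llv[mem].sum() + pri_new[j] - pri_old[j]):
                    acc_t[j] = True
                    sl = slice(et0 + self.time_offsets[j],
                               et0 + self.time_offsets[j] + self.K[j] - 1)
                    x[sl] = xp[sl]
                    llv[mem] = llv_p[mem]
            ad_time.update(acc_t)

            # -- population effects, element-wise parallel
            sigma_pop = x[s["sigma_pop"]][0]
            self._parallel_update(
                x, llv, rng, s["eps_pop"], ad_pop, pop_members,
                prior=lambda v: _normal_logpdf(v, 0.0, sigma_pop))

            # -- individual effects, element-wise parallel
            sigma_ind = x[s["sigma_ind"]][0]
            sl = s["eps_ind"]
            xp = x.copy()
            xp[sl] = x[sl] + ad_ind.scale * rng.standard_normal(self.n_ind)
            llv_p = self.loglik_vector(xp)
            dpri = (_normal_logpdf(xp[sl], 0, sigma_ind) - _normal_logpdf(x[sl], 0, sigma_ind))
            acc_i = np.log(rng.uniform(size=self.n_ind)) < (llv_p - llv + dpri)
            xs = x[sl]
            xs[acc_i] = xp[sl][acc_i]
            x[sl] = xs
            llv[acc_i] = llv_p[acc_i]
            ad_ind.update(acc_i)

            # -- joint (SD, effects) rescaling moves: sigma' = sigma*exp(delta)
            #    with the effects scaled by the same factor.  The effects-prior
            #    change and the transformation Jacobian cancel up to +delta,
            #    so the acceptance ratio is Delta-loglik + delta (uniform SD
            #    prior, support permitting).  These break the slow coupling
            #    between each SD and its shrunken effects.
            self._rescale_move(x, llv, rng, "sigma_ind", s["eps_ind"], 0.0, ad_resc_ind)
            self._rescale_move(x, llv, rng, "sigma_pop", s["eps_pop"], 0.0, ad_resc_pop)
            self._rescale_move(x, llv, rng, "sigma_d", s["b"], x[s["d"]][0], ad_resc_d)
            # eps_time rescales are population-specific (independent sigmas)
            delta = ad_resc_time.scale[0] * rng.standard_normal(self.n_pop)
            xp = x.copy()
            et0 = s["eps_time"].start
            sp = x[s["sigma_p"]]
            ok = (sp * np.exp(delta) <= pr.sd_upper)
            for j in range(self.n_pop):
                if ok[j]:
                    sl = slice(et0 + self.time_offsets[j],
                               et0 + self.time_offsets[j] + self.K[j] - 1)
                    xp[sl] = x[sl] * np.exp(delta[j])
            llv_p = self.loglik_vector(xp)
            logu = np.log(rng.uniform(size=self.n_pop))
            acc_r = np.zeros(self.n_pop, dtype=bool)
            spn = sp.copy()
            for j in range(self.n_pop):
                mem = pop_members[j]
                if ok[j] and logu[j] < (llv_p[mem].sum() - llv[mem].sum() + delta[j]):
                    acc_r[j] = True
                    spn[j] = sp[j] * np.exp(delta[j])
                    sl = slice(et0 + self.time_offsets[j],
                               et0 + self.time_offsets[j] + self.K[j] - 1)
                    x[sl] = xp[sl]
                    llv[mem] = llv_p[mem]
            x[s["sigma_p"]] = spn
            ad_resc_time.update(acc_r.mean() if self.n_pop else 0.0)

            # -- prior-only translation moves along the intercept/effects
            #    ridges (likelihood-invariant shifts; only priors decide)
            # eps_pop + delta, alpha and gamma - delta
            for eff_name, ad_t in (("eps_pop", ad_tr_pop), ("eps_ind", ad_tr_ind)):
                delta = ad_t.scale[0] * rng.standard_normal()
                sd_now = x[s["sigma_pop" if eff_name == "eps_pop" else "sigma_ind"]][0]
                eff = x[s[eff_name]]
                coefs = np.concatenate([x[s["alpha"]], x[s["gamma"]]])
                dlp = (_normal_logpdf(eff + delta, 0, sd_now).sum()
                       - _normal_logpdf(eff, 0, sd_now).sum()
                       + _normal_logpdf(coefs - delta, 0, pr.coef_prior_sd).sum()
                       - _normal_logpdf(coefs, 0, pr.coef_prior_sd).sum())
                if np.log(rng.uniform()) < dlp:
                    x[s[eff_name]] = eff + delta
                    x[s["alpha"]] = x[s["alpha"]] - delta
                    x[s["gamma"]] = x[s["gamma"]] - delta
                    ad_t.update(True)
                else:
                    ad_t.update(False)
            # eps_time[j] + delta_j, both sexes' eta[j] - delta_j (per pop)
            delta = ad_tr_time.scale[0] * rng.standard_normal(self.n_pop)
            sp_now = x[s["sigma_p"]]
            acc_tt = np.zeros(self.n_pop, dtype=bool)
            for j in range(self.n_pop):
                sl = slice(et0 + self.time_offsets[j],
                           et0 + self.time_offsets[j] + self.K[j] - 1)
                eta_j = slice(s["eta"].start + 2 * j, s["eta"].start + 2 * j + 2)
                dlp = (_normal_logpdf(x[sl] + delta[j], 0, sp_now[j]).sum()
                       - _normal_logpdf(x[sl], 0, sp_now[j]).sum()
                       + _normal_logpdf(x[eta_j] - delta[j], 0, pr.coef_prior_sd).sum()
                       - _normal_logpdf(x[eta_j], 0, pr.coef_prior_sd).sum())
                if np.log(rng.uniform()) < dlp:
                    x[sl] = x[sl] + delta[j]
                    x[eta_j] = x[eta_j] - delta[j]
                    acc_tt[j] = True
            ad_tr_time.update(acc_tt.mean() if self.n_pop else 0.0)

            # -- hyperparameters: d by Gibbs, SDs by cheap Metropolis
            sigma_d = x[s["sigma_d"]][0]
            b = x[s["b"]]
            prec = len(b) / sigma_d**2 + 1.0 / pr.coef_prior_sd**2
            mean = (b.sum() / sigma_d**2) / prec
            x[s["d"]] = mean + rng.standard_normal() / math.sqrt(prec)

            self._update_sds(x, rng, ad_sd)

            if it >= burnin and (it - burnin) % thinning == 0:
                kept.append(x.copy())
        acc = {"alpha": float(ad_alpha.scale[0]), "eps_ind_mean_scale": float(ad_ind.scale.mean())}
        return np.asarray(kept), acc

    def _rescale_move(self, x, llv, rng, sd_name, eff_slice, center, adapt):
        """Joint log-scale move of one SD and its (centered) random effects."""
        s, pr = self.slices, self.priors
        delta = adapt.scale[0] * rng.standard_normal()
        cur = x[s[sd_name]][0]
        prop_sd = cur * math.exp(delta)
        if not (0 < prop_sd <= pr.sd_upper):
            adapt.update(False)
            return
        xp = x.copy()
        xp[s[sd_name]] = prop_sd
        xp[eff_slice] = center + (x[eff_slice] - center) * math.exp(delta)
        llv_p = self.loglik_vector(xp)
        if np.log(rng.uniform()) < (llv_p.sum() - llv.sum() + delta):
            x[s[sd_name]] = prop_sd
            x[eff_slice] = xp[eff_slice]
            llv[:] = llv_p
            adapt.update(True)
        else:
            adapt.update(False)

    def _parallel_update(self, x, llv, rng, sl, adapt, members, prior):
        """Element-wise Metropolis over disjoint likelihood groups."""
        n = sl.stop - sl.start
        xp = x.copy()
        xp[sl] = x[sl] + adapt.scale * rng.standard_normal(n)
        llv_p = self.loglik_vector(xp)
        dpri = prior(xp[sl]) - prior(x[sl])
        logu = np.log(rng.uniform(size=n))
        acc = np.zeros(n, dtype=bool)
        for k in range(n):
            mem = members[k]
            if logu[k] < (llv_p[mem].sum() - llv[mem].sum() + dpri[k]):
                acc[k] = True
                llv[mem] = llv_p[mem]
        xs = x[sl]
        xs[acc] = xp[sl][acc]
        x[sl] = xs
        adapt.update(acc)

    def _update_sds(self, x, rng, ad_sd):
        """Metropolis on the SD hyperparameters; only prior terms involved."""
        s, pr = self.slices, self.priors
        et = x[s["eps_time"]]
        groups = [("sigma_d", x[s["b"]], x[s["d"]][0]),
                  ("sigma_pop", x[s["eps_pop"]], 0.0),
                  ("sigma_ind", x[s["eps_ind"]], 0.0)]
        acc = np.zeros(3 + self.n_pop, dtype=bool)
        for k, (name, eff, mu) in enumerate(groups):
            cur = x[s[name]][0]
            prop = cur + ad_sd.scale[k] * rng.standard_normal()
            if 0 < prop <= pr.sd_upper:
                delta = (_normal_logpdf(eff, mu, prop).sum()
                         - _normal_logpdf(eff, mu, cur).sum())
                if np.log(rng.uniform()) < delta:
                    x[s[name]] = prop
                    acc[k] = True
        sp = x[s["sigma_p"]].copy()
        for j in range(self.n_pop):
            sl_j = slice(self.time_offsets[j], self.time_offsets[j] + self.K[j] - 1)
            cur = sp[j]
            prop = cur + ad_sd.scale[3 + j] * rng.standard_normal()
            if 0 < prop <= pr.sd_upper:
                delta = (_normal_logpdf(et[sl_j], 0, prop).sum()
                         - _normal_logpdf(et[sl_j], 0, cur).sum())
                if np.log(rng.uniform()) < delta:
                    sp[j] = prop
                    acc[3 + j] = True
        x[s["sigma_p"]] = sp
        ad_sd.update(acc)


class CJSSurvivalResults:
    """Posterior draws from a fitted CJS survival model plus summaries."""

    def __init__(self, model: CJSSurvivalModel, draws: PosteriorDraws):
        self.model = model
        self.draws = draws

    @property
    def variant(self) -> str:
        return self.model.variant

    def rhat(self):
        return gelman_rubin(self.draws)

    @property
    def converged(self) -> bool:
        return bool((self.rhat() < 1.1).all())

    def summary(self, include_random_effects: bool = False):
        """Posterior summary table (fixed effects and SDs by default)."""
        tab = summarize_draws(self.draws)
        if not include_random_effects:
            keep = [l for l in self.draws.labels
                    if not (l.startswith("eps_") or l.startswith("b["))]
            tab = tab.loc[keep]
        return tab

    def sex_effect(self) -> dict:
        """Posterior of d, the mean male-female logit survival difference."""
        d = self.draws.get("d")
        return {"mean": float(d.mean()),
                "cri": (float(np.percentile(d, 2.5)), float(np.percentile(d, 97.5))),
                "p_positive": float((d > 0).mean() + 0.5 * (d == 0).mean())}

    def recapture_means(self) -> dict:
        """Average recapture probability by sex (posterior mean of expit(eta),
        averaged over populations), plus the per-population range."""
        out = {}
        for sx in ("female", "male"):
            per_pop = np.column_stack(
                [expit(self.draws.get(f"eta[{p},{sx}]")) for p in self.model.pop_ids])
            pop_means = per_pop.mean(axis=0)
            out[sx] = {"mean": float(pop_means.mean()),
                       "range": (float(pop_means.min()), float(pop_means.max()))}
        return out

    def age_trajectory(self, sex: str = "both", scale: str = "probability",
                       reference: str | None = None, n_draws: int | None = None):
        from .slopes import age_trajectory
        return age_trajectory(self, which="survival", sex=sex, scale=scale,
                              reference=reference, n_draws=n_draws)

    def slope_summary(self, sex: str = "both", scale: str = "probability",
                      reference: str | None = None, n_draws: int | None = 12000):
        from .slopes import age_trajectory, slope_distribution
        traj = age_trajectory(self, which="survival", sex=sex, scale=scale,
                              reference=reference, n_draws=n_draws)
        ages = np.arange(1, self.model.age_cap + 1)
        return slope_distribution(traj, ages, scale=scale)


def survival_logposterior(
    params: SurvivalParams,
    variant: ModelVariant | str,
    dataset: StudyDataset,
    priors: PriorSpec | None = None,
    age_cap: int | None = None,
) -> float:
    """Log-posterior of named parameter values for a dataset (op-level API)."""
    model = CJSSurvivalModel(dataset, variant=variant, age_cap=age_cap, priors=priors)
    return model.logposterior(model.pack(params))


_LOG_SQRT_2PI = 0.5 * math.log(2 * math.pi)


def _normal_logpdf(x, mu, sd):
    x = np.asarray(x, dtype=float)
    if np.ndim(sd) == 0 and sd <= 0:
        return np.where(x == mu, np.inf, -np.inf)
    return -_LOG_SQRT_2PI - np.log(sd) - 0.5 * ((x - mu) / sd) ** 2
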