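"""CJS likelihood exactness, predictors, priors and the fixed-effect reduction."""

import itertools
import math

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import expit, logit

from cjsage.data import EncounterHistory, Population, StudyDataset
from cjsage.mcmc import PriorSpec
from cjsage.survival import (
    CJSSurvivalModel,
    ModelVariant,
    SurvivalParams,
    history_loglik,
    recapture_predictor,
    survival_logposterior,
    survival_predictor,
    _normal_logpdf,
)

from conftest import brute_force_cjs_loglik


def _hist(entry=1, age=2, det=(1, 0, 1), pop="p", sex="female", iid="x"):
    return EncounterHistory(iid, pop, sex, entry, age, tuple(det))


class TestPredictors:
    def test_all_effects_zero_gives_half(self):
        p = SurvivalParams(alpha_common={a: 0.0 for a in range(1, 6)})
        assert survival_predictor(p, "model2", _hist(), 1) == pytest.approx(0.5)

    def test_known_age_model1_closed_form(self):
        p = SurvivalParams(alpha={(2, "male"): 1.0})
        h = _hist(sex="male")
        assert survival_predictor(p, "model1", h, 1) == pytest.approx(expit(1.0))

    def test_unknown_age_female_sums_terms(self):
        p = SurvivalParams(gamma_mean=0.2, eps_pop={"p": -0.1}, eps_ind={"x": 0.3})
        h = _hist(age=None)
        assert survival_predictor(p, "model1", h, 1) == pytest.approx(expit(0.4))
        # unknown-age birds use the gamma predictor under both variants
        assert survival_predictor(p, "model2", h, 1) == pytest.approx(expit(0.4))

    def test_aging_across_intervals_uses_current_age(self):
        p = SurvivalParams(alpha_common={2: 0.0, 3: 1.0, 4: 2.0})
        h = _hist(entry=1, age=2, det=(1, 0, 1, 0))
        assert survival_predictor(p, "model2", h, 2) == pytest.approx(expit(1.0))

    def test_missing_age_class_raises(self):
        p = SurvivalParams(alpha={(1, "female"): 0.0})
        with pytest.raises(KeyError):
            survival_predictor(p, "model1", _hist(age=4), 1)

    def test_interval_outside_exposure(self):
        p = SurvivalParams(alpha_common={2: 0.0})
        with pytest.raises(ValueError):
            survival_predictor(p, "model2", _hist(), 3)

    @pytest.mark.parametrize("pbar", [0.5, 0.66, 0.49])
    def test_recapture_predictor(self, pbar):
        p = SurvivalParams(eta={("p", "male"): logit(pbar)})
        h = _hist(sex="male")
        assert recapture_predictor(p, h, 2) == pytest.approx(pbar)

    def test_recapture_needs_occasion_after_entry(self):
        with pytest.raises(ValueError):
            recapture_predictor(SurvivalParams(), _hist(), 1)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            ModelVariant("model3")


class TestHistoryLoglik:
    def test_seen_again(self):
        assert history_loglik([1, 1], [0.5], [0.5]) == pytest.approx(math.log(0.25))

    def test_never_seen_again(self):
        # (1-phi) + phi(1-p)((1-phi) + phi(1-p)) = 0.6875
        assert history_loglik([1, 0, 0], [0.5, 0.5], [0.5, 0.5]) == pytest.approx(
            math.log(0.6875))

    def test_certainty(self):
        assert history_loglik([1, 1, 1], [1, 1], [1, 1]) == 0.0

    def test_entry_at_final_occasion(self):
        assert history_loglik([1], [], []) == 0.0

    def test_rejects_bad_probability(self):
        with pytest.raises(ValueError):
            history_loglik([1, 1], [1.5], [0.5])

    def test_matches_enumeration_and_conserves_mass(self):
        """Forward marginalization equals brute-force enumeration for every
        pattern up to length 6, and pattern probabilities sum to one."""
        rng = np.random.default_rng(42)
        for _ in range(25):
            for L in range(2, 7):
                phi = rng.uniform(0.05, 0.95, L - 1)
                p = rng.uniform(0.05, 0.95, L - 1)
                total = 0.0
                for tail in itertools.product([0, 1], repeat=L - 1):
                    y = (1,) + tail
                    ll = history_loglik(y, phi, p)
                    oracle = brute_force_cjs_loglik(y, phi, p)
                    assert ll == pytest.approx(oracle, abs=1e-12)
                    total += math.exp(ll)
                assert total == pytest.approx(1.0, abs=1e-12)

    def test_monotone_in_phi_for_all_ones(self):
        base = history_loglik([1, 1, 1], [0.4, 0.6], [0.5, 0.5])
        higher = history_loglik([1, 1, 1], [0.5, 0.6], [0.5, 0.5])
        assert higher > base


class TestLogPosterior:
    POPS = {"p": Population("p", 2000, 2001)}

    def _ds(self, n=1):
        hists = [EncounterHistory(f"x{i}", "p", "female", 1, 1, (1, 1))
                 for i in range(n)]
        return StudyDataset(populations=self.POPS, histories=hists)

    def _zero_params(self):
        return SurvivalParams(alpha_common={a: 0.0 for a in range(1, 6)},
                              sigma_d=0.5, sigma_pop=0.5, sigma_ind=0.5,
                              sigma_p={"p": 0.5})

    def test_hand_summed_single_history(self):
        """Data term log(0.25) plus the Normal/uniform prior terms."""
        ds = self._ds(1)
        priors = PriorSpec(coef_prior_sd=10.0, sd_upper=5.0)
        got = survival_logposterior(self._zero_params(), "model2", ds, priors)
        coefs = np.zeros(5 + 1 + 2 + 1)  # alpha(5), gamma, eta(2), d
        expected = math.log(0.25)
        expected += _normal_logpdf(coefs, 0, 10.0).sum()
        expected += _normal_logpdf(0.0, 0.0, 0.5)  # b[p] ~ N(d=0, sigma_d)
        expected += _normal_logpdf(0.0, 0.0, 0.5)  # eps_pop
        expected += _normal_logpdf(0.0, 0.0, 0.5)  # eps_ind
        expected += _normal_logpdf(0.0, 0.0, 0.5)  # eps_time[p,2]
        assert got == pytest.approx(expected, rel=1e-12)

    def test_negative_sd_is_minus_inf(self):
        params = self._zero_params()
        params.sigma_pop = -0.1
        assert survival_logposterior(params, "model2", self._ds(1)) == -math.inf

    def test_doubling_dataset_doubles_data_term(self):
        priors = PriorSpec()
        lp1 = survival_logposterior(self._zero_params(), "model2", self._ds(1), priors)
        lp2 = survival_logposterior(self._zero_params(), "model2", self._ds(2), priors)
        # the extra history adds log(0.25) plus one more eps_ind prior term
        assert lp2 - lp1 == pytest.approx(math.log(0.25) + _normal_logpdf(0, 0, 0.5))

    def test_m_array_equivalence(self):
        """With constant phi and p, the product of history likelihoods equals
        the multinomial m-array likelihood up to the multinomial constant."""
        from cjsage.data import build_m_array
        from cjsage.simulate import SimulationConfig, PopulationConfig, simulate_study

        cfg = SimulationConfig(
            populations=[PopulationConfig("p", 6, 40, 15, first_year=2000)],
            seed=9, sigma_pop=1e-9, sigma_ind=1e-9, sigma_d=1e-9, sigma_p=1e-9,
            eta_pop_sd=0.0,
            survival_female=(0.5, 0.5, 0.5, 0.5, 0.5), d=0.0,
            p_female=0.6, p_male=0.6)
        ds, _ = simulate_study(cfg)
        phi_c, p_c = 0.45, 0.55
        ll_hist = sum(
            history_loglik(h.detections,
                           [phi_c] * (len(h.detections) - 1),
                           [p_c] * (len(h.detections) - 1))
            for h in ds.histories)
        ma = build_m_array(ds, "p")
        K = ma.m.shape[0]
        ll_m = 0.0
        for r in range(K):
            for c in range(r + 1, K):
                # released at r+1, first seen again at c+1
                pr = p_c * phi_c
                for _ in range(c - r - 1):
                    pr *= phi_c * (1 - p_c)
                ll_m += ma.m[r, c] * math.log(pr)
            if ma.never_seen[r]:
                ll_m += ma.never_seen[r] * math.log(_chi(r + 1, K, phi_c, p_c))
        assert ll_hist == pytest.approx(ll_m, rel=1e-9)

    def test_fixed_effect_reduction_matches_direct_optimizer(self):
        """With no random effects and one population, the model-2 posterior
        mode under flat-ish priors equals a directly optimized CJS fit."""
        from cjsage.simulate import SimulationConfig, PopulationConfig, simulate_study

        cfg = SimulationConfig(
            populations=[PopulationConfig("p", 8, 250, 80, first_year=2000)],
            seed=21, sigma_pop=1e-9, sigma_ind=1e-9, sigma_d=1e-9, sigma_p=1e-9,
            eta_pop_sd=0.0, juvenile_return_prob=0.3)
        ds, _ = simulate_study(cfg)
        model = CJSSurvivalModel(ds, variant="model2",
                                 priors=PriorSpec(coef_prior_sd=1e4))
        s = model.slices
        free = np.r_[np.arange(s["alpha"].start, s["alpha"].stop),
                     s["gamma"].start, s["b"].start,
                     np.arange(s["eta"].start, s["eta"].stop)]

        def nll(v):
            x = np.zeros(model.n_params)
            x[free] = v
            return -model.loglik_vector(x).sum()

        r1 = minimize(nll, np.zeros(len(free)), method="BFGS")

        # independent fit: enumerate per-history likelihood directly
        def nll_direct(v):
            alpha = {a: v[a - 1] for a in range(1, 6)}
            gamma, b, eta_f, eta_m = v[5], v[6], v[7], v[8]
            tot = 0.0
            for h in ds.histories:
                L = len(h.detections) - 1
                if L == 0:
                    continue
                if h.age_at_entry is None:
                    lp = gamma + (b if h.sex == "male" else 0.0)
                    phi = [expit(lp)] * L
                else:
                    from cjsage.data import interval_age_classes
                    phi = [expit(alpha[a] + (b if h.sex == "male" else 0.0))
                           for a in interval_age_classes(h, 5)]
                p = [expit(eta_m if h.sex == "male" else eta_f)] * L
                tot += brute_force_cjs_loglik(h.detections, phi, p)
            return -tot

        r2 = minimize(nll_direct, np.zeros(9), method="BFGS")
        # compare on the probability scale where both are identified
        assert np.allclose(expit(r1.x), expit(r2.x), atol=1e-4)


def _chi(release_occ, K, phi, p):
    """Probability of never being reencountered after release at release_occ."""
    chi = 1.0
    for _ in range(K - release_occ):
        chi = (1 - phi) + phi * (1 - p) * chi
    return chi
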