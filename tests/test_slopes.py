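"""Per-draw slope regression: closed form, summaries, and trajectories."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.special import expit, logit

from cjsage.slopes import SlopeSummary, slope_distribution

AGES = np.arange(1, 6)


class TestSlopeDistribution:
    def test_matches_closed_form_on_random_inputs(self):
        rng = np.random.default_rng(8)
        traj = rng.uniform(0, 1, size=(300, 5))
        got = slope_distribution(traj, AGES)
        x = AGES - AGES.mean()
        for i in range(0, 300, 37):
            y = traj[i]
            expected = ((x * (y - y.mean())).sum()) / (x * x).sum()
            assert got.slope_draws[i] == pytest.approx(expected, abs=1e-12)

    def test_exactly_linear_trajectories(self):
        traj = np.tile([0.5, 0.45, 0.4, 0.35, 0.3], (200, 1))
        s = slope_distribution(traj, AGES)
        assert s.mean == pytest.approx(-0.05, abs=1e-12)
        assert s.cri_low == pytest.approx(-0.05, abs=1e-12)
        assert s.cri_high == pytest.approx(-0.05, abs=1e-12)
        assert s.p_negative == 1.0

    def test_constant_trajectories_split_ties(self):
        s = slope_distribution(np.full((150, 5), 0.6), AGES)
        assert s.mean == pytest.approx(0.0, abs=1e-15)
        assert s.p_negative == 0.5

    def test_symmetric_slopes_give_half(self):
        up = np.outer(np.ones(100), 0.1 * AGES)
        down = np.outer(np.ones(100), -0.1 * AGES)
        s = slope_distribution(np.vstack([up, down]) + 0.5, AGES)
        assert s.p_negative == 0.5

    def test_location_equivariance(self):
        rng = np.random.default_rng(9)
        traj = rng.uniform(0.2, 0.8, size=(120, 5))
        s1 = slope_distribution(traj, AGES)
        s2 = slope_distribution(traj + 0.17, AGES)
        assert np.allclose(s1.slope_draws, s2.slope_draws, atol=1e-12)

    @settings(max_examples=50, derandomize=True)
    @given(arrays(np.float64, (7, 5), elements=st.floats(0.0, 1.0)),
           st.floats(-0.5, 0.5))
    def test_closed_form_and_equivariance_property(self, traj, shift):
        """OLS slope equals the closed form for arbitrary trajectories and is
        invariant to adding a constant to every rate."""
        import warnings

        x = AGES - AGES.mean()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s1 = slope_distribution(traj, AGES)
            s2 = slope_distribution(traj + shift, AGES)
        for i in range(traj.shape[0]):
            y = traj[i]
            expected = (x * (y - y.mean())).sum() / (x * x).sum()
            assert abs(s1.slope_draws[i] - expected) < 1e-12
            assert abs(s2.slope_draws[i] - s1.slope_draws[i]) < 1e-9

    def test_needs_two_ages(self):
        with pytest.raises(ValueError):
            slope_distribution(np.ones((200, 1)), [1])

    def test_few_draws_warns(self):
        with pytest.warns(UserWarning, match="fewer than 100"):
            slope_distribution(np.ones((5, 5)) * 0.5, AGES)


class TestTrajectories:
    def _fake_survival_results(self, alpha_by_draw, d=None, variant="common_age_sex_intercept"):
        """Results stand-in built from explicit draw matrices."""
        from cjsage.mcmc import PosteriorDraws

        class _M:
            pass

        n, A = alpha_by_draw.shape
        labels, cols = [], []
        if variant == "common_age_sex_intercept":
            for a in range(1, A + 1):
                labels.append(f"alpha[{a}]")
                cols.append(alpha_by_draw[:, a - 1])
            labels.append("d")
            cols.append(np.zeros(n) if d is None else d)
        m = _M()
        m.variant = variant
        m.age_cap = A
        m.pop_ids = ["p"]

        class _R:
            pass

        r = _R()
        r.model = m
        r.draws = PosteriorDraws(np.column_stack(cols), labels, np.zeros(n))
        return r

    def test_constant_alpha_gives_constant_half(self):
        from cjsage.slopes import age_trajectory

        r = self._fake_survival_results(np.zeros((120, 5)))
        traj = age_trajectory(r, which="survival", sex="female", scale="probability")
        assert np.allclose(traj, 0.5)

    def test_logit_scale_is_identity_on_alpha(self):
        from cjsage.slopes import age_trajectory

        r = self._fake_survival_results(np.tile([0.0, -0.5], (120, 1)))
        traj = age_trajectory(r, which="survival", sex="female", scale="logit")
        assert np.allclose(traj, [0.0, -0.5])

    def test_probability_scale_inverse_logit(self):
        from cjsage.slopes import age_trajectory

        probs = np.array([0.5, 0.45, 0.40, 0.35, 0.30])
        r = self._fake_survival_results(np.tile(logit(probs), (150, 1)))
        traj = age_trajectory(r, which="survival", sex="female", scale="probability")
        assert np.allclose(traj, probs, atol=1e-12)

    def test_both_averages_sexes_on_probability_scale(self):
        from cjsage.slopes import age_trajectory

        alpha = np.tile(logit([0.5, 0.4]), (150, 1))
        d = np.full(150, 0.8)
        r = self._fake_survival_results(alpha, d=d)
        traj = age_trajectory(r, which="survival", sex="both", scale="probability")
        expected = 0.5 * (np.array([0.5, 0.4]) + expit(logit([0.5, 0.4]) + 0.8))
        assert np.allclose(traj[0], expected, atol=1e-12)

    def test_named_reference_population_shifts_intercept(self):
        """A named population's trajectory is the average one shifted by that
        population's random effect (and its own sex contrast for males)."""
        from cjsage.mcmc import PosteriorDraws
        from cjsage.slopes import age_trajectory

        n, A = 150, 3
        alpha = np.tile(logit([0.5, 0.45, 0.4]), (n, 1))
        labels = [f"alpha[{a}]" for a in range(1, A + 1)] + ["d", "eps_pop[p]", "b[p]"]
        cols = np.column_stack([alpha, np.full(n, 0.3), np.full(n, -0.4),
                                np.full(n, 0.7)])

        class _M:
            variant = "common_age_sex_intercept"
            age_cap = A
            pop_ids = ["p"]

        class _R:
            model = _M()
            draws = PosteriorDraws(cols, labels, np.zeros(n))

        ref_f = age_trajectory(_R(), sex="female", scale="logit", reference="p")
        assert np.allclose(ref_f[0], logit([0.5, 0.45, 0.4]) - 0.4, atol=1e-12)
        ref_m = age_trajectory(_R(), sex="male", scale="logit", reference="p")
        # males add the named population's own contrast b, not the mean d
        assert np.allclose(ref_m[0], logit([0.5, 0.45, 0.4]) + 0.7 - 0.4, atol=1e-12)
        with pytest.raises(KeyError):
            age_trajectory(_R(), sex="female", reference="elsewhere")

    def test_sex_specific_requires_stratified_breeding(self):
        from cjsage.mcmc import PosteriorDraws
        from cjsage.slopes import age_trajectory

        class _M:
            stratify = False
            age_cap = 5

        class _R:
            model = _M()
            draws = PosteriorDraws(np.zeros((10, 5)),
                                   [f"alpha_bs[{a}]" for a in range(1, 6)],
                                   np.zeros(10))

        with pytest.raises(ValueError, match="stratified"):
            age_trajectory(_R(), which="breeding", sex="male")
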