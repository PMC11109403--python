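"""Therapy-perturbed dynamics: LQ kills, IT closed forms, courses, synergy."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from tumorgl import (
    GompertzParams,
    ImmunotherapyProfile,
    RadiationSchedule,
    SynergyParams,
    TherapyCourse,
    abscopal_trajectory,
    combined_log_effect,
    course_log_size,
    gompertz_size,
    integrate_growth,
    it_trajectory,
    lqm_survival,
    regression_condition,
)

from conftest import random_gompertz


class TestLQM:
    def test_zero_dose_no_kill(self):
        assert lqm_survival(0.0, 0.3, 0.03) == 1.0

    def test_eight_gy(self):
        # exp(-(0.3*8 + 0.03*64)) = exp(-4.32)
        assert lqm_survival(8.0, 0.3, 0.03) == pytest.approx(0.0133, rel=2e-3)

    def test_beta_tenth_alpha_convention(self):
        assert lqm_survival(8.0, 0.3, 0.3 / 10) == lqm_survival(8.0, 0.3, 0.03)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            lqm_survival(-1.0, 0.3, 0.03)

    def test_survival_in_unit_interval(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            s = lqm_survival(rng.uniform(0, 20), rng.uniform(0, 1), rng.uniform(0, 0.1))
            assert 0.0 < s <= 1.0


class TestItTrajectory:
    def test_gamma_zero_is_untreated(self):
        gp = GompertzParams(a=0.08, k=0.02, N0=20.0)
        it = ImmunotherapyProfile(gamma=0.0, I0=3.0, rho=0.1)
        t = np.linspace(0.0, 60.0, 20)
        np.testing.assert_allclose(it_trajectory(gp, it, t), gompertz_size(gp, t), rtol=1e-12)

    def test_constant_mode_shifts_carrying_capacity(self):
        # gamma*I0/k = 2 -> asymptote Ninf * e^-2
        gp = GompertzParams(a=0.1, k=0.01, N0=50.0)
        it = ImmunotherapyProfile(gamma=0.02, I0=1.0, rho=0.0)
        asymptote = it_trajectory(gp, it, 5000.0)
        assert asymptote == pytest.approx(gp.carrying_capacity * math.exp(-2.0), rel=1e-8)

    def test_fast_decay_recovers_untreated(self):
        gp = GompertzParams(a=0.1, k=0.02, N0=50.0)
        it = ImmunotherapyProfile(gamma=0.05, I0=1.0, rho=1e3)
        t = np.linspace(0.1, 60.0, 30)
        assert np.max(np.abs(it_trajectory(gp, it, t) / gompertz_size(gp, t) - 1.0)) <= 1e-4

    def test_exponential_mode_matches_ode(self):
        gp = GompertzParams(a=0.1, k=0.03, N0=50.0)
        it = ImmunotherapyProfile(gamma=0.04, I0=1.0, rho=0.08)
        grid = np.linspace(0.0, 80.0, 33)
        oracle = integrate_growth(gp, lambda t: -it.gamma * it.level(t), None, grid)
        np.testing.assert_allclose(it_trajectory(gp, it, grid), oracle.sizes, rtol=1e-8)

    def test_equal_rates_limit_branch(self):
        gp = GompertzParams(a=0.1, k=0.05, N0=50.0)
        it = ImmunotherapyProfile(gamma=0.04, I0=1.0, rho=0.05)
        grid = np.linspace(0.0, 60.0, 25)
        oracle = integrate_growth(gp, lambda t: -it.gamma * it.level(t), None, grid)
        np.testing.assert_allclose(it_trajectory(gp, it, grid), oracle.sizes, rtol=1e-8)

    @pytest.mark.parametrize("gamma,cmp", [(-0.02, np.greater_equal), (0.02, np.less_equal)])
    def test_sign_semantics_agonist_antagonist(self, gamma, cmp):
        gp = GompertzParams(a=0.08, k=0.02, N0=20.0)
        it = ImmunotherapyProfile(gamma=gamma, I0=1.0, rho=0.0)
        t = np.linspace(0.5, 60.0, 30)
        assert np.all(cmp(it_trajectory(gp, it, t), gompertz_size(gp, t)))

    def test_w_bar_matches_quadrature(self):
        from tumorgl.therapy import _w_bar

        rng = np.random.default_rng(3)
        for _ in range(20):
            k = rng.uniform(0.0, 0.2)
            gamma, i0, rho = rng.uniform(-0.05, 0.05), rng.uniform(0, 3), rng.uniform(0, 0.3)
            it = ImmunotherapyProfile(gamma=gamma, I0=i0, rho=rho)
            t = rng.uniform(1.0, 60.0)
            num, _ = quad(lambda s: gamma * math.exp(-k * (t - s)) * it.level(s), 0.0, t)
            assert _w_bar(it, k, t) == pytest.approx(num, abs=1e-8)


class TestCombinedLogEffect:
    def test_no_therapy_reduces_to_gompertz(self, untreated_fibrosarcoma):
        eff = combined_log_effect(untreated_fibrosarcoma, None, None, 0.0, 20.0)
        assert eff.D_nf == 0.0 and eff.W_bar == 0.0
        assert eff.size == pytest.approx(gompertz_size(untreated_fibrosarcoma, 20.0), rel=1e-12)

    def test_single_fraction_at_evaluation_time(self):
        gp = GompertzParams(a=0.05, k=0.02, N0=30.0)
        sched = RadiationSchedule((10.0,), (8.0,), 0.3, 0.03)
        eff = combined_log_effect(gp, sched, None, 0.0, 10.0)
        assert eff.D_nf == pytest.approx(0.3 * 8 + 0.03 * 64, rel=1e-12)

    def test_three_fraction_discounted_sum(self, untreated_fibrosarcoma, eight_gy_course):
        eff = combined_log_effect(untreated_fibrosarcoma, eight_gy_course, None, 0.0, 15.0)
        # sum of 4.32 * exp(-0.0164 * (15 - t_i)), frozen from the event oracle
        assert eff.D_nf == pytest.approx(11.9408, rel=1e-4)

    def test_identity_against_recursive_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            gp = random_gompertz(rng)
            nf = rng.integers(1, 7)
            times = np.sort(rng.uniform(1.0, 24.0, nf))
            doses = rng.uniform(1.0, 12.0, nf)
            alpha, beta = rng.uniform(0.05, 0.5), rng.uniform(0.0, 0.05)
            sched = RadiationSchedule(tuple(times), tuple(doses), alpha, beta)
            t_eval = 25.0
            eff = combined_log_effect(gp, sched, None, 0.0, t_eval)
            kills = [(t, alpha * d + beta * d**2) for t, d in zip(times, doses)]
            oracle = integrate_growth(gp, None, kills, [0.0, *times, t_eval])
            assert math.log(eff.size) == pytest.approx(
                math.log(oracle.sizes[-1]), abs=1e-8
            )

    def test_course_log_size_matches_pointwise(self, untreated_fibrosarcoma, eight_gy_course):
        it = ImmunotherapyProfile(gamma=0.005, I0=1.0, rho=0.05)
        course = TherapyCourse(it=it, rt=eight_gy_course)
        grid = np.arange(0.0, 26.0, 1.0)
        u = course_log_size(untreated_fibrosarcoma, course, grid)
        pert = lambda t: -it.gamma * it.level(t)
        kills = [(t, k) for t, k in zip(eight_gy_course.fraction_times, eight_gy_course.log_kills)]
        oracle = integrate_growth(untreated_fibrosarcoma, pert, kills, grid)
        np.testing.assert_allclose(u, np.log(oracle.sizes), atol=1e-8)

    def test_fraction_outside_window_rejected(self, untreated_fibrosarcoma, eight_gy_course):
        with pytest.raises(ValueError):
            combined_log_effect(untreated_fibrosarcoma, eight_gy_course, None, 0.0, 10.0)


class TestRegressionCondition:
    def test_untreated_growth_not_regressing(self, untreated_fibrosarcoma):
        eff = combined_log_effect(untreated_fibrosarcoma, None, None, 0.0, 15.0)
        assert not regression_condition(eff).is_regressing

    def test_dominant_rt_regresses(self, untreated_fibrosarcoma, eight_gy_course):
        eff = combined_log_effect(untreated_fibrosarcoma, eight_gy_course, None, 0.0, 15.0)
        res = regression_condition(eff)
        assert res.is_regressing and res.margin < 0

    def test_near_critical_small_it_tips_balance(self):
        from tumorgl.therapy import CombinedLogEffect

        eff = CombinedLogEffect(growth_term=1.0, W_bar=0.01, D_nf=1.0, t0=0.0, t=10.0, N_t0=50.0)
        res = regression_condition(eff)
        assert res.is_regressing
        assert res.margin == pytest.approx(-0.01)
        assert res.near_critical


class TestAbscopal:
    def make(self, y0, **kw):
        return SynergyParams(delta=kw.get("delta", 1.0), tau=kw.get("tau", 2.0),
                             Y0=y0, lag=kw.get("lag", 2.0), t_in=9.0)

    def test_no_synergy_is_untreated_exactly(self, untreated_fibrosarcoma, eight_gy_course):
        grid = np.arange(0.0, 26.0, 1.0)
        for syn in (self.make(0.0), SynergyParams(delta=0.0, tau=2.0, Y0=0.5, lag=2.0, t_in=9.0)):
            traj = abscopal_trajectory(untreated_fibrosarcoma, syn, eight_gy_course, grid)
            np.testing.assert_array_equal(traj.sizes, gompertz_size(untreated_fibrosarcoma, grid))

    def test_stronger_coupling_smaller_metastasis(self, untreated_fibrosarcoma, eight_gy_course):
        grid = np.arange(0.0, 26.0, 0.5)
        lo = abscopal_trajectory(untreated_fibrosarcoma, self.make(0.1), eight_gy_course, grid)
        hi = abscopal_trajectory(untreated_fibrosarcoma, self.make(0.3), eight_gy_course, grid)
        post = grid >= 11.0  # first fraction + lag
        assert np.all(hi.sizes[post] <= lo.sizes[post] + 1e-12)

    def test_untreated_before_onset(self, untreated_fibrosarcoma, eight_gy_course):
        grid = np.arange(0.0, 26.0, 1.0)
        traj = abscopal_trajectory(untreated_fibrosarcoma, self.make(0.4), eight_gy_course, grid)
        pre = grid <= 11.0
        np.testing.assert_allclose(
            traj.sizes[pre], gompertz_size(untreated_fibrosarcoma, grid[pre]), rtol=1e-9
        )

    def test_continuous_everywhere(self, untreated_fibrosarcoma, eight_gy_course):
        grid = np.arange(0.0, 26.0, 0.05)
        traj = abscopal_trajectory(untreated_fibrosarcoma, self.make(0.4), eight_gy_course, grid)
        # no instantaneous kills on the metastasis: log-size jumps bounded by rate * dt
        steps = np.abs(np.diff(np.log(traj.sizes)))
        assert steps.max() < 0.2 * 0.05 * 25  # generous Lipschitz bound

    def test_final_size_monotone_in_synergy_parameters(self, untreated_fibrosarcoma, eight_gy_course):
        grid = np.arange(0.0, 26.0, 1.0)

        def final(**kw):
            syn = SynergyParams(delta=kw.get("delta", 1.0), tau=kw.get("tau", 2.0),
                                Y0=kw.get("y0", 0.2), lag=2.0, t_in=9.0)
            return abscopal_trajectory(untreated_fibrosarcoma, syn, eight_gy_course, grid).sizes[-1]

        assert final(y0=0.05) >= final(y0=0.2) >= final(y0=0.5)
        assert final(delta=0.5) >= final(delta=1.0) >= final(delta=2.0)
        assert final(tau=1.0) >= final(tau=2.0) >= final(tau=4.0)

    def test_synergy_without_schedule_rejected(self, untreated_fibrosarcoma):
        with pytest.raises(ValueError):
            abscopal_trajectory(untreated_fibrosarcoma, self.make(0.3), None, np.arange(0.0, 10.0))

    def test_post_rt_exponential_continuation(self, untreated_fibrosarcoma, eight_gy_course):
        # strong synergy -> negative rate at RT end -> pure exponential tail
        grid = np.arange(0.0, 26.0, 1.0)
        traj = abscopal_trajectory(untreated_fibrosarcoma, self.make(0.5), eight_gy_course, grid)
        tail = grid >= 13.0  # last fraction (11) + lag (2)
        logs = np.log(traj.sizes[tail])
        slopes = np.diff(logs) / np.diff(grid[tail])
        assert np.all(slopes < 0)
        np.testing.assert_allclose(slopes, slopes[0], rtol=1e-9)


class TestScheduleValidation:
    def test_mismatched_lengths(self):
        with pytest.raises(ValueError):
            RadiationSchedule((1.0, 2.0), (8.0,), 0.3, 0.03)

    def test_decreasing_times(self):
        with pytest.raises(ValueError):
            RadiationSchedule((2.0, 1.0), (8.0, 8.0), 0.3, 0.03)

    def test_negative_dose(self):
        with pytest.raises(ValueError):
            RadiationSchedule((1.0,), (-8.0,), 0.3, 0.03)
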