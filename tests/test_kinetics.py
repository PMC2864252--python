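"""Kinetic model: closed form vs numerical integration, and the derived laws."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from decaykinetics.kinetics import (
    FoldTarget,
    KineticParameters,
    PulseStimulus,
    calibrate_beta_for_level,
    half_life_from_rate,
    rate_from_half_life,
    shutoff_max_half_life,
    simulate_pulse,
    steady_state_level,
    time_to_fold_induction,
    transition_level,
)

FIG1B_ALPHAS = (2.0, 1.0, 0.5, 0.2)


def rk4(beta, alpha, x0, t_end, dt=1e-3):
    """Independent 4th-order Runge-Kutta integration of dX/dt = beta - alpha*X."""
    f = lambda x: beta - alpha * x
    x, t = x0, 0.0
    n = int(round(t_end / dt))
    dt = t_end / n if n else 0.0
    for _ in range(n):
        k1 = f(x)
        k2 = f(x + 0.5 * dt * k1)
        k3 = f(x + 0.5 * dt * k2)
        k4 = f(x + dt * k3)
        x += dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    return x


class TestSteadyStateAndHalfLife:
    @pytest.mark.parametrize(
        "beta,alpha,expected",
        [(5.0, 2.0, 2.5), (5.0, 0.2, 25.0), (0.0, 1.0, 0.0)],
    )
    def test_steady_state_is_beta_over_alpha(self, beta, alpha, expected):
        assert steady_state_level(KineticParameters(beta=beta, alpha=alpha)) == expected

    def test_half_life_closed_form_and_inverse(self):
        assert half_life_from_rate(math.log(2)) == pytest.approx(1.0)
        assert half_life_from_rate(0.2) == pytest.approx(3.4657, abs=1e-4)
        # published murine median 274 min -> rate
        assert rate_from_half_life(274 / 60) == pytest.approx(0.15178, abs=1e-5)
        for a in (0.1, 1.0, 7.3):
            assert rate_from_half_life(half_life_from_rate(a)) == pytest.approx(a)

    @pytest.mark.parametrize("alpha", [0.0, -1.0])
    def test_nonpositive_alpha_rejected(self, alpha):
        with pytest.raises(ValueError):
            half_life_from_rate(alpha)
        with pytest.raises(ValueError):
            KineticParameters(beta=1.0, alpha=alpha)


class TestTransitionLevel:
    def test_starts_at_x0(self):
        p = KineticParameters(beta=3.0, alpha=0.7, x0=1.3)
        assert transition_level(0.0, p) == pytest.approx(1.3)

    def test_half_transition_at_half_life(self):
        for alpha in FIG1B_ALPHAS:
            p = KineticParameters(beta=5.0, alpha=alpha, x0=0.0)
            mid = transition_level(math.log(2) / alpha, p)
            assert mid == pytest.approx(steady_state_level(p) / 2, rel=1e-12)

    def test_matches_rk4_fig1b_case(self):
        p = KineticParameters(beta=5.0, alpha=1.0, x0=0.0)
        assert transition_level(5.0, p) == pytest.approx(5 * (1 - math.exp(-5)), rel=1e-12)
        assert transition_level(5.0, p) == pytest.approx(rk4(5.0, 1.0, 0.0, 5.0), abs=1e-8)

    def test_matches_rk4_on_random_draws(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            beta = rng.uniform(0.1, 10)
            alpha = rng.uniform(0.05, 3)
            x0 = rng.uniform(0, 20)
            t = rng.uniform(0, 8)
            p = KineticParameters(beta=beta, alpha=alpha, x0=x0)
            assert abs(transition_level(t, p) - rk4(beta, alpha, x0, t)) < 1e-6 * (
                beta / alpha + 1
            )

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            transition_level(-0.1, KineticParameters(beta=1, alpha=1))

    @given(
        st.floats(0.05, 3.0),
        st.floats(0.0, 10.0),
        st.floats(0.0, 20.0),
        st.floats(0.0, 20.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_toward_steady_state(self, alpha, beta, x0, t):
        p = KineticParameters(beta=beta, alpha=alpha, x0=x0)
        x_t = transition_level(t, p)
        x_later = transition_level(t + 1.0, p)
        ss = steady_state_level(p)
        assert abs(x_later - ss) <= abs(x_t - ss) + 1e-12


class TestTimeToFoldInduction:
    def test_midpoint_case_equals_half_life(self):
        # k=2, L=3 -> f=0.5, so T_k is exactly one half-life
        assert time_to_fold_induction(FoldTarget(k=2, L=3), t_half=1.0) == pytest.approx(1.0)

    def test_vanishing_induction_takes_no_time(self):
        assert time_to_fold_induction(FoldTarget(k=1 + 1e-9, L=3), 2.0) == pytest.approx(
            0.0, abs=1e-8
        )

    def test_closed_form_against_root_finding(self):
        # T_k must equal the time at which the transient with beta -> L*beta
        # reaches k*X0, starting from the old steady state X0 = beta/alpha
        rng = np.random.default_rng(3)
        for _ in range(20):
            alpha = rng.uniform(0.1, 2.0)
            L = rng.uniform(2.0, 10.0)
            k = rng.uniform(1.05, 0.95 * L)
            beta = rng.uniform(0.5, 5.0)
            x0 = beta / alpha
            p = KineticParameters(beta=L * beta, alpha=alpha, x0=x0)
            t_root = brentq(lambda t: transition_level(t, p) - k * x0, 0, 500)
            t_k = time_to_fold_induction(FoldTarget(k=k, L=L), math.log(2) / alpha)
            assert t_k == pytest.approx(t_root, rel=1e-9)
        # the printed example: k=2, L=5, t_half=2 -> 2*(-log2(0.75))
        assert time_to_fold_induction(FoldTarget(k=2, L=5), 2.0) == pytest.approx(
            0.8301, abs=1e-4
        )

    def test_linear_in_half_life(self):
        tgt = FoldTarget(k=2, L=4)
        assert time_to_fold_induction(tgt, 3.0) == pytest.approx(
            3 * time_to_fold_induction(tgt, 1.0)
        )

    def test_unattainable_and_asymptotic_folds(self):
        with pytest.raises(ValueError):
            FoldTarget(k=5, L=3)
        assert time_to_fold_induction(FoldTarget(k=3, L=3), 1.0) == math.inf


class TestSimulatePulse:
    def test_pulse_level_matches_rk4(self):
        stim = PulseStimulus(t_on=0.0, t_off=5.0, beta_on=5.0, beta_off=0.0)
        grid = np.arange(0.0, 10.001, 0.25)
        traj = simulate_pulse(KineticParameters(beta=5, alpha=0.2, x0=0.0), stim, grid)
        assert traj.level_at(5.0) == pytest.approx(25 * (1 - math.exp(-1)), rel=1e-12)
        assert traj.level_at(5.0) == pytest.approx(rk4(5.0, 0.2, 0.0, 5.0), abs=1e-8)
        # after shut-off the decay is pure exponential from the t=5 level
        assert traj.level_at(8.0) == pytest.approx(
            traj.level_at(5.0) * math.exp(-0.2 * 3.0), rel=1e-10
        )

    def test_no_pulse_at_steady_state_is_constant(self):
        stim = PulseStimulus(t_on=1.0, t_off=2.0, beta_on=4.0, beta_off=4.0)
        p = KineticParameters(beta=4.0, alpha=2.0, x0=2.0)  # x0 = beta/alpha
        traj = simulate_pulse(p, stim, np.linspace(0, 6, 25))
        assert np.allclose(traj.levels, 2.0, rtol=1e-12)

    def test_fractional_completion_ranked_by_alpha(self):
        # at a fixed early time, the fraction of the transition completed
        # ranks by alpha: the least stable transcript is the fastest
        stim = PulseStimulus(t_on=0.0, t_off=5.0, beta_on=5.0, beta_off=0.0)
        grid = np.array([0.0, 0.5])
        fracs = []
        for alpha in FIG1B_ALPHAS:
            p = KineticParameters(beta=5.0, alpha=alpha, x0=0.0)
            traj = simulate_pulse(p, stim, grid)
            fracs.append(traj.level_at(0.5) / (5.0 / alpha))
        assert fracs == sorted(fracs, reverse=True)

    def test_shutoff_decay_measured_half_life(self):
        # beta_off=0 decay: the measured time to halve equals ln2/alpha
        for alpha in FIG1B_ALPHAS:
            grid = np.round(np.arange(0.0, 30.0, 0.001), 9)
            stim = PulseStimulus(t_on=0.0, t_off=5.0, beta_on=5.0, beta_off=0.0)
            p = KineticParameters(beta=5.0, alpha=alpha, x0=0.0)
            traj = simulate_pulse(p, stim, grid)
            peak = traj.level_at(5.0)
            after = traj.times >= 5.0
            below = traj.times[after][traj.levels[after] <= peak / 2]
            assert below[0] - 5.0 == pytest.approx(math.log(2) / alpha, abs=0.002)

    def test_empty_or_bad_grid_rejected(self):
        stim = PulseStimulus(t_on=0.0, t_off=5.0, beta_on=5.0)
        p = KineticParameters(beta=5.0, alpha=1.0)
        with pytest.raises(ValueError):
            simulate_pulse(p, stim, [])
        with pytest.raises(ValueError):
            simulate_pulse(p, stim, [0.0, 0.0, 1.0])
        with pytest.raises(ValueError):
            simulate_pulse(p, stim, [1.0, 2.0])  # starts after pulse onset


class TestCalibrateBeta:
    def test_limit_recovers_base_rate(self):
        assert calibrate_beta_for_level(25.0, 0.2, 1e6, x0=0.0) == pytest.approx(5.0)

    def test_round_trip_hits_target(self):
        beta = calibrate_beta_for_level(5.0, 1.0, 5.0, x0=0.0)
        assert beta == pytest.approx(5 / (1 - math.exp(-5)), rel=1e-12)
        p = KineticParameters(beta=beta, alpha=1.0, x0=0.0)
        assert transition_level(5.0, p) == pytest.approx(5.0, abs=1e-9)

    def test_zero_target_zero_rate(self):
        assert calibrate_beta_for_level(0.0, 1.0, 2.0, x0=0.0) == 0.0

    def test_unreachable_target_rejected(self):
        with pytest.raises(ValueError):
            calibrate_beta_for_level(0.1, 0.01, 0.5, x0=10.0)


class TestShutoffBound:
    @pytest.mark.parametrize(
        "fold,t,expected", [(2.0, 1.0, 1.0), (4.0, 2.0, 1.0), (2.0, 2.0, 2.0)]
    )
    def test_bound_values(self, fold, t, expected):
        assert shutoff_max_half_life(fold, t) == pytest.approx(expected)

    def test_stable_transcript_violates_bound(self):
        # a >5 h half-life transcript halving within 1-2 h exceeds the bound
        assert 5.0 > shutoff_max_half_life(2.0, 2.0)

    @given(st.floats(1.01, 50.0), st.floats(0.1, 24.0), st.floats(0.01, 5.0))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_time_and_fold(self, fold, t, dt):
        b = shutoff_max_half_life(fold, t)
        assert shutoff_max_half_life(fold, t + dt) > b
        assert shutoff_max_half_life(fold + 0.5, t) < b

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            shutoff_max_half_life(1.0, 1.0)
        with pytest.raises(ValueError):
            shutoff_max_half_life(2.0, 0.0)
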