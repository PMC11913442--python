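"""Smoothed selection/update primitives and the differentiable simulator."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

import dgasim.autodiff as ad
from dgasim.dga_engine import (
    Smoothing,
    pathwise_gradient,
    simulate_dga,
    soft_select,
    soft_time_update,
    soft_update,
)
from dgasim.estimation import MomentTarget, ensemble_mean_std, moment_loss
from dgasim.promoter_models import TWO_STATE_X0
from dgasim.reaction_core import (
    AbsorbingStateError,
    NoiseSource,
    Propensity,
    ReactionSystem,
    SimConfig,
    simulate_exact,
)


def birth_death(r=10.0, gamma=1.0):
    return ReactionSystem(
        ["m"],
        np.array([[1], [-1]]),
        [Propensity(params="r"), Propensity(params="gamma", orders={"m": 1})],
        {"r": r, "gamma": gamma},
    )


class TestSmoothing:
    def test_defaults_match_benchmark_settings(self):
        s = Smoothing()
        assert 1 / s.a == pytest.approx(200) and 1 / s.b == pytest.approx(20)

    def test_unstable_regime_warns(self):
        with pytest.warns(UserWarning, match="unstable"):
            Smoothing.from_inverse(2000.0, 20.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            Smoothing(a=-1.0)


class TestSoftSelect:
    def test_midpoint_symmetry(self):
        assert soft_select(np.array([1.0, 1.0]), 0.5, 0.1) == pytest.approx(1.5)

    def test_steep_sigmoid_reaches_second_reaction(self):
        got = soft_select(np.array([1.0, 1.0]), 0.75, 1 / 200)
        assert got == pytest.approx(2 - expit(-50.0), abs=1e-21)

    def test_hard_limit_recovers_exact_selection(self):
        got = soft_select(np.array([2.0, 0.0, 3.0]), 0.5, 1e-9)
        assert got == pytest.approx(3.0)

    def test_absorbing_signals(self):
        with pytest.raises(AbsorbingStateError):
            soft_select(np.array([0.0, 0.0]), 0.5, 0.01)

    @given(
        rates=st.lists(st.floats(0.01, 20.0), min_size=2, max_size=6),
        a=st.sampled_from([0.05, 1 / 200]),
    )
    @settings(max_examples=40, deadline=None)
    def test_nondecreasing_in_u_prime(self, rates, a):
        r = np.array(rates)
        grid = np.linspace(0.0, 0.999, 101)
        idx = np.array([float(soft_select(r, u, a)) for u in grid])
        assert np.all(np.diff(idx) >= -1e-12)
        assert idx.min() >= 1.0 - 1e-9 and idx.max() <= len(rates) + 1e-9


class TestSoftUpdate:
    def test_integer_index_adds_row_with_gaussian_spillover(self):
        S = np.array([[0, -1], [1, 0], [0, 1]])
        b = 1 / 20
        x = soft_update(np.zeros(2), 2.0, S, b)
        spill = np.exp(-1 / b)
        assert x[0] == pytest.approx(1.0)
        assert x[1] == pytest.approx(-spill + spill, abs=1e-12)  # rows 1,3 cancel
        assert spill == pytest.approx(2.06e-9, rel=0.01)

    def test_midway_opposite_stoichiometry_cancels(self):
        S = np.array([[1], [-1]])
        x = soft_update(np.array([5.0]), 1.5, S, 1 / 20)
        assert x[0] == pytest.approx(5.0)

    def test_single_reaction_exact_row_addition(self):
        S = np.array([[2, -1]])
        x = soft_update(np.array([0.0, 0.0]), 1.0, S, 1 / 20)
        assert np.allclose(x, [2.0, -1.0])


class TestSoftTimeUpdate:
    def test_u_one_leaves_time(self):
        assert soft_time_update(3.0, 2.0, 1.0) == pytest.approx(3.0)

    def test_closed_form_increment(self):
        assert soft_time_update(0.0, 2.0, np.e**-1) == pytest.approx(0.5)

    def test_derivative_in_rate(self):
        R = ad.Dual(np.array(2.0), np.ones(1))
        out = soft_time_update(0.0, R, np.e**-1)
        assert out.tan[0] == pytest.approx(-0.25)

    def test_invalid_inputs_signal(self):
        with pytest.raises(AbsorbingStateError):
            soft_time_update(0.0, 0.0, 0.5)
        with pytest.raises(ValueError):
            soft_time_update(0.0, 1.0, 0.0)


class TestSimulateDga:
    def test_identical_seeds_bitwise_identical(self, two_state_system, default_smoothing):
        cfg = SimConfig(t_end=5.0, n_traj=20, seed=9, max_steps=2000)
        a = simulate_dga(two_state_system, TWO_STATE_X0, cfg, default_smoothing)
        b = simulate_dga(two_state_system, TWO_STATE_X0, cfg, default_smoothing)
        assert np.array_equal(ad.value(a.states), ad.value(b.states))
        assert np.array_equal(ad.value(a.clocks), ad.value(b.clocks))

    def test_hard_limit_matches_exact_on_shared_noise(self, two_state_system):
        cfg = SimConfig(t_end=10.0, n_traj=100, seed=5, max_steps=4000)
        exact = simulate_exact(two_state_system, TWO_STATE_X0, cfg,
                               noise=NoiseSource(5, 100))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # deliberately ultra-steep smoothing
            soft = simulate_dga(two_state_system, TWO_STATE_X0, cfg,
                                Smoothing(a=1e-8, b=1e-4), noise=NoiseSource(5, 100))
        mismatch = np.abs(exact.final_states - ad.value(soft.states)) > 1e-6
        assert mismatch.mean() < 0.01  # identical up to rare boundary-tie steps

    def test_ensemble_mean_near_cme(self, two_state_system, default_smoothing):
        cfg = SimConfig(t_end=10.0, n_traj=2000, seed=11, max_steps=4000)
        ens = simulate_dga(two_state_system, TWO_STATE_X0, cfg, default_smoothing)
        assert ens.counts("m").mean() == pytest.approx(20 / 3, rel=0.15)

    def test_clocks_frozen_at_horizon(self, two_state_system, default_smoothing):
        cfg = SimConfig(t_end=4.0, n_traj=50, seed=2, max_steps=3000)
        ens = simulate_dga(two_state_system, TWO_STATE_X0, cfg, default_smoothing)
        assert ens.done.all()
        assert np.all(ad.value(ens.clocks) <= cfg.t_end + 1e-12)

    def test_indicator_stays_in_physical_bounds(self, two_state_system, default_smoothing):
        cfg = SimConfig(t_end=50.0, n_traj=300, seed=4, max_steps=8000)
        ens = simulate_dga(two_state_system, TWO_STATE_X0, cfg, default_smoothing)
        d = ad.value(ens.states)[:, 0]
        assert d.min() >= 0.0 and d.max() <= 1.0

    def test_unfinished_trajectories_warn(self, two_state_system, default_smoothing):
        cfg = SimConfig(t_end=1000.0, n_traj=5, seed=2, max_steps=30)
        with pytest.warns(UserWarning, match="did not reach"):
            ens = simulate_dga(two_state_system, TWO_STATE_X0, cfg, default_smoothing)
        assert ens.unfinished == 5


class TestPathwiseGradient:
    def _loss(self, system, names, target, seed=3, n=200, t_end=5.0,
              rate_tangents="full"):
        def loss_fn(log_th):
            params = {nm: ad.exp(log_th[j]) for j, nm in enumerate(names)}
            cfg = SimConfig(t_end=t_end, n_traj=n, max_steps=4000, seed=seed)
            ens = simulate_dga(system, [0] * system.n_species, cfg, Smoothing(),
                               params=params, noise=NoiseSource(seed, n),
                               rate_tangents=rate_tangents)
            mean, std = ensemble_mean_std(ens.soft_counts(system.species[-1]))
            return moment_loss(mean, std, target)
        return loss_fn

    def test_matches_finite_differences_on_birth_death(self):
        system = birth_death()
        target = MomentTarget(mean=8.0, std=3.0)
        loss_fn = self._loss(system, ["r", "gamma"], target)
        log_th = np.log([10.0, 1.0])
        _, grad = pathwise_gradient(loss_fn, log_th)
        h = 1e-5

        def f(lt):
            return float(ad.value(loss_fn(ad.seed_duals(lt))))

        fd = np.array([(f(log_th + h * e) - f(log_th - h * e)) / (2 * h)
                       for e in np.eye(2)])
        assert np.allclose(grad, fd, rtol=1e-3)

    def test_loss_independent_of_theta_gives_zero_gradient(self):
        _, grad = pathwise_gradient(lambda th: ad.vsum(th * 0.0) + 3.0, np.array([1.0, 2.0]))
        assert np.allclose(grad, 0.0)

    def test_pure_birth_count_has_zero_pathwise_gradient(self):
        # with a single reaction there is no selection path: the final count
        # depends on the rate only through the discrete number of steps, so
        # the pathwise derivative is identically zero
        system = ReactionSystem(["m"], np.array([[1]]), [Propensity(params="r")],
                                {"r": 2.0})

        def loss_fn(log_th):
            cfg = SimConfig(t_end=5.0, n_traj=50, max_steps=2000, seed=1)
            ens = simulate_dga(system, [0], cfg, Smoothing(),
                               params={"r": ad.exp(log_th[0])},
                               noise=NoiseSource(1, 50))
            return ad.vmean(ens.soft_counts("m"))

        _, grad = pathwise_gradient(loss_fn, np.log([2.0]))
        assert grad[0] == pytest.approx(0.0, abs=1e-12)

    def test_clipped_estimator_bounded_and_descent_aligned(self, two_state_system):
        # at parameters below truth the clipped gradient must push the
        # transcription rate up (negative log-r component)
        target = MomentTarget(mean=6.667, std=3.95)
        grads = []
        for seed in range(5):
            loss_fn = self._loss(two_state_system, ["kon", "r"], target, seed=seed,
                                 n=300, t_end=10.0, rate_tangents="clipped")
            _, g = pathwise_gradient(
                lambda th: loss_fn(th), np.log([0.5, 3.0]))
            grads.append(g)
        grads = np.array(grads)
        assert np.all(np.isfinite(grads)) and np.abs(grads).max() < 1e3
        assert grads[:, 1].mean() < 0
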