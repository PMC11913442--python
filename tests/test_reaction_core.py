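"""Exact SSA mechanics, ensembles, and the truncated-CME oracle."""

import numpy as np
import pytest
from scipy.stats import kstest, poisson

from dgasim.distribution_metrics import jsd
from dgasim.promoter_models import TWO_STATE_X0, TwoStateParams, build_two_state
from dgasim.reaction_core import (
    AbsorbingStateError,
    NoiseSource,
    Propensity,
    ReactionSystem,
    SimConfig,
    TruncationError,
    cme_steady_state,
    exact_step,
    simulate_exact,
    total_rate,
)


def birth_death(r=10.0, gamma=1.0):
    return ReactionSystem(
        ["m"],
        np.array([[1], [-1]]),
        [Propensity(params="r"), Propensity(params="gamma", orders={"m": 1})],
        {"r": r, "gamma": gamma},
    )


class TestTotalRate:
    def test_two_state_off_only_unbinding_active(self, two_state_system):
        # repressed promoter with no mRNA: only "repressor unbinds" can fire
        assert total_rate(two_state_system, np.array([0.0, 0.0])) == pytest.approx(1.0)

    def test_all_zero_propensities(self):
        sys_ = ReactionSystem(["m"], np.array([[1]]),
                              [Propensity(params="r", orders={"m": 1})], {"r": 2.0})
        assert total_rate(sys_, np.array([0.0])) == 0.0

    def test_single_reaction_identity(self):
        sys_ = ReactionSystem(["m"], np.array([[1]]), [Propensity(params="r")], {"r": 10.0})
        assert total_rate(sys_, np.array([0.0])) == pytest.approx(10.0)


class TestExactStep:
    def test_selection_ladder_upper_half(self, queued_rng):
        sys_ = ReactionSystem(["m"], np.array([[1], [-1]]),
                              [Propensity(params="a"), Propensity(params="b")],
                              {"a": 1.0, "b": 1.0})
        # u drawn first (waiting time), then u' = 0.75 -> cumulative 0.5 < 0.75 -> index 1
        _, idx, _ = exact_step(sys_, np.array([5]), queued_rng([0.5, 0.75]))
        assert idx == 1

    def test_waiting_time_closed_form(self, queued_rng):
        sys_ = ReactionSystem(["m"], np.array([[1], [-1]]),
                              [Propensity(params="a"), Propensity(params="b")],
                              {"a": 1.0, "b": 1.0})
        # u = e^-1 (rng.random returns 1 - u), so dt = -ln(e^-1)/2 = 0.5
        dt, _, _ = exact_step(sys_, np.array([5]), queued_rng([1.0 - np.e**-1, 0.3]))
        assert dt == pytest.approx(0.5)

    def test_zero_rate_reaction_skipped(self, queued_rng):
        sys_ = ReactionSystem(
            ["m"], np.array([[1], [1], [1]]),
            [Propensity(params="a"), Propensity(params="b"), Propensity(params="c")],
            {"a": 2.0, "b": 0.0, "c": 3.0})
        # cumulative (0.4, 0.4, 1.0); u' = 0.5 -> smallest index with C > u' is 3
        _, idx, _ = exact_step(sys_, np.array([0]), queued_rng([0.5, 0.5]))
        assert idx == 2  # zero-based row of reaction 3

    def test_absorbing_state_signals(self, rng):
        sys_ = ReactionSystem(["m"], np.array([[-1]]),
                              [Propensity(params="g", orders={"m": 1})], {"g": 1.0})
        with pytest.raises(AbsorbingStateError):
            exact_step(sys_, np.array([0]), rng)


class TestSimulateExact:
    def test_pure_death_reaches_absorbing_zero(self):
        sys_ = ReactionSystem(["m"], np.array([[-1]]),
                              [Propensity(params="g", orders={"m": 1})], {"g": 1.0})
        ens = simulate_exact(sys_, [5], SimConfig(t_end=100.0, n_traj=50, seed=0))
        assert np.all(ens.final_states == 0)

    def test_two_state_mean_matches_cme(self, two_state_system):
        ens = simulate_exact(two_state_system, TWO_STATE_X0,
                             SimConfig(t_end=50.0, n_traj=2000, seed=1, max_steps=10_000))
        m = ens.counts(two_state_system, "m")
        se = m.std() / np.sqrt(len(m))
        assert abs(m.mean() - 20 / 3) < 3 * se

    def test_determinism_under_seed(self, two_state_system):
        cfg = SimConfig(t_end=5.0, n_traj=3, seed=7, max_steps=2000)
        a = simulate_exact(two_state_system, TWO_STATE_X0, cfg)
        b = simulate_exact(two_state_system, TWO_STATE_X0, cfg)
        assert np.array_equal(a.final_states, b.final_states)
        assert np.array_equal(a.final_times, b.final_times)
        assert np.array_equal(a.fired_counts, b.fired_counts)

    def test_event_count_conservation(self, two_state_system):
        ens = simulate_exact(two_state_system, TWO_STATE_X0,
                             SimConfig(t_end=10.0, n_traj=100, seed=3, max_steps=5000))
        reconstructed = TWO_STATE_X0 + ens.fired_counts @ two_state_system.S
        assert np.array_equal(reconstructed, ens.final_states)

    def test_max_steps_flags_not_fatal(self, two_state_system):
        ens = simulate_exact(two_state_system, TWO_STATE_X0,
                             SimConfig(t_end=1000.0, n_traj=5, seed=3, max_steps=50))
        assert ens.flagged.all()

    def test_waiting_times_exponential(self, rng):
        # constant total rate R=4: inter-event times must be Exp(4)
        sys_ = ReactionSystem(["m"], np.array([[1], [1]]),
                              [Propensity(params="a"), Propensity(params="b")],
                              {"a": 1.0, "b": 3.0})
        x = np.array([0])
        dts = []
        for _ in range(2000):
            dt, _, x_next = exact_step(sys_, x, rng)
            dts.append(dt)
        assert kstest(dts, "expon", args=(0, 1 / 4)).pvalue > 0.01

    def test_empirical_pmf_converges_to_cme(self, two_state_system, paper_params):
        from dgasim.distribution_metrics import empirical_pmf
        from dgasim.promoter_models import two_state_cme

        p_exact = two_state_cme(paper_params).marginal("m")
        divs = []
        for n in (500, 5000):
            ens = simulate_exact(two_state_system, TWO_STATE_X0,
                                 SimConfig(t_end=30.0, n_traj=n, seed=5, max_steps=10_000))
            divs.append(jsd(empirical_pmf(ens.counts(two_state_system, "m")), p_exact))
        assert divs[1] < divs[0]


class TestNoiseSource:
    def test_streams_stable_under_ensemble_growth(self):
        a = NoiseSource(3, 4)
        b = NoiseSource(3, 6)
        ua, upa = a.next_pair()
        ub, upb = b.next_pair()
        assert np.allclose(ua, ub[:4]) and np.allclose(upa, upb[:4])

    def test_u_in_half_open_unit_interval(self):
        ns = NoiseSource(0, 100)
        for _ in range(300):  # cross several chunk refills
            u, up = ns.next_pair()
            assert np.all(u > 0) and np.all(u <= 1.0)
            assert np.all(up >= 0) and np.all(up < 1.0)


class TestCme:
    def test_birth_death_is_poisson(self):
        dist = cme_steady_state(birth_death(), {"m": 100})
        pmf = dist.marginal("m")
        analytic = poisson.pmf(pmf.support, 10)
        assert np.abs(pmf.probs - analytic).sum() < 1e-8

    def test_two_state_paper_parameters(self, two_state_system):
        dist = cme_steady_state(two_state_system, {"d": 1, "m": 80})
        assert dist.mean("m") == pytest.approx(20 / 3, rel=1e-9)
        assert dist.fano("m") == pytest.approx(7 / 3, rel=1e-9)

    def test_zero_production_point_mass(self):
        dist = cme_steady_state(birth_death(r=1e-14), {"m": 30})
        pmf = dist.marginal("m")
        assert pmf.probs[0] == pytest.approx(1.0, abs=1e-9)

    def test_truncation_too_small_signals_with_mass(self):
        with pytest.raises(TruncationError) as exc:
            cme_steady_state(birth_death(r=50.0), {"m": 30})
        assert exc.value.boundary_mass > 1e-6

    def test_truncation_insensitivity(self, two_state_system):
        d1 = cme_steady_state(two_state_system, {"d": 1, "m": 60})
        d2 = cme_steady_state(two_state_system, {"d": 1, "m": 90})
        assert d1.mean("m") == pytest.approx(d2.mean("m"), rel=1e-10)


class TestSerialization:
    def test_system_round_trips_through_dict(self, two_state_system):
        rebuilt = ReactionSystem.from_dict(two_state_system.to_dict())
        assert rebuilt.species == two_state_system.species
        assert np.array_equal(rebuilt.S, two_state_system.S)
        assert rebuilt.params == two_state_system.params
        assert rebuilt.bounds == two_state_system.bounds
        x = np.array([1.0, 3.0])
        assert np.allclose(rebuilt.rates(x), two_state_system.rates(x))

    def test_invalid_shapes_rejected(self):
        with pytest.raises(ValueError):
            ReactionSystem(["a"], np.array([[1, 0]]), [Propensity(params="r")], {"r": 1.0})
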