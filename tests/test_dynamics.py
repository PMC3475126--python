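"""Coupled ODE system: balances, integration, events, post-processing."""

import dataclasses

import numpy as np
import pytest

import microtrait as mt
from microtrait.dynamics import (
    N_POOLS,
    PulseEvent,
    SolverOptions,
    apply_knockout,
    derivatives,
    detect_steady_state,
    initial_community,
    integrate,
    running_average,
)
from microtrait.environment import EnvironmentState
from microtrait.kinetics import UM, GuildState, nh3_uptake_rate
from microtrait.params import DEFAULT_PARAMS
from microtrait.traits import FunctionalGroup


class TestDerivatives:
    def test_dead_system_is_inert(self, mean_analogs):
        env = EnvironmentState(tan=1e-4, no2=1e-5, ph=7.8, temperature=293.15)
        gs = [GuildState(0.0, 0.0, 0.0) for _ in mean_analogs]
        dy = derivatives(mt.CommunityState(mean_analogs, gs, env))
        assert np.all(dy == 0.0)

    def test_single_guild_tan_balance(self, aob7):
        """Hand-assembled one-guild budget: dTAN = -(oxidation + assimilation)
        + mortality recycling, with the standalone rate laws as oracle."""
        p = DEFAULT_PARAMS
        env = EnvironmentState(tan=2e-4, ph=7.8, temperature=293.15)
        gs = GuildState(1e-6, 1.4e-6, 1.4e-7)
        state = mt.CommunityState([aob7], [gs], env)
        dy = derivatives(state)

        tf = mt.temperature_factor(env.temperature, aob7)
        ox = nh3_uptake_rate(aob7, env.nh3_free, env.o2, gs.b_total, temp_factor=tf)
        qn = gs.q_n
        headroom = (p.quota.qn_max - qn) / (p.quota.qn_max - p.quota.qn_min)
        assim = (
            p.n_uptake_scale * tf * aob7.vmax_substrate * gs.b_total
            * env.tan / (p.km_assim + env.tan) * headroom
        )
        recycle = p.mortality * gs.b_nitrogen
        assert dy[0] == pytest.approx(-(ox + assim) + recycle, rel=1e-12)
        # all oxidized N goes to NO2 less the hydroxylamine fraction
        assert dy[1] == pytest.approx(ox * (1 - p.hydroxylamine_fraction), rel=1e-12)
        assert dy[3] == pytest.approx(ox * p.hydroxylamine_fraction, rel=1e-12)

    def test_nitrogen_closure_random_states(self, mean_analogs):
        rng = np.random.default_rng(1)
        for _ in range(20):
            env = EnvironmentState(
                tan=rng.uniform(0, 1e-3), no2=rng.uniform(0, 1e-4),
                no=rng.uniform(0, 1e-5), n2o=rng.uniform(0, 1e-6),
                no3=rng.uniform(0, 1e-4), o2=1e-3, co2=1e-3,
                ph=rng.uniform(4.5, 7.8), temperature=rng.uniform(278, 303),
            )
            gs = [
                GuildState(b, b * rng.uniform(1, 2), b * rng.uniform(0.08, 0.15))
                for b in rng.uniform(0, 1e-5, len(mean_analogs))
            ]
            dy = derivatives(mt.CommunityState(mean_analogs, gs, env))
            total_n_rate = dy[0] + dy[1] + dy[2] + dy[3] + dy[4] + dy[N_POOLS + 2 :: 3].sum()
            assert abs(total_n_rate) < 1e-20

    def test_negative_state_rejected(self, mean_analogs):
        env = EnvironmentState(tan=1e-4)
        gs = [GuildState(1e-8, 1e-8, 1e-9) for _ in mean_analogs]
        state = mt.CommunityState(mean_analogs, gs, env)
        y = state.as_vector()
        y[0] = -1.0
        with pytest.raises(ValueError):
            state.with_vector(y)


class TestIntegrate:
    def test_empty_community_pools_unchanged(self):
        env = EnvironmentState(tan=1e-4, no2=1e-5, ph=7.8, temperature=293.15)
        state = mt.CommunityState([], [], env)
        res = integrate(state, 180.0)
        assert np.allclose(res.pools[-1], res.pools[0])

    def test_closed_run_conserves_nitrogen(self, coupled_run):
        res, _ = coupled_run
        tn = res.total_n_series
        assert (tn.max() - tn.min()) / tn[0] < 1e-6

    def test_states_non_negative(self, coupled_run):
        res, _ = coupled_run
        assert res.pools.min() >= 0.0
        assert res.b_total.min() >= 0.0

    def test_pulses_raise_tan_at_event_times(self, mean_analogs):
        env = EnvironmentState(tan=1e-4, ph=7.8, temperature=293.15)
        state = initial_community(mean_analogs, env)
        amt = 3e-5
        res = integrate(state, 100.0, pulses=[PulseEvent(time=50.0, amount=amt)])
        tan = res.pool("tan")
        jump = tan[51] - tan[49]
        assert jump > 0.8 * amt  # pulse visible net of ~2 days of consumption

    def test_pulse_outside_run_rejected(self, mean_analogs):
        env = EnvironmentState(tan=1e-4)
        state = initial_community(mean_analogs, env)
        with pytest.raises(ValueError):
            integrate(state, 10.0, pulses=[PulseEvent(time=50.0, amount=1e-6)])

    def test_solver_tolerance_convergence(self, mean_analogs):
        """Halving tolerances changes final biomasses by < 0.1%."""
        env = EnvironmentState(
            tan=1e-5 / mt.nh3_fraction(7.8), ph=7.8, temperature=293.15
        )
        state = initial_community(mean_analogs, env)
        res1 = integrate(state, 180.0, solver=SolverOptions(rtol=1e-7))
        res2 = integrate(state, 180.0, solver=SolverOptions(rtol=5e-8))
        b1, b2 = res1.b_total[-1], res2.b_total[-1]
        live = b1 > 1e-12
        assert np.max(np.abs(b1[live] - b2[live]) / b1[live]) < 1e-3


class TestKnockout:
    def test_knockout_zeroes_group(self, mean_analogs):
        env = EnvironmentState(tan=1e-4)
        state = initial_community(mean_analogs, env)
        knocked = apply_knockout(state, FunctionalGroup.NOB)
        assert knocked.group_biomass(FunctionalGroup.NOB) == 0.0
        assert knocked.group_biomass(FunctionalGroup.AOB) > 0.0

    def test_knockout_of_empty_group_is_noop(self, mean_analogs):
        env = EnvironmentState(tan=1e-4)
        state = initial_community(mean_analogs, env)
        once = apply_knockout(state, FunctionalGroup.NOB)
        twice = apply_knockout(once, FunctionalGroup.NOB)
        assert once.biomass_vector().tolist() == twice.biomass_vector().tolist()

    def test_no2_accumulates_after_knockout(self, coupled_run):
        """Removing NOB stops NO2 consumption; the pool builds up."""
        res, template = coupled_run
        steady = res.final_state(template)
        knocked = apply_knockout(steady, FunctionalGroup.NOB)
        after = integrate(knocked, 60.0, knockout=[FunctionalGroup.NOB])
        assert np.all(after.no2_ox_rate == 0.0)
        assert after.pool("no2")[-1] > 5.0 * after.pool("no2")[0]


class TestRunningAverage:
    def test_constant_series_unchanged(self):
        s = np.full(100, 3.5)
        assert np.allclose(running_average(s, 30), 3.5)

    def test_unit_impulse_plateau(self):
        s = np.zeros(100)
        s[40] = 1.0
        out = running_average(s, 30)
        assert np.allclose(out[40:70], 1.0 / 30.0)
        assert np.allclose(out[70:], 0.0)
        assert out[39] == 0.0

    def test_window_one_is_identity(self):
        s = np.random.default_rng(0).normal(size=50)
        assert np.allclose(running_average(s, 1), s)


class TestSteadyStateDetection:
    def test_constant_series_at_time_zero(self):
        assert detect_steady_state(np.full((50, 2), 1.0)) == 0.0

    def test_fast_decay_never_steady(self):
        t = np.arange(100.0)
        series = np.exp(-0.05 * t)[:, None]
        assert detect_steady_state(series, tol=1e-4) is None

    def test_logistic_plateau_detected(self):
        t = np.arange(200.0)
        series = (1.0 / (1.0 + np.exp(-(t - 60) / 8.0)))[:, None]
        found = detect_steady_state(series, tol=1e-4)
        assert found is not None and 60.0 < found < 200.0
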