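"""Scenario protocols: determinism, qualitative community patterns."""

import numpy as np
import pytest

import microtrait as mt
from microtrait.dynamics import running_average
from microtrait.environment import nh3_fraction
from microtrait.scenarios import (
    ScenarioConfig,
    build_analogs,
    default_site_fixtures,
    run_decoupling,
    run_ph_gradient,
    run_pulsed_substrate,
    run_site_comparison,
    run_temperature_gradient,
)


def aoo_guild_fractions(res):
    b = res.b_total[-1]
    guilds = {}
    for i, a in enumerate(res.analogs):
        if a.functional_group.is_aoo:
            guilds[a.parent_guild] = guilds.get(a.parent_guild, 0.0) + b[i]
    total = sum(guilds.values())
    return {g: v / total for g, v in guilds.items()}


@pytest.fixture(scope="module")
def ph_results():
    return run_ph_gradient(ScenarioConfig(scenario_id="ph_gradient"))


@pytest.fixture(scope="module")
def temp_results():
    return run_temperature_gradient(ScenarioConfig(scenario_id="temperature_gradient"))


class TestConfig:
    def test_ph_outside_gradient_rejected(self):
        with pytest.raises(ValueError):
            ScenarioConfig(scenario_id="ph_gradient", ph_values=(9.0,))

    def test_mc_requires_analogs(self):
        with pytest.raises(ValueError):
            ScenarioConfig(scenario_id="ph_gradient", trait_mode="monte_carlo", n_analogs=0)

    def test_mean_mode_one_analog_per_guild(self, guilds):
        analogs = build_analogs(guilds, "mean", 5, seed=0)
        assert len(analogs) == 11

    def test_mc_mode_n_analogs_per_guild(self, guilds):
        analogs = build_analogs(guilds, "monte_carlo", 5, seed=0)
        assert len(analogs) == 55
        assert build_analogs(guilds, "monte_carlo", 5, seed=0) == analogs


class TestPhGradient:
    def test_neutral_ph_dominated_by_oligotrophic_aob(self, ph_results):
        fr = aoo_guild_fractions(ph_results[7.8]["result"])
        top2 = sorted(fr, key=fr.get, reverse=True)[:2]
        assert set(top2) == {"AOB(7)", "AOB(4)"}

    def test_aoa_dominates_acid_end(self, ph_results):
        for ph in (5.0, 4.5):
            c = ph_results[ph]["composition"]
            assert max(c.fractions, key=c.fractions.get) == "AOA"

    def test_aoa_negligible_at_neutral(self, ph_results):
        fr = aoo_guild_fractions(ph_results[7.8]["result"])
        assert fr["AOA"] < 0.05

    def test_coupled_n2o_dominated_by_hydroxylamine(self, ph_results):
        for d in ph_results.values():
            assert d["rates"]["detox_share"] < 0.01

    def test_deterministic_under_fixed_config(self):
        cfg = ScenarioConfig(scenario_id="ph_gradient", ph_values=(6.0,), seed=3,
                             trait_mode="monte_carlo", n_analogs=2)
        a = run_ph_gradient(cfg)[6.0]["result"]
        b = run_ph_gradient(cfg)[6.0]["result"]
        assert np.array_equal(a.b_total, b.b_total)
        assert np.array_equal(a.pools, b.pools)


class TestTemperatureGradient:
    def test_oxidation_maximal_at_25c(self, temp_results):
        rates = {t: d["rates"]["max_nh3_ox_rate_smoothed"] for t, d in temp_results.items()}
        assert max(rates, key=rates.get) == 25

    def test_cold_adapted_guild_dominates_at_5c(self, temp_results):
        fr = aoo_guild_fractions(temp_results[5]["result"])
        assert max(fr, key=fr.get) == "AOB(6)"

    def test_warm_guilds_take_over_above_15c(self, temp_results):
        fr = aoo_guild_fractions(temp_results[25]["result"])
        assert fr["AOB(6)"] < 0.05


@pytest.fixture(scope="module")
def pair():
    out = run_decoupling(ScenarioConfig(scenario_id="decoupling", trait_mode="mean"))
    return out["replicates"][0]


class TestDecoupling:
    def test_no2_accumulates_after_knockout(self, pair):
        ko = pair["knockout"]
        assert ko.pool("no2").max() > 10.0 * ko.pool("no2")[0]

    def test_no2_oxidation_ceases(self, pair):
        assert np.all(pair["knockout"].no2_ox_rate == 0.0)

    def test_control_nob_alive_throughout(self, pair):
        ct = pair["control"]
        nob = [a.functional_group is mt.FunctionalGroup.NOB for a in ct.analogs]
        assert np.all(ct.b_total[:, nob].sum(axis=1) > 0.0)

    def test_aoo_biomass_declines_after_knockout(self, pair):
        assert pair["aoo_final_biomass"] < 0.5 * pair["aoo_steady_biomass"]

    def test_knockout_cumulative_below_control(self, pair):
        assert (
            pair["knockout_rates"]["cumulative_n2o_n"]
            < pair["control_rates"]["cumulative_n2o_n"]
        )


@pytest.fixture(scope="module")
def result():
    return run_pulsed_substrate(ScenarioConfig(scenario_id="pulsed_substrate"))


class TestPulsedSubstrate:
    def test_evenness_declines_over_run(self, result):
        gb = result.guild_biomass()
        j_start = mt.evenness([gb[g][30] for g in gb])
        j_end = mt.evenness([gb[g][-1] for g in gb])
        assert j_end < j_start

    def test_n2o_pool_non_decreasing(self, result):
        assert np.all(np.diff(result.pool("n2o")) >= -1e-18)

    def test_aoa_gain_share_at_low_nh3_lose_after_pulses(self, result):
        gb = result.guild_biomass()
        aoo = [g for g in gb if g != "NOB(1)" and g != "NOB(2)" and g != "NOB(3)"]
        tot = sum(gb[g] for g in aoo)
        share = gb["AOA"] / tot
        free = nh3_fraction(7.8) * result.pool("tan")
        # share rises while free NH3 is drawn below the initial 1e-6 M
        assert free[55] < 1e-6 and share[55] > 1.5 * share[0]
        # large pulses (5e-5) inhibit the AOA; share collapses by the end
        assert share[-1] < 0.25 * share.max()

    def test_substrate_drawdown_between_pulses(self, result):
        tan = result.pool("tan")
        assert tan[59] < tan[0]          # first low-amplitude phase drawn down
        assert tan[121] > tan[119]       # pulse at day 120 visible


@pytest.fixture(scope="module")
def sites():
    return run_site_comparison()


class TestSiteComparison:
    def test_aob_dominate_high_tan_sites(self, sites):
        for name in ("Tussock Grassland", "Emergent Fen", "Rich Fen"):
            assert sites["sites"][name]["composition"].aoa_aob_ratio < 1.0

    def test_rate_increases_with_substrate(self, sites):
        assert sites["rate_tan_rank_correlation"] >= 0.8
        rates = {n: d["rates"]["max_nh3_ox_rate_smoothed"] for n, d in sites["sites"].items()}
        assert max(rates, key=rates.get) == "Emergent Fen"

    def test_fixtures_span_printed_ranges(self):
        fx = default_site_fixtures()
        assert len(fx) == 5
        tans = [s.tan for s in fx]
        phs = [s.ph for s in fx]
        assert min(tans) == pytest.approx(7.3e-3) and max(tans) == pytest.approx(0.1)
        assert all(4.3 <= p <= 4.8 for p in phs)
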