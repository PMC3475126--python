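"""Pre-configured simulation protocols.

Five experiment designs: a pH gradient (neutral to acid), a temperature
gradient (5-30 C), forced decoupling of ammonia and nitrite oxidation (NOB
knockout vs control), pulsed substrate inputs over nine months, and a
site-comparison mode driven by user-supplied initial chemistry.

Convention: protocol ammonia concentrations (``nh3_init``, pulse amounts)
are free-NH3 values referred to the reference pH 7.8 and converted once to
the total-ammonium (TAN) pool; the same TAN is then used at every pH of a
gradient so that pH acts purely through speciation.  Site chemistry, by
contrast, is supplied directly as TAN (field ammonium measurements).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .diagnostics import CommunitySummary, composition, rate_summary
from .dynamics import (
    CommunityState,
    PulseEvent,
    SolverOptions,
    TimeSeriesResult,
    apply_knockout,
    initial_community,
    integrate,
)
from .environment import EnvironmentState, nh3_fraction
from .params import DEFAULT_PARAMS, ModelParams
from .traits import (
    Distribution,
    FunctionalGroup,
    GuildAnalog,
    GuildTraits,
    default_guilds,
    mean_traits,
    sample_analogs,
)

__all__ = [
    "ScenarioConfig",
    "SiteConfig",
    "build_analogs",
    "run_ph_gradient",
    "run_temperature_gradient",
    "run_decoupling",
    "run_pulsed_substrate",
    "run_site_comparison",
    "default_site_fixtures",
    "SCENARIOS",
]

REFERENCE_PH = 7.8
C0 = 273.15

# protocol reference temperatures (Celsius) when the config leaves it unset
SCENARIO_TEMP_C = {
    "ph_gradient": 25.0,
    "pulsed_substrate": 25.0,
    "decoupling": 20.0,
    "site_comparison": 15.0,
    "temperature_gradient": 25.0,
}


def _temp_c(config: "ScenarioConfig") -> float:
    if config.temperature_c is not None:
        return config.temperature_c
    return SCENARIO_TEMP_C.get(config.scenario_id, 25.0)

PH_RANGE = (4.5, 7.8)
DEFAULT_PH_VALUES = (7.8, 7.0, 6.5, 6.0, 5.5, 5.0, 4.5)
DEFAULT_TEMPS_C = (5, 10, 15, 20, 25, 30)


def _tan_from_free_nh3(nh3_free: float, reference_ph: float = REFERENCE_PH) -> float:
    return nh3_free / nh3_fraction(reference_ph)


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything needed to reproduce a scenario run."""

    scenario_id: str
    seed: int = 0
    duration: float = 180.0
    trait_mode: str = "mean"  # "mean" | "monte_carlo"
    n_analogs: int = 5
    n_replicates: int = 3
    distribution: Distribution = Distribution.UNIFORM
    ph_values: tuple[float, ...] = DEFAULT_PH_VALUES
    temperatures_c: tuple[float, ...] = DEFAULT_TEMPS_C
    ph: float = REFERENCE_PH
    temperature_c: float | None = None  # per-scenario default when None
    nh3_init: float = 1.0e-5  # free NH3 at the reference pH, M
    o2: float = 1.0e-3
    co2: float = 1.0e-3
    pulse_times: tuple[float, ...] = (60.0, 120.0)
    pulse_amounts: tuple[float, ...] = (1.0e-6, 1.0e-6)  # free NH3 equivalents
    replenish_o2: bool = True
    replenish_co2: bool = True
    knockout_group: str | None = None
    solver: SolverOptions = field(default_factory=SolverOptions)

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.trait_mode not in ("mean", "monte_carlo"):
            raise ValueError("trait_mode must be 'mean' or 'monte_carlo'")
        if self.trait_mode == "monte_carlo" and self.n_analogs < 1:
            raise ValueError("monte_carlo mode requires n_analogs >= 1")
        if len(self.pulse_times) != len(self.pulse_amounts):
            raise ValueError("pulse_times and pulse_amounts must align")
        if self.scenario_id == "ph_gradient":
            for ph in self.ph_values:
                if not PH_RANGE[0] <= ph <= PH_RANGE[1]:
                    raise ValueError(f"pH {ph} outside the gradient range {PH_RANGE}")


@dataclass(frozen=True)
class SiteConfig:
    """Initial chemistry of one site (synthetic stand-ins, see fixtures)."""

    name: str
    tan: float  # M, field ammonium
    ph: float
    temperature_c: float = 15.0


def build_analogs(
    guilds: Sequence[GuildTraits],
    mode: str,
    n_analogs: int,
    seed: int,
    distribution: Distribution = Distribution.UNIFORM,
) -> list[GuildAnalog]:
    """Instantiate analogs for every guild; mean-trait or Monte Carlo mode.

    The master seed spawns one independent substream per guild, so adding
    guilds or replicates never perturbs existing draws.
    """
    if mode == "mean":
        return [mean_traits(g) for g in guilds]
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(guilds))
    out: list[GuildAnalog] = []
    for g, child in zip(guilds, children):
        g = g.with_distribution(distribution)
        out.extend(sample_analogs(g, n_analogs, np.random.default_rng(child)))
    return out


def _pulses(config: ScenarioConfig) -> list[PulseEvent]:
    f = nh3_fraction(REFERENCE_PH)
    return [
        PulseEvent(time=t, amount=a / f)
        for t, a in zip(config.pulse_times, config.pulse_amounts)
        if t <= config.duration
    ]


def _run_single(
    config: ScenarioConfig,
    analogs: Sequence[GuildAnalog],
    ph: float,
    temperature_c: float,
    tan: float | None = None,
    params: ModelParams = DEFAULT_PARAMS,
    pulses: Sequence[PulseEvent] | None = None,
    duration: float | None = None,
) -> TimeSeriesResult:
    env = EnvironmentState(
        tan=_tan_from_free_nh3(config.nh3_init) if tan is None else tan,
        o2=config.o2,
        co2=config.co2,
        ph=ph,
        temperature=temperature_c + C0,
    )
    state = initial_community(analogs, env, params)
    return integrate(
        state,
        duration=config.duration if duration is None else duration,
        params=params,
        pulses=_pulses(config) if pulses is None else pulses,
        replenish_o2=config.replenish_o2,
        replenish_co2=config.replenish_co2,
        solver=config.solver,
    )


def run_ph_gradient(
    config: ScenarioConfig,
    params: ModelParams = DEFAULT_PARAMS,
    guilds: Sequence[GuildTraits] | None = None,
) -> dict[float, dict]:
    """Six-month runs across the pH gradient; per-pH series and diagnostics."""
    guilds = list(guilds) if guilds is not None else default_guilds()
    analogs = build_analogs(
        guilds, config.trait_mode, config.n_analogs, config.seed, config.distribution
    )
    out: dict[float, dict] = {}
    for ph in config.ph_values:
        res = _run_single(config, analogs, ph, _temp_c(config), params=params)
        out[ph] = {
            "result": res,
            "composition": composition(res),
            "rates": rate_summary(res),
        }
    return out


def run_temperature_gradient(
    config: ScenarioConfig,
    params: ModelParams = DEFAULT_PARAMS,
    guilds: Sequence[GuildTraits] | None = None,
) -> dict[float, dict]:
    """Runs at each temperature (Celsius) at pH 7.8, NH3 = 5e-5 M."""
    guilds = list(guilds) if guilds is not None else default_guilds()
    analogs = build_analogs(
        guilds, config.trait_mode, config.n_analogs, config.seed, config.distribution
    )
    cfg = replace(config, nh3_init=5.0e-5, pulse_times=(), pulse_amounts=())
    out: dict[float, dict] = {}
    for t_c in config.temperatures_c:
        res = _run_single(cfg, analogs, cfg.ph, t_c, params=params)
        out[t_c] = {
            "result": res,
            "composition": composition(res),
            "rates": rate_summary(res),
        }
    return out


def run_decoupling(
    config: ScenarioConfig,
    params: ModelParams = DEFAULT_PARAMS,
    guilds: Sequence[GuildTraits] | None = None,
) -> dict:
    """Spin up to steady state, then knock out NOB vs an undisturbed control.

    Replicates differ by trait-sampling seed (one analog per guild drawn from
    the trait ranges unless the config requests mean traits, in which case a
    single deterministic pair is run).
    """
    guilds = list(guilds) if guilds is not None else default_guilds()
    n_rep = 1 if config.trait_mode == "mean" else max(config.n_replicates, 1)
    rep_seeds = np.random.SeedSequence(config.seed).spawn(n_rep)
    pairs = []
    for rep, rep_ss in enumerate(rep_seeds):
        if config.trait_mode == "mean":
            analogs = build_analogs(guilds, "mean", 1, config.seed)
        else:
            analogs = build_analogs(
                guilds, "monte_carlo", config.n_analogs,
                rep_ss.generate_state(1)[0] % (2**31), config.distribution,
            )
        spinup = _run_single(
            config, analogs, config.ph, _temp_c(config), params=params,
            pulses=[], duration=config.duration,
        )
        steady = spinup.final_state(
            initial_community(analogs, EnvironmentState(
                tan=0, ph=config.ph, temperature=_temp_c(config) + C0,
                o2=config.o2, co2=config.co2,
            ), params)
        )
        aoo_steady = steady.group_biomass(FunctionalGroup.AOB) + steady.group_biomass(
            FunctionalGroup.AOA
        )
        knocked = apply_knockout(steady, FunctionalGroup.NOB)
        arm_kwargs = dict(
            params=params, pulses=[],
            replenish_o2=config.replenish_o2, replenish_co2=config.replenish_co2,
            solver=config.solver,
        )
        ko = integrate(knocked, config.duration, knockout=[FunctionalGroup.NOB], **arm_kwargs)
        ctrl = integrate(steady, config.duration, **arm_kwargs)
        aoo_final = (
            ko.b_total[-1][[a.functional_group.is_aoo for a in analogs]].sum()
        )
        pairs.append({
            "replicate": rep,
            "knockout": ko,
            "control": ctrl,
            "knockout_rates": rate_summary(ko),
            "control_rates": rate_summary(ctrl),
            "aoo_steady_biomass": float(aoo_steady),
            "aoo_final_biomass": float(aoo_final),
        })
    return {"replicates": pairs}


def run_pulsed_substrate(
    config: ScenarioConfig | None = None,
    params: ModelParams = DEFAULT_PARAMS,
    guilds: Sequence[GuildTraits] | None = None,
) -> TimeSeriesResult:
    """Nine-month run at pH 7.8, 25 C with substrate pulses stepping up
    from 1e-6 through 5e-6 to 5e-5 M on two-month cycles."""
    if config is None:
        config = ScenarioConfig(scenario_id="pulsed_substrate")
    cfg = replace(
        config,
        duration=270.0,
        nh3_init=1.0e-6,
        pulse_times=(60.0, 120.0, 180.0, 240.0),
        pulse_amounts=(5.0e-6, 5.0e-5, 5.0e-5, 5.0e-5),
    ) if config.scenario_id == "pulsed_substrate" and config.duration == 180.0 else config
    guilds = list(guilds) if guilds is not None else default_guilds()
    analogs = build_analogs(
        guilds, cfg.trait_mode, cfg.n_analogs, cfg.seed, cfg.distribution
    )
    return _run_single(cfg, analogs, cfg.ph, _temp_c(cfg), params=params)


def default_site_fixtures() -> list[SiteConfig]:
    """Five synthetic site configurations spanning acid, ammonium-rich soils
    (TAN 7.3e-3 to 0.1 M, pH 4.3-4.8); illustrative stand-ins, not field data."""
    return [
        SiteConfig("Black Spruce", tan=7.3e-3, ph=4.3),
        SiteConfig("Bog Birch", tan=1.5e-2, ph=4.5),
        SiteConfig("Rich Fen", tan=3.0e-2, ph=4.6),
        SiteConfig("Tussock Grassland", tan=5.0e-2, ph=4.45),
        SiteConfig("Emergent Fen", tan=1.0e-1, ph=4.8),
    ]


def run_site_comparison(
    site_configs: Sequence[SiteConfig] | None = None,
    config: ScenarioConfig | None = None,
    params: ModelParams = DEFAULT_PARAMS,
    guilds: Sequence[GuildTraits] | None = None,
) -> dict[str, dict]:
    """Per-site six-month runs (mean-trait and/or MC mode per config)."""
    from scipy import stats

    sites = list(site_configs) if site_configs is not None else default_site_fixtures()
    if config is None:
        config = ScenarioConfig(scenario_id="site_comparison", pulse_times=(), pulse_amounts=())
    guilds = list(guilds) if guilds is not None else default_guilds()
    analogs = build_analogs(
        guilds, config.trait_mode, config.n_analogs, config.seed, config.distribution
    )
    out: dict[str, dict] = {}
    for site in sites:
        res = _run_single(
            config, analogs, site.ph, site.temperature_c, tan=site.tan,
            params=params, pulses=[],
        )
        comp = composition(res)
        rates = rate_summary(res)
        out[site.name] = {
            "site": site,
            "result": res,
            "composition": comp,
            "rates": rates,
        }
    tans = [s.tan for s in sites]
    ox = [out[s.name]["rates"]["max_nh3_ox_rate_smoothed"] for s in sites]
    rho = stats.spearmanr(tans, ox).statistic if len(sites) >= 3 else np.nan
    return {"sites": out, "rate_tan_rank_correlation": float(rho)}


def _run_sites_from_config(config: ScenarioConfig, params: ModelParams = DEFAULT_PARAMS):
    return run_site_comparison(site_configs=None, config=config, params=params)


SCENARIOS = {
    "ph_gradient": run_ph_gradient,
    "temperature_gradient": run_temperature_gradient,
    "decoupling": run_decoupling,
    "pulsed_substrate": run_pulsed_substrate,
    "site_comparison": _run_sites_from_config,
}
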