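"""Coupled community-chemistry ODE system and its integration.

State layout: seven dissolved pools (TAN, NO2-, NO, N2O-N, NO3-, O2, CO2)
followed by (B_T, B_C, B_N) for every guild analog.  Nitrogen is conserved
exactly by construction in a closed run (mortality recycles biomass N to the
TAN pool, detoxification returns the N content of degraded biomass); carbon
moves between the CO2 pool and biomass carbon.  O2 and CO2 are held at their
initial, non-limiting concentrations by default (replenished chemostat-
style); a scenario may disable replenishment to let oxidation draw them down.

Integration is adaptive and stiff-capable (LSODA), stopped and restarted at
every discrete event (substrate pulse, knockout) with daily dense output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .detox import BIOMASS_C_PER_N
from .environment import POOLS, EnvironmentState, nh3_fraction, temperature_factor
from .kinetics import UM, GuildState
from .params import DEFAULT_PARAMS, ModelParams
from .traits import FunctionalGroup, GuildAnalog

__all__ = [
    "CommunityState",
    "PulseEvent",
    "TimeSeriesResult",
    "SolverOptions",
    "derivatives",
    "integrate",
    "apply_knockout",
    "running_average",
    "detect_steady_state",
]

N_POOLS = len(POOLS)


@dataclass(frozen=True)
class PulseEvent:
    """Instantaneous addition to a dissolved pool at a given time (days)."""

    time: float
    amount: float  # M added
    pool: str = "tan"

    def __post_init__(self) -> None:
        if self.amount <= 0:
            raise ValueError("pulse amount must be positive")
        if self.pool not in POOLS:
            raise ValueError(f"unknown pool {self.pool!r}")


@dataclass(frozen=True)
class SolverOptions:
    rtol: float = 1.0e-7
    atol: float = 1.0e-16
    method: str = "LSODA"
    max_step: float = np.inf


@dataclass
class CommunityState:
    """Per-analog biomass states plus the chemical environment."""

    analogs: list[GuildAnalog]
    guild_states: list[GuildState]
    environment: EnvironmentState

    def __post_init__(self) -> None:
        if len(self.analogs) != len(self.guild_states):
            raise ValueError("one GuildState per analog required")

    @property
    def n_analogs(self) -> int:
        return len(self.analogs)

    def biomass_vector(self) -> np.ndarray:
        out = np.empty(3 * self.n_analogs)
        for i, gs in enumerate(self.guild_states):
            out[3 * i : 3 * i + 3] = (gs.b_total, gs.b_carbon, gs.b_nitrogen)
        return out

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.environment.as_vector(), self.biomass_vector()])

    def with_vector(self, y: np.ndarray) -> "CommunityState":
        env = self.environment.with_pools(y[:N_POOLS])
        states = [
            GuildState(*(float(v) for v in y[N_POOLS + 3 * i : N_POOLS + 3 * i + 3]))
            for i in range(self.n_analogs)
        ]
        return CommunityState(self.analogs, states, env)

    @property
    def total_n(self) -> float:
        """Nitrogen atoms in pools plus biomass N (M)."""
        return self.environment.total_n + sum(g.b_nitrogen for g in self.guild_states)

    def group_biomass(self, group: FunctionalGroup) -> float:
        return sum(
            gs.b_total
            for a, gs in zip(self.analogs, self.guild_states)
            if a.functional_group is group
        )


def initial_community(
    analogs: Sequence[GuildAnalog],
    environment: EnvironmentState,
    params: ModelParams = DEFAULT_PARAMS,
) -> CommunityState:
    """Equal inoculum for every analog at the default quotas."""
    b = params.init_biomass
    gs = [GuildState(b, b * params.init_qc, b * params.init_qn) for _ in analogs]
    return CommunityState(list(analogs), gs, environment)


class _System:
    """Vectorized RHS over all analogs at fixed pH and temperature."""

    def __init__(
        self,
        analogs: Sequence[GuildAnalog],
        environment: EnvironmentState,
        params: ModelParams,
        replenish_o2: bool = True,
        replenish_co2: bool = True,
        knockout: Sequence[FunctionalGroup] = (),
    ):
        self.params = params
        self.analogs = list(analogs)
        n = len(self.analogs)
        self.n = n
        self.f_nh3 = nh3_fraction(environment.ph, params.pka_nh4)
        self.replenish_o2 = replenish_o2
        self.replenish_co2 = replenish_co2

        self.vmax = np.array([a.vmax_substrate for a in self.analogs])
        self.km_m = np.array([a.km_substrate for a in self.analogs]) * UM
        self.kmo2_m = np.array([a.km_o2 for a in self.analogs]) * UM
        self.mu_max = np.array([a.mu_max for a in self.analogs])
        self.yield_co2 = np.array([a.yield_co2_per_n for a in self.analogs])
        self.ki_m = np.array(
            [np.inf if a.ki_nh3 is None else a.ki_nh3 * UM for a in self.analogs]
        )
        self.is_aoo = np.array(
            [a.functional_group.is_aoo for a in self.analogs], dtype=bool
        )
        self.is_nob = ~self.is_aoo
        self.tf = np.array(
            [temperature_factor(environment.temperature, a, params) for a in self.analogs]
        )
        self.alive = np.array(
            [a.functional_group not in knockout for a in self.analogs], dtype=bool
        )

    def fluxes(self, y: np.ndarray) -> dict[str, np.ndarray]:
        p = self.params
        q = p.quota
        y = np.maximum(y, 0.0)
        tan, no2, no, _n2o, _no3, o2, co2 = y[:N_POOLS]
        b_t = y[N_POOLS::3] * self.alive
        b_c = y[N_POOLS + 1 :: 3] * self.alive
        b_n = y[N_POOLS + 2 :: 3] * self.alive

        live = b_t > p.extinction_floor
        b_t = np.where(live, b_t, 0.0)
        qc = np.where(live, b_c / np.maximum(b_t, 1e-300), p.init_qc)
        qn = np.where(live, b_n / np.maximum(b_t, 1e-300), p.init_qn)

        nh3 = self.f_nh3 * tan
        o2_eff = max(o2, p.o2_floor)
        o2_mm = o2 / (self.kmo2_m + o2) if o2 > 0 else np.zeros(self.n)

        # substrate oxidation (energy-yielding)
        km_eff = self.km_m * np.where(
            self.is_aoo, 1.0 + p.kd_max * (no2 + no) / o2_eff, 1.0
        )
        bh = nh3 / (km_eff + nh3 * (1.0 + nh3 / self.ki_m)) if nh3 > 0 else 0.0
        v_nh3 = np.where(self.is_aoo, self.tf * self.vmax * bh * o2_mm * b_t, 0.0)
        mm_no2 = no2 / (self.km_m + no2) if no2 > 0 else 0.0
        v_no2 = np.where(self.is_nob, self.tf * self.vmax * mm_no2 * o2_mm * b_t, 0.0)
        v_sub = v_nh3 + v_no2

        # detoxification (AOO only); sigmoidal stress induction in the toxin
        o2_inhib = p.k_o2_detox / (p.k_o2_detox + o2)
        v_det = p.v_detox_scale * self.vmax * b_t * o2_inhib
        kh2 = p.k_detox**p.detox_hill
        khn = p.k_detox_no**p.detox_hill
        hill_no2 = no2**p.detox_hill / (kh2 + no2**p.detox_hill) if no2 > 0 else 0.0
        hill_no = no**p.detox_hill / (khn + no**p.detox_hill) if no > 0 else 0.0
        d_no2 = np.where(self.is_aoo, v_det * hill_no2, 0.0)
        d_no = np.where(self.is_aoo, v_det * hill_no, 0.0)
        cost = BIOMASS_C_PER_N * (d_no2 + d_no)

        # carbon fixation, energy-coupled to realized oxidation
        r_cn = qc / np.maximum(qn, 1e-12)
        ramp = np.clip(1.0 - (r_cn - q.rcn_min) / (q.rcn_max - q.rcn_min), 0.0, 1.0)
        co2_mm = co2 / (p.km_co2 + co2) if co2 > 0 else 0.0
        v_co2 = self.yield_co2 / q.qn_max * ramp * co2_mm * v_sub

        # N assimilation into biomass: transporter-limited TAN uptake,
        # down-regulated as the nitrogen quota fills
        headroom = np.clip((q.qn_max - qn) / (q.qn_max - q.qn_min), 0.0, 1.0)
        tan_mm = tan / (p.km_assim + tan) if tan > 0 else 0.0
        v_n = p.n_uptake_scale * self.tf * self.vmax * b_t * tan_mm * headroom

        # division (Droop x Liebig)
        d_c = np.maximum(1.0 - q.qc_min / np.maximum(qc, 1e-12), 0.0)
        d_n = np.maximum(1.0 - q.qn_min / np.maximum(qn, 1e-12), 0.0)
        division = self.tf * self.mu_max * np.minimum(d_c, d_n) * b_t

        hydrox = p.hydroxylamine_fraction * v_nh3

        return {
            "b_t": b_t, "b_c": b_c, "b_n": b_n, "qc": qc, "qn": qn,
            "v_nh3": v_nh3, "v_no2": v_no2, "v_co2": v_co2, "v_n": v_n,
            "d_no2": d_no2, "d_no": d_no, "cost": cost,
            "division": division, "hydrox": hydrox,
        }

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        p = self.params
        f = self.fluxes(y)
        mort = p.mortality
        b_t, b_c, b_n = f["b_t"], f["b_c"], f["b_n"]
        qc, qn = f["qc"], f["qn"]
        cost = f["cost"]

        dy = np.empty_like(y)
        d_pools = dy[:N_POOLS]
        d_pools[0] = (
            -f["v_nh3"].sum()
            - f["v_n"].sum()
            + mort * b_n.sum()
            + (cost * qn).sum()
        )
        d_pools[1] = (f["v_nh3"] - f["hydrox"]).sum() - f["v_no2"].sum() - f["d_no2"].sum()
        d_pools[2] = f["d_no2"].sum() - f["d_no"].sum()
        d_pools[3] = f["hydrox"].sum() + f["d_no"].sum()
        d_pools[4] = f["v_no2"].sum()
        d_pools[5] = (
            0.0
            if self.replenish_o2
            else -(p.o2_per_nh3 * f["v_nh3"].sum() + p.o2_per_no2 * f["v_no2"].sum())
        )
        d_pools[6] = (
            0.0
            if self.replenish_co2
            else -f["v_co2"].sum() + mort * b_c.sum() + (cost * qc).sum()
        )

        dy[N_POOLS::3] = f["division"] - mort * b_t - cost
        dy[N_POOLS + 1 :: 3] = f["v_co2"] - mort * b_c - cost * qc
        dy[N_POOLS + 2 :: 3] = f["v_n"] - mort * b_n - cost * qn
        # extinct or knocked-out analogs stay at zero
        dead = ~(self.alive & (f["b_t"] > 0))
        for off in range(3):
            dy[N_POOLS + off :: 3][dead & (np.maximum(y[N_POOLS + off :: 3], 0.0) <= p.extinction_floor)] = 0.0
        return dy


@dataclass
class TimeSeriesResult:
    """Daily time series of a single integration.

    Arrays are indexed [time, analog] for per-analog quantities.  Rates are
    instantaneous fluxes re-evaluated at each output time; N2O pathways are
    reported separately (hydroxylamine vs detoxification), both in M N d-1.
    """

    time: np.ndarray
    analogs: list[GuildAnalog]
    pools: np.ndarray  # [time, 7], order as environment.POOLS
    b_total: np.ndarray
    b_carbon: np.ndarray
    b_nitrogen: np.ndarray
    nh3_ox_rate: np.ndarray
    no2_ox_rate: np.ndarray
    n2o_hydrox_rate: np.ndarray
    n2o_detox_rate: np.ndarray
    ph: float
    temperature: float

    @property
    def pool_index(self) -> dict[str, int]:
        return {p: i for i, p in enumerate(POOLS)}

    def pool(self, name: str) -> np.ndarray:
        return self.pools[:, self.pool_index[name]]

    @property
    def n2o_rate(self) -> np.ndarray:
        """Total N2O-N production rate summed over analogs, M d-1."""
        return (self.n2o_hydrox_rate + self.n2o_detox_rate).sum(axis=1)

    @property
    def nh3_ox_total(self) -> np.ndarray:
        return self.nh3_ox_rate.sum(axis=1)

    def guild_biomass(self) -> dict[str, np.ndarray]:
        """Per-guild B_T series (analogs summed within each parent guild)."""
        out: dict[str, np.ndarray] = {}
        for i, a in enumerate(self.analogs):
            out.setdefault(a.parent_guild, np.zeros(len(self.time)))
            out[a.parent_guild] += self.b_total[:, i]
        return out

    def final_state(self, template: CommunityState) -> CommunityState:
        y = np.concatenate([self.pools[-1], np.ravel(
            np.column_stack([self.b_total[-1], self.b_carbon[-1], self.b_nitrogen[-1]])
        )])
        return template.with_vector(y)

    @property
    def total_n_series(self) -> np.ndarray:
        n_pools = self.pools[:, [0, 1, 2, 3, 4]].sum(axis=1)
        return n_pools + self.b_nitrogen.sum(axis=1)


def derivatives(
    state: CommunityState,
    params: ModelParams = DEFAULT_PARAMS,
    replenish_o2: bool = True,
    replenish_co2: bool = True,
) -> np.ndarray:
    """Rate of change of the full state vector (pools then biomass triples)."""
    y = state.as_vector()
    if np.any(y < 0):
        raise ValueError("negative state rejected")
    sys = _System(state.analogs, state.environment, params, replenish_o2, replenish_co2)
    return sys.rhs(0.0, y)


def apply_knockout(state: CommunityState, group: FunctionalGroup) -> CommunityState:
    """Zero the biomass of every analog in ``group`` (held at zero thereafter)."""
    new_states = [
        GuildState(0.0, 0.0, 0.0) if a.functional_group is group else gs
        for a, gs in zip(state.analogs, state.guild_states)
    ]
    return CommunityState(state.analogs, new_states, state.environment)


def integrate(
    initial: CommunityState,
    duration: float,
    params: ModelParams = DEFAULT_PARAMS,
    pulses: Sequence[PulseEvent] = (),
    replenish_o2: bool = True,
    replenish_co2: bool = True,
    knockout: Sequence[FunctionalGroup] = (),
    solver: SolverOptions = SolverOptions(),
    output_dt: float = 1.0,
) -> TimeSeriesResult:
    """Integrate the community for ``duration`` days with daily output.

    Pulses are handled by stopping the solver, adding the pulse amount to its
    pool, and restarting.  States are clamped non-negative at output; any
    variable that falls below the extinction floor is set to zero.
    """
    for ev in pulses:
        if not 0.0 <= ev.time <= duration:
            raise ValueError(f"pulse at t={ev.time} outside run [0, {duration}]")

    sys = _System(
        initial.analogs, initial.environment, params,
        replenish_o2, replenish_co2, knockout,
    )
    y0 = initial.as_vector()
    if knockout:
        mask = np.repeat(~sys.alive, 3)
        y0[N_POOLS:][mask] = 0.0

    breakpoints = sorted({0.0, duration, *(ev.time for ev in pulses)})
    t_out = np.arange(0.0, duration + 0.5 * output_dt, output_dt)
    t_out[-1] = min(t_out[-1], duration)

    times: list[np.ndarray] = []
    states: list[np.ndarray] = []
    y = y0.copy()
    for t0, t1 in zip(breakpoints[:-1], breakpoints[1:]):
        if t1 <= t0:
            continue
        seg_eval = t_out[(t_out >= t0) & (t_out <= t1)]
        if len(seg_eval) == 0 or seg_eval[0] > t0:
            seg_eval = np.concatenate([[t0], seg_eval])
        if seg_eval[-1] < t1:
            seg_eval = np.concatenate([seg_eval, [t1]])
        sol = solve_ivp(
            sys.rhs, (t0, t1), y, t_eval=seg_eval,
            method=solver.method, rtol=solver.rtol, atol=solver.atol,
            max_step=solver.max_step,
        )
        if not sol.success:
            raise RuntimeError(
                f"solver failed at t={sol.t[-1] if len(sol.t) else t0:.3f} d: "
                f"{sol.message}; state snapshot: {y}"
            )
        times.append(sol.t)
        states.append(sol.y.T)
        y = sol.y[:, -1].copy()
        y = np.maximum(y, 0.0)
        y[y < params.extinction_floor] = 0.0
        for ev in pulses:
            if ev.time == t1:
                y[POOLS.index(ev.pool)] += ev.amount

    t_all = np.concatenate(times)
    y_all = np.concatenate(states, axis=0)
    # deduplicate breakpoints, keep daily grid
    keep = np.searchsorted(t_all, t_out)
    keep = np.minimum(keep, len(t_all) - 1)
    t_grid = t_all[keep]
    y_grid = np.maximum(y_all[keep], 0.0)
    y_grid[y_grid < params.extinction_floor] = 0.0

    n = len(initial.analogs)
    nt = len(t_grid)
    rates = {k: np.zeros((nt, n)) for k in ("v_nh3", "v_no2", "hydrox", "detox")}
    for j in range(nt):
        f = sys.fluxes(y_grid[j])
        rates["v_nh3"][j] = f["v_nh3"]
        rates["v_no2"][j] = f["v_no2"]
        rates["hydrox"][j] = f["hydrox"]
        rates["detox"][j] = f["d_no"]

    return TimeSeriesResult(
        time=t_grid,
        analogs=list(initial.analogs),
        pools=y_grid[:, :N_POOLS],
        b_total=y_grid[:, N_POOLS::3],
        b_carbon=y_grid[:, N_POOLS + 1 :: 3],
        b_nitrogen=y_grid[:, N_POOLS + 2 :: 3],
        nh3_ox_rate=rates["v_nh3"],
        no2_ox_rate=rates["v_no2"],
        n2o_hydrox_rate=rates["hydrox"],
        n2o_detox_rate=rates["detox"],
        ph=initial.environment.ph,
        temperature=initial.environment.temperature,
    )


def running_average(series: np.ndarray, window: int = 30) -> np.ndarray:
    """Trailing mean over ``window`` samples; shorter effective window at the start."""
    if window < 1:
        raise ValueError("window must be >= 1")
    series = np.asarray(series, dtype=float)
    c = np.cumsum(np.insert(series, 0, 0.0))
    out = np.empty_like(series)
    idx = np.arange(len(series))
    lo = np.maximum(idx - window + 1, 0)
    out = (c[idx + 1] - c[lo]) / (idx + 1 - lo)
    return out


def detect_steady_state(
    series: np.ndarray, tol: float = 1.0e-4, dt: float = 1.0
) -> float | None:
    """First time after which every surviving column's relative daily change < tol.

    ``series`` is [time, guild] (or 1-D); columns that end extinct (0) are
    ignored.  Returns the time in days, or None if never reached.
    """
    arr = np.atleast_2d(np.asarray(series, dtype=float).T).T
    nt = arr.shape[0]
    if nt < 2:
        return 0.0
    surviving = arr[-1] > 0
    if not surviving.any():
        return None
    a = arr[:, surviving]
    rel = np.abs(np.diff(a, axis=0)) / np.maximum(np.abs(a[:-1]), 1e-300) / dt
    ok = (rel < tol).all(axis=1)
    # find first index from which ok holds to the end
    bad = np.where(~ok)[0]
    first = 0 if len(bad) == 0 else bad[-1] + 1
    if first >= nt - 1 and not ok[-1]:
        return None
    return float(first * dt)
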