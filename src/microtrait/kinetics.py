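"""Per-guild instantaneous rate laws.

Pure functions: Droop quota limitation of cell division, Briggs-Haldane NH3
oxidation (high-substrate inhibition), Michaelis-Menten NO2 and CO2 uptake,
and the nitrite-stress inflation of the apparent NH3 half-saturation.

Units: concentrations in M; half-saturation trait values in uM (converted
internally); biomass-specific rates in d-1; fluxes in M d-1.
"""

from __future__ import annotations

from dataclasses import dataclass

from .params import DEFAULT_PARAMS, ModelParams, QuotaConstants
from .traits import GuildAnalog

__all__ = [
    "GuildState",
    "QuotaConstants",
    "droop_limitation",
    "division_rate",
    "effective_km_nh3",
    "nh3_uptake_rate",
    "no2_uptake_rate",
    "co2_vmax",
    "co2_uptake_rate",
]

UM = 1.0e-6  # uM -> M


@dataclass
class GuildState:
    """Biomass triple of one analog: total (B_T), carbon (B_C), nitrogen (B_N), M."""

    b_total: float
    b_carbon: float
    b_nitrogen: float

    def __post_init__(self) -> None:
        if min(self.b_total, self.b_carbon, self.b_nitrogen) < 0:
            raise ValueError("biomass components must be non-negative")

    @property
    def q_c(self) -> float:
        return self.b_carbon / self.b_total if self.b_total > 0 else 0.0

    @property
    def q_n(self) -> float:
        return self.b_nitrogen / self.b_total if self.b_total > 0 else 0.0


def droop_limitation(q: float, q_min: float) -> float:
    """Droop division-limitation factor max(1 - q_min/q, 0)."""
    if q <= 0:
        raise ValueError("quota must be positive")
    return max(1.0 - q_min / q, 0.0)


def division_rate(mu_max: float, d_c: float, d_n: float, b_total: float) -> float:
    """Cell division flux (M d-1): mu_max * min(d_C, d_N) * B_T (Liebig minimum)."""
    return mu_max * min(d_c, d_n) * b_total


def effective_km_nh3(
    km_base_um: float,
    toxin_conc: float,
    o2: float,
    kd_max: float = DEFAULT_PARAMS.kd_max,
    o2_floor: float = DEFAULT_PARAMS.o2_floor,
) -> float:
    """Apparent NH3 half-saturation (uM) inflated by nitrite/NO stress.

    K_M = K_M_base * (1 + kd_max * [C]/[O2]) with [C] = [NO2-] + [NO] (M).
    """
    o2_eff = max(o2, o2_floor)
    return km_base_um * (1.0 + kd_max * toxin_conc / o2_eff)


def nh3_uptake_rate(
    analog: GuildAnalog,
    nh3_free: float,
    o2: float,
    b_total: float,
    km_eff_um: float | None = None,
    temp_factor: float = 1.0,
) -> float:
    """NH3 oxidation flux (M N d-1) with Briggs-Haldane substrate inhibition.

    V = tf * Vmax * [NH3] / (K_M + [NH3] (1 + [NH3]/K_i)) * [O2]/(K_M^O2+[O2]) * B_T
    """
    if nh3_free <= 0 or b_total <= 0:
        return 0.0
    km = (analog.km_substrate if km_eff_um is None else km_eff_um) * UM
    ki = float("inf") if analog.ki_nh3 is None else analog.ki_nh3 * UM
    denom = km + nh3_free * (1.0 + nh3_free / ki)
    o2_term = o2 / (analog.km_o2 * UM + o2) if o2 > 0 else 0.0
    return temp_factor * analog.vmax_substrate * (nh3_free / denom) * o2_term * b_total


def no2_uptake_rate(
    analog: GuildAnalog,
    no2: float,
    o2: float,
    b_total: float,
    temp_factor: float = 1.0,
) -> float:
    """NO2- oxidation flux (M N d-1), Michaelis-Menten in NO2 and O2."""
    if no2 <= 0 or b_total <= 0:
        return 0.0
    km = analog.km_substrate * UM
    o2_term = o2 / (analog.km_o2 * UM + o2) if o2 > 0 else 0.0
    return temp_factor * analog.vmax_substrate * (no2 / (km + no2)) * o2_term * b_total


def co2_vmax(
    analog: GuildAnalog,
    r_cn: float,
    quota: QuotaConstants = DEFAULT_PARAMS.quota,
) -> float:
    """CO2-fixation capacity (d-1) per unit realized oxidation rate scale.

    Vmax^CO2 = Y_N^CO2 * Vmax_substrate / Q_N^max * ramp(r_CN), where the
    linear ramp down-regulates C uptake from full at r_CN = 6.6 to zero at
    r_CN = 13.2 (cells stop storing carbon at their maximum C:N).
    """
    if r_cn <= 0:
        raise ValueError("C:N ratio must be positive")
    ramp = max(1.0 - (r_cn - quota.rcn_min) / (quota.rcn_max - quota.rcn_min), 0.0)
    ramp = min(ramp, 1.0)
    return analog.yield_co2_per_n * analog.vmax_substrate / quota.qn_max * ramp


def co2_uptake_rate(vmax_co2: float, co2: float, km_co2: float, b_total: float) -> float:
    """CO2 fixation flux (M C d-1), Michaelis-Menten in CO2, scaled by biomass."""
    if co2 <= 0 or b_total <= 0:
        return 0.0
    return vmax_co2 * co2 / (km_co2 + co2) * b_total
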