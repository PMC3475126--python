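"""N2O production pathways of the ammonia oxidizers.

Two routes: (1) a fixed small fraction of the NH3 oxidation flux lost as N2O
during hydroxylamine decomposition, and (2) nitrite detoxification, in which
accumulated NO2- is reduced to N2O via NO at the cost of cellular biomass
carbon (4 NO2- + CH2O -> 4 NO + CO2 + 3 H2O; 8 NO + 2 CH2O -> 4 N2O + 2 CO2
+ 2 H2O, i.e. 1/4 mol biomass-C per mol N reduced in each step).  The
detox pathway engages only when NO2-/NO build up (mM-scale half-saturation)
and is strongly suppressed by O2.
"""

from __future__ import annotations

from dataclasses import dataclass

from .environment import EnvironmentState
from .kinetics import GuildState
from .params import DEFAULT_PARAMS, ModelParams
from .traits import GuildAnalog

__all__ = ["DetoxFluxes", "hydroxylamine_n2o_rate", "detox_fluxes"]

BIOMASS_C_PER_N = 0.25  # mol biomass-C consumed per mol NO2- (or NO) reduced


@dataclass(frozen=True)
class DetoxFluxes:
    """Detoxification fluxes (M d-1): NO2->NO, NO->N2O, and the biomass-C cost."""

    d_no2: float
    d_no: float

    @property
    def biomass_cost(self) -> float:
        """Biomass-C consumed: (D^NO2 + D^NO) / 4."""
        return BIOMASS_C_PER_N * (self.d_no2 + self.d_no)

    @property
    def n2o_n_rate(self) -> float:
        """N2O production in N atoms: every N leaving the NO pool ends in N2O."""
        return self.d_no


def hydroxylamine_n2o_rate(nh3_ox_rate: float, fraction: float = DEFAULT_PARAMS.hydroxylamine_fraction) -> float:
    """N2O-N produced by hydroxylamine decomposition: fraction * NH3 oxidation flux."""
    if not 0.0 <= fraction <= 0.05:
        raise ValueError("hydroxylamine fraction must lie in [0, 0.05]")
    return fraction * nh3_ox_rate


def detox_fluxes(
    analog: GuildAnalog,
    state: EnvironmentState,
    guild_state: GuildState,
    params: ModelParams = DEFAULT_PARAMS,
) -> DetoxFluxes:
    """Detoxification fluxes for one AOO analog.

    Each step follows a sigmoidal (Hill) induction in its substrate pool —
    the pathway is stress-induced, switching on only as the toxin approaches
    its half-induction concentration (``k_detox`` for NO2-, ``k_detox_no``
    for NO) — and is damped by O2 (factor K/(K+[O2]), K = ``k_o2_detox``).
    The maximum specific rate is ``v_detox_scale`` x the analog's Vmax.
    """
    if not analog.functional_group.is_aoo:
        return DetoxFluxes(0.0, 0.0)
    b = guild_state.b_total
    if b <= 0:
        return DetoxFluxes(0.0, 0.0)
    v = params.v_detox_scale * analog.vmax_substrate * b
    o2_inhib = params.k_o2_detox / (params.k_o2_detox + max(state.o2, 0.0))
    h = params.detox_hill

    def hill(c: float, k: float) -> float:
        return c**h / (k**h + c**h) if c > 0 else 0.0

    return DetoxFluxes(
        v * hill(state.no2, params.k_detox) * o2_inhib,
        v * hill(state.no, params.k_detox_no) * o2_inhib,
    )
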