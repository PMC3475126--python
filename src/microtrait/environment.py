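"""Chemical environment: pools, NH3 speciation, and temperature response.

pH acts on the community only through acid-base speciation of total
ammoniacal nitrogen (TAN = NH4+ + NH3): the ammonia monooxygenase substrate
is free NH3, whose fraction falls ~10x per pH unit below the pKa.  Guild
temperature niches follow a Ratkowsky-type square-root response anchored on
each guild's temperature window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .params import DEFAULT_PARAMS, ModelParams
from .traits import GuildAnalog

__all__ = ["EnvironmentState", "nh3_fraction", "temperature_factor"]

POOLS = ("tan", "no2", "no", "n2o", "no3", "o2", "co2")


@dataclass
class EnvironmentState:
    """Chemical pools (M), pH, and temperature (K).

    ``n2o`` is accounted in nitrogen atoms (M of N2O-N) so that nitrogen
    bookkeeping stays linear.
    """

    tan: float = 0.0
    no2: float = 0.0
    no: float = 0.0
    n2o: float = 0.0
    no3: float = 0.0
    o2: float = 1.0e-3
    co2: float = 1.0e-3
    ph: float = 7.8
    temperature: float = 293.15

    def __post_init__(self) -> None:
        for name in POOLS:
            if getattr(self, name) < 0:
                raise ValueError(f"pool {name} must be non-negative")
        if not 0.0 <= self.ph <= 14.0:
            raise ValueError("pH must lie in [0, 14]")

    @property
    def nh3_free(self) -> float:
        """Free NH3 concentration (M) at the current pH."""
        return nh3_fraction(self.ph) * self.tan

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, p) for p in POOLS])

    def with_pools(self, vec: np.ndarray) -> "EnvironmentState":
        return replace(self, **{p: float(v) for p, v in zip(POOLS, vec)})

    @property
    def total_n(self) -> float:
        """Nitrogen atoms summed over dissolved pools (M)."""
        return self.tan + self.no2 + self.no + self.n2o + self.no3


def nh3_fraction(ph: float, pka: float = DEFAULT_PARAMS.pka_nh4) -> float:
    """Fraction of TAN present as free NH3: 1 / (1 + 10^(pKa - pH))."""
    return 1.0 / (1.0 + 10.0 ** (pka - ph))


def temperature_factor(
    temperature: float,
    guild: GuildAnalog,
    params: ModelParams = DEFAULT_PARAMS,
) -> float:
    """Guild activity multiplier in [0, 1].

    Square-root (Ratkowsky) response: sqrt(rate) grows linearly from
    T_min = window_low - 15 K, reaching 1 at the guild optimum (window high);
    above the optimum activity decays exponentially with a 4 K scale.
    """
    t_lo, t_opt = guild.temp_window
    t_min = t_lo - params.temp_tmin_offset
    if temperature <= t_min:
        return 0.0
    if temperature <= t_opt:
        ramp = (temperature - t_min) / (t_opt - t_min)
        return ramp * ramp
    return math.exp(-(temperature - t_opt) / params.temp_decay_scale)
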