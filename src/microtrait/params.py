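"""Global model constants and tunable closure parameters.

Everything the trait table does not provide lives here: quota bounds, the
NH3/NH4+ acid dissociation constant, mortality, the detoxification rate-law
constants, and numerical floors.  All concentrations are molar (M) and all
rates are per day unless noted.  See docs/methods.md for the rationale behind
each default.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class QuotaConstants:
    """Cellular stoichiometry bounds (Redfield-anchored)."""

    qc_min: float = 1.0          # minimum carbon quota (B_C/B_T)
    qn_min: float = 1.0 / 13.2   # minimum nitrogen quota (B_N/B_T)
    rcn_min: float = 6.6         # C:N at which N is replete
    rcn_max: float = 13.2        # C:N at which C uptake shuts off

    @property
    def qn_max(self) -> float:
        """Maximum nitrogen quota, reached at the Redfield C:N of 6.6."""
        return 1.0 / self.rcn_min


@dataclass(frozen=True)
class ModelParams:
    """Closure parameters of the community model."""

    quota: QuotaConstants = field(default_factory=QuotaConstants)

    # NH4+/NH3 speciation
    pka_nh4: float = 9.25  # at 298 K; Henderson-Hasselbalch

    # temperature response
    temp_tmin_offset: float = 15.0   # K below the window low where activity is zero
    temp_decay_scale: float = 4.0    # K; e-folding of the super-optimal decay

    # mortality (first order, all guilds); dead biomass N recycles to TAN
    mortality: float = 0.016  # d-1

    # N2O pathways
    hydroxylamine_fraction: float = 0.001  # N2O-N per NH3-N oxidized
    kd_max: float = 400.0        # dimensionless, Km inflation per unit [C]/[O2]
    v_detox_scale: float = 0.4   # v_detox^max = scale * vmax_substrate
    k_detox: float = 3.0e-5      # M; NO2- half-induction of the detox pathway
    k_detox_no: float = 6.0e-5   # M; NO half-induction of the NO -> N2O step
    detox_hill: float = 4.0      # Hill coefficient of detox induction by the toxin
    k_o2_detox: float = 1.0e-3   # M; O2 inhibition constant of the detox pathway

    # carbon acquisition
    km_co2: float = 1.0e-5  # M (10 uM), CO2 half-saturation

    # N assimilation into biomass
    km_assim: float = 1.0e-6  # M; Monod constant of TAN uptake into B_N
    n_uptake_scale: float = 0.1  # assimilation capacity as a fraction of vmax_substrate

    # O2 stoichiometry (mol O2 per mol N oxidized)
    o2_per_nh3: float = 1.5
    o2_per_no2: float = 0.5

    # numerics
    o2_floor: float = 1.0e-12       # M; divide-by-zero guard in [C]/[O2]
    extinction_floor: float = 1.0e-30  # M; states below this are clamped to 0
    conc_floor: float = 0.0

    # default inoculum per analog
    init_biomass: float = 1.0e-6  # M biomass-C equivalent (B_T units)
    init_qc: float = 1.0
    init_qn: float = 0.1


DEFAULT_PARAMS = ModelParams()
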