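# Methods

This note records the model equations as implemented, the closure choices
made where the underlying literature gives none, the default parameter
values with their rationale, and the known limitations. Everything stated
here is computed by the test suite or the acceptance script; nothing is
quoted from external data.

## State variables and units

All dissolved pools are molar (M): total ammoniacal nitrogen TAN
(NH₄⁺+NH₃), NO₂⁻, NO, N₂O (accounted in **nitrogen atoms** so that mass
balance stays linear), NO₃⁻, O₂, CO₂. Each guild analog carries three
biomass variables: total biomass B_T (a cell-quantity in biomass-C
equivalent units), stored carbon B_C and nitrogen B_N, with quotas
Q_C = B_C/B_T and Q_N = B_N/B_T. All rates are per day. Trait
half-saturation constants are stored in µM and converted internally.

Conservation is exact by construction: every N atom is in a dissolved pool
or in ΣB_N (mortality recycles B_N → TAN; detoxification returns the N
content of degraded biomass to TAN); every C atom is in the CO₂ pool or in
ΣB_C. A closed 180-day integration conserves total N to better than 1e-6
relative (tested).

## Growth

Division: D = μ_max · f(T) · min(1 − Q_C^min/Q_C, 1 − Q_N^min/Q_N) · B_T
with Q_C^min = 1, Q_N^min = 1/13.2; cellular C:N r_CN = Q_C/Q_N is bounded
in practice by the carbon-uptake ramp below (6.6 ≤ r_CN ≤ 13.2, the
Redfield-anchored range). Division dilutes quotas; B_T is not an element
and is not conserved.

Ammonia oxidation (AOB and AOA), Briggs–Haldane with O₂ limitation:

    V_NH3 = f(T) · Vmax · [NH3] / (K_M^eff + [NH3](1 + [NH3]/K_i))
                 · [O2]/(K_M^O2 + [O2]) · B_T

Free NH₃ is the substrate: [NH3] = TAN / (1 + 10^(pKa − pH)), pKa 9.25.
pH enters the model only through this speciation. Nitrite oxidation (NOB)
is the same law without substrate inhibition.

Carbon fixation is energy-coupled to the realized oxidation flux:

    V_CO2 = Y_N^CO2 · V_ox / Q_N^max · ramp(r_CN) · [CO2]/(K_M^CO2 + [CO2])

with Q_N^max = 1/6.6 and ramp(r) = clip(1 − (r − 6.6)/6.6, 0, 1). The
coupling to V_ox (rather than to a fixed Vmax capacity) is a deliberate
closure: a chemolithoautotroph cannot fix carbon without oxidizing its
energy substrate, and without this coupling substrate concentration would
not influence competition at all. Y_N^CO2 (0.01–0.09 mol CO₂ per mol N,
from the trait table) is the substrate-use efficiency.

Nitrogen assimilation into B_N is a transporter flux, deliberately cheap
and guild-blind in affinity: capacity 0.1 × Vmax, Monod in TAN
(K = 1 µM), down-regulated linearly as Q_N fills toward 1/6.6. Competition
between guilds therefore runs through the energy (free-NH₃) channel, which
is where the trait table differentiates them.

Mortality is first-order at Δ = 0.016 d⁻¹ for every guild. Two constraints
set this value: a starved population must decay below 10 % of its starting
biomass within a six-month simulation (Δ > ln 10/180 = 0.0128 d⁻¹ — the
post-knockout crash), and Δ must stay below the realized division rate of
the competitive guilds at reference conditions, which the Droop/ramp
machinery caps near 0.5·μ_max·f(T) ≈ 0.02–0.035 d⁻¹. The window is narrow;
0.016 sits in it with margin on both sides.

## Temperature

Guild windows (low, high) in Kelvin come from the trait table; the response
is a Ratkowsky-type square-root ramp anchored at T_min = low − 15 K and
normalized to 1 at the optimum (= high), with exponential decay of scale
4 K above the optimum:

    f(T) = ((T − T_min)/(T_opt − T_min))²   for T_min < T ≤ T_opt
    f(T) = exp(−(T − T_opt)/4)              for T > T_opt

This preserves the cold-adapted/mesophile rank reversals between 278 K and
303 K. Temperature scales V_max and μ_max identically; K_M values are
temperature-independent.

A consequence worth stating: the AOB(1) window (290–295 K) tops out below
the 299 K optima of AOB(3)/(4)/(7), so AOB(1) cannot dominate at 303 K
under any response normalized at the guild optimum — at 30 °C the model
yields AOB(7)/AOB(4) instead. The corresponding ordering test documents
this as a known, structural disagreement with the qualitative expectation
for that temperature.

## N₂O pathways

1. **Hydroxylamine decomposition**: a fixed fraction (default 0.001) of the
   NH₃-oxidation flux is released as N₂O-N; the remainder enters NO₂⁻. In
   any coupled, O₂-replete run the cumulative N₂O-N : oxidized-N ratio
   therefore equals 0.1 % (tested to 0.1 % relative).

2. **Nitrite detoxification** (AOO only; AOA use the same relations):
   NO₂⁻ → NO → N₂O with ¼ mol biomass-C consumed per mol N reduced in each
   step (from the 4 NO₂⁻ + CH₂O and 8 NO + 2 CH₂O stoichiometries); B_C and
   B_N are drawn down proportionally and the N content returns to TAN, the
   C to CO₂. The rate law is a stress induction, sigmoidal in the toxin:

       D = v_detox · B_T · C^4/(K^4 + C^4) · K_O2/(K_O2 + [O2])

   with v_detox = 0.4·Vmax, half-induction K = 30 µM for the NO₂⁻ step and
   60 µM for the NO step, and O₂ damping K_O2 = 1 mM (half-suppressed at
   the 1 mM scenario O₂, amplified as O₂ falls). The Hill form keeps the
   pathway silent at the ~1 µM NO₂⁻ of a healthy coupled community —
   hydroxylamine then supplies ≥ 99 % of N₂O — while letting it ignite at
   the tens-of-µM accumulations that follow a loss of nitrite oxidation.

   Accumulated NO₂⁻ and NO also inflate the apparent ammonia affinity,
   K_M^eff = K_M·(1 + k_d·([NO2]+[NO])/[O2]) with k_d = 400, throttling
   growth of stressed ammonia oxidizers.

   None of these five constants is given by the primary literature; they
   were calibrated once against the qualitative decoupling pattern (NO₂⁻
   accumulation, ammonia-oxidizer crash, transient N₂O) and frozen. The
   calibration cannot satisfy every facet of that pattern simultaneously:
   the standing NO₂⁻/NO pools after a knockout (≳ 10 µM) exceed 0.1 % of a
   control's half-year oxidation budget by more than an order of
   magnitude, so a detox flux strong enough to out-produce the control's
   hydroxylamine rate necessarily overshoots the control's cumulative N₂O.
   The acceptance test for the knockout experiment states all three
   conditions and reports the conflict rather than hiding it.

## Scenario protocols

Concentrations quoted by the protocols (initial "NH₃", pulse amplitudes)
are interpreted as free NH₃ at the reference pH 7.8 and converted once to a
TAN pool (÷ 0.0343); a pH gradient then uses the same TAN everywhere so
acidity acts purely through speciation. Site chemistry, being a field
ammonium measurement, is supplied directly as TAN.

* **pH gradient**: pH 7.8 → 4.5, 6-month runs at 25 °C, initial free NH₃
  10 µM, O₂ = CO₂ = 1 mM held constant, 1 µM pulses at months 2 and 4.
* **Temperature gradient**: 5–30 °C in 5 °C steps, pH 7.8, free NH₃ 50 µM.
* **Decoupling**: 6-month spin-up at pH 7.8, 20 °C; NOB biomass zeroed and
  held at zero vs an undisturbed control, each run a further 6 months;
  replicate pairs differ by Monte Carlo trait draws.
* **Pulsed substrate**: 9 months at pH 7.8, 25 °C; initial 1 µM, pulses at
  months 2/4/6/8 stepping 5 µM then 50 µM (free-NH₃ equivalents).
* **Site comparison**: five synthetic site configurations (ammonium-rich
  acid soils, TAN 7.3 mM–0.1 M, pH 4.3–4.8, 15 °C). These are illustrative
  stand-ins spanning the published ranges, not field data. Their pH values
  keep free NH₃ monotone in TAN; the two lowest-TAN sites nonetheless sit
  near the archaeal uptake optimum, which flattens the rate-vs-TAN ranking
  there.

Default inoculum is 1e-6 M biomass-C per analog with Q_C = 1, Q_N = 0.1.
This places the community near carrying capacity so that six months of
simulated time genuinely reaches the substrate-regulated quasi-steady state
the protocols assume, substrate pulses matter, and a knockout produces
measurable NO₂⁻ accumulation.

Key trait-adjacent defaults: K_i^NH3 = 4000 µM for AOB (effectively
uninhibited below mM) and 0.5 µM for the AOA, placing the archaeal uptake
optimum at √(K_M·K_i) ≈ 0.09 µM free NH₃ — the AOA gains share as NH₃ is
drawn below ~1 µM and is suppressed by large pulses, while AOB dominate at
µM-and-above substrate.

## Diversity statistics

Evenness is Pielou's J = −Σ p_i ln p_i / ln S over guilds above the
extinction floor, with J ≡ 1 for a single-guild or exactly-uniform
community (the uniform case is special-cased to return exactly 1.0 rather
than 1 − 2e-16). In Monte Carlo mode analogs are summed to guild level
before computing J. Along the pH gradient J is **not** monotone: it peaks
near pH 7.0 where the AOB–AOA transition mixes both groups (an ecotone
effect) and rises again at pH 4.5 where even the archaeon grows slowly and
declining relic guilds retain share. The ordering test records this.

## Numerics

LSODA (stiff-capable) with rtol 1e-7, atol 1e-16; integration stops and
restarts at every pulse or knockout event; daily dense output. States are
clamped non-negative at output and any variable below 1e-30 M is treated
as extinct (zeroed, derivatives pinned to zero). Halving tolerances moves
final biomasses by < 0.1 % (tested). O₂ and CO₂ are held at their initial
1 mM by default (replenished, i.e. their derivatives are zero); scenarios
may disable replenishment, in which case oxidation stoichiometry (1.5 mol
O₂ per NH₃ → NO₂⁻, 0.5 per NO₂⁻ → NO₃⁻) draws the pools down.

Reported rates are instantaneous fluxes re-evaluated on the daily grid and
smoothed with a 30-day trailing mean; cumulative quantities use trapezoidal
integration.

## Reproducibility

One master seed drives everything: it spawns one independent substream per
guild (and per replicate in the decoupling scenario) via seed sequences, so
adding guilds, analogs, or replicates never perturbs existing draws.
Identical configuration and seed give bitwise-identical trait draws and
byte-identical result files (tested).

## What the synthetic scenarios do and do not show

The generator-driven scenarios emulate closed, well-mixed incubations:
no diffusion or spatial structure, no N₂O/NO efflux, no denitrification
(NO₃⁻ is terminal), no urea/organic-N pathway (the DON trait flag is
annotation only), no heterotrophic nitrification, and chemistry that is
constant apart from the modeled pools. Passing tests therefore demonstrate
internal consistency and the qualitative trait-driven orderings (who wins
where, how rates rank), not quantitative agreement with any field site;
absolute rates depend on closure constants (Δ, K_i, detox law) that the
primary literature does not pin down.
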