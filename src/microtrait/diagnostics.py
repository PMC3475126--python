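"""Community and rate summary statistics.

Evenness is Pielou's J: Shannon entropy of guild biomass fractions divided
by ln(richness), in [0, 1], with J := 1 for a single-guild community.
Richness counts guilds above the extinction floor; in Monte Carlo mode
analogs are summed to guild level before computing J.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dynamics import TimeSeriesResult, running_average
from .params import DEFAULT_PARAMS
from .traits import FunctionalGroup

__all__ = [
    "CommunitySummary",
    "evenness",
    "composition",
    "rate_summary",
    "rate_correlation",
]


@dataclass(frozen=True)
class CommunitySummary:
    fractions: dict[str, float]  # per-guild biomass fraction p_i
    evenness: float
    richness: int
    aoa_aob_ratio: float
    total_biomass: float


def evenness(biomasses, floor: float = 0.0) -> float:
    """Pielou evenness J = -sum(p ln p) / ln S over guilds with biomass > floor."""
    b = np.asarray(list(biomasses), dtype=float)
    b = b[b > floor]
    if b.size == 0:
        raise ValueError("evenness undefined for an empty community")
    if b.size == 1:
        return 1.0
    if np.all(b == b[0]):
        return 1.0  # uniform community: J = 1 exactly, no rounding
    p = b / b.sum()
    return float(-(p * np.log(p)).sum() / np.log(b.size))


def composition(
    result: TimeSeriesResult,
    time: float | None = None,
    floor: float = DEFAULT_PARAMS.extinction_floor,
) -> CommunitySummary:
    """Guild-level community summary at ``time`` (default: end of run)."""
    t = result.time
    idx = len(t) - 1 if time is None else int(np.argmin(np.abs(t - time)))
    guild_b: dict[str, float] = {}
    group_b = {g: 0.0 for g in FunctionalGroup}
    for i, a in enumerate(result.analogs):
        b = float(result.b_total[idx, i])
        guild_b[a.parent_guild] = guild_b.get(a.parent_guild, 0.0) + b
        group_b[a.functional_group] += b
    extant = {g: b for g, b in guild_b.items() if b > floor}
    total = sum(extant.values())
    fractions = {g: (b / total if total > 0 else 0.0) for g, b in guild_b.items()}
    aob = group_b[FunctionalGroup.AOB]
    aoa = group_b[FunctionalGroup.AOA]
    return CommunitySummary(
        fractions=fractions,
        evenness=evenness(list(extant.values())) if extant else 0.0,
        richness=len(extant),
        aoa_aob_ratio=aoa / aob if aob > 0 else np.inf,
        total_biomass=total,
    )


def rate_summary(result: TimeSeriesResult, window: int = 30) -> dict[str, float]:
    """Maximum smoothed rates, cumulative amounts, and the N2O pathway split."""
    t = result.time
    n2o = result.n2o_rate
    nh3 = result.nh3_ox_total
    hyd = result.n2o_hydrox_rate.sum(axis=1)
    det = result.n2o_detox_rate.sum(axis=1)
    cum_n2o = float(np.trapezoid(n2o, t))
    cum_hyd = float(np.trapezoid(hyd, t))
    cum_det = float(np.trapezoid(det, t))
    return {
        "max_n2o_rate_smoothed": float(running_average(n2o, window).max()),
        "max_nh3_ox_rate_smoothed": float(running_average(nh3, window).max()),
        "cumulative_n2o_n": cum_n2o,
        "cumulative_nh3_ox": float(np.trapezoid(nh3, t)),
        "cumulative_n2o_hydroxylamine": cum_hyd,
        "cumulative_n2o_detox": cum_det,
        "hydroxylamine_share": cum_hyd / cum_n2o if cum_n2o > 0 else np.nan,
        "detox_share": cum_det / cum_n2o if cum_n2o > 0 else np.nan,
    }


def rate_correlation(series_a, series_b) -> tuple[float, float]:
    """Pearson r and least-squares slope of b on a."""
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("series must be equal length, n >= 3")
    r = float(stats.pearsonr(a, b).statistic)
    slope = float(np.polyfit(a, b, 1)[0])
    return r, slope
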