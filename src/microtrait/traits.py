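"""Guild trait database and Monte Carlo sampling of intra-guild analogs.

Each nitrifier guild (seven betaproteobacterial AOB lineages, one AOA, three
NOB) is described by ranges of physiological traits compiled from culture
ecophysiology: maximum substrate oxidation rate ``vmax_substrate`` (NH3 for
ammonia oxidizers, NO2- for nitrite oxidizers; d-1, biomass-specific),
substrate half-saturation ``km_substrate`` (uM), maximum specific division
rate ``mu_max`` (d-1), O2 half-saturation ``km_o2`` (uM), CO2-fixation yield
``yield_co2_per_n`` (mol CO2 fixed per mol N oxidized, dimensionless), and a
temperature-optimum window in Kelvin.  Intra-guild diversity is represented
by drawing point-valued "analogs" from each trait range.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "Distribution",
    "FunctionalGroup",
    "TraitRange",
    "GuildTraits",
    "GuildAnalog",
    "default_guilds",
    "mean_traits",
    "sample_analogs",
    "load_trait_table",
    "write_trait_table",
]

_RANGE_FIELDS = ("vmax_substrate", "km_substrate", "mu_max", "km_o2", "yield_co2_per_n")


class FunctionalGroup(str, enum.Enum):
    AOB = "AOB"
    AOA = "AOA"
    NOB = "NOB"

    @property
    def is_aoo(self) -> bool:
        """Ammonia-oxidizing organisms = AOB + AOA."""
        return self in (FunctionalGroup.AOB, FunctionalGroup.AOA)


class Distribution(str, enum.Enum):
    UNIFORM = "uniform"
    NORMAL = "normal"


@dataclass(frozen=True)
class TraitRange:
    """Closed interval of admissible trait values; a point trait has low == high."""

    low: float
    high: float
    distribution: Distribution = Distribution.UNIFORM

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError(f"TraitRange low {self.low} > high {self.high}")

    @property
    def mean(self) -> float:
        return 0.5 * (self.low + self.high)

    @property
    def is_point(self) -> bool:
        return self.low == self.high

    def sample(self, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        """Draw n values; uniform over [low, high] or a truncated normal with
        mean at the midpoint and SD (high - low)/4."""
        if self.is_point:
            return np.full(n, self.low)
        if self.distribution is Distribution.UNIFORM:
            return rng.uniform(self.low, self.high, size=n)
        sd = (self.high - self.low) / 4.0
        out = np.empty(n)
        for i in range(n):
            x = rng.normal(self.mean, sd)
            while not (self.low <= x <= self.high):
                x = rng.normal(self.mean, sd)
            out[i] = x
        return out


@dataclass(frozen=True)
class GuildTraits:
    """One guild's trait-range parameter set (the model's unit of diversity)."""

    guild_id: str
    functional_group: FunctionalGroup
    uses_don: str  # "yes" | "no" | "unknown"; annotation only
    vmax_substrate: TraitRange  # d-1
    km_substrate: TraitRange  # uM
    mu_max: TraitRange  # d-1
    km_o2: TraitRange  # uM
    yield_co2_per_n: TraitRange  # dimensionless
    temp_window: tuple[float, float]  # Kelvin, (suboptimal low, optimum)
    ki_nh3: float | None = None  # uM; AOO only
    phylogeny: str = ""

    def __post_init__(self) -> None:
        for name in _RANGE_FIELDS:
            tr: TraitRange = getattr(self, name)
            if tr.low <= 0:
                raise ValueError(f"{self.guild_id}: {name} must be strictly positive")
        lo, hi = self.temp_window
        if not lo < hi:
            raise ValueError(f"{self.guild_id}: temp_window low must be < high")
        if self.functional_group is FunctionalGroup.NOB and self.ki_nh3 is not None:
            raise ValueError(f"{self.guild_id}: NOB guilds carry no NH3 inhibition constant")
        if self.uses_don not in ("yes", "no", "unknown"):
            raise ValueError(f"{self.guild_id}: uses_don must be yes/no/unknown")

    def with_distribution(self, dist: Distribution) -> "GuildTraits":
        """Copy of this guild with every non-point trait range resampled from `dist`."""
        kw = {
            name: replace(getattr(self, name), distribution=dist) for name in _RANGE_FIELDS
        }
        return replace(self, **kw)


@dataclass(frozen=True)
class GuildAnalog:
    """A point-valued trait draw within a parent guild's ranges."""

    parent_guild: str
    analog_index: int
    functional_group: FunctionalGroup
    vmax_substrate: float
    km_substrate: float
    mu_max: float
    km_o2: float
    yield_co2_per_n: float
    temp_window: tuple[float, float]
    ki_nh3: float | None = None

    @property
    def label(self) -> str:
        return f"{self.parent_guild}#{self.analog_index}"


def _parse_row(row: pd.Series) -> GuildTraits:
    def tr(prefix: str) -> TraitRange:
        return TraitRange(float(row[f"{prefix}_lo"]), float(row[f"{prefix}_hi"]))

    ki = row.get("ki_nh3")
    ki = None if ki is None or (isinstance(ki, float) and math.isnan(ki)) or ki == "" else float(ki)
    return GuildTraits(
        guild_id=str(row["guild_id"]),
        functional_group=FunctionalGroup(row["functional_group"]),
        uses_don=str(row["uses_don"]),
        vmax_substrate=tr("vmax"),
        km_substrate=tr("km"),
        mu_max=tr("mu"),
        km_o2=tr("kmo2"),
        yield_co2_per_n=tr("yield"),
        temp_window=(float(row["temp_lo"]), float(row["temp_hi"])),
        ki_nh3=ki,
        phylogeny=str(row["phylogeny"]),
    )


def load_trait_table(path: str | Path | None = None) -> list[GuildTraits]:
    """Read a guild trait table (tab-delimited). Defaults to the packaged table."""
    if path is None:
        with resources.as_file(resources.files("microtrait.data") / "guild_traits.tsv") as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    return [_parse_row(row) for _, row in df.iterrows()]


def write_trait_table(guilds: Iterable[GuildTraits], path: str | Path) -> None:
    """Write guilds to a tab-delimited table (round-trips with load_trait_table)."""
    rows = []
    for g in guilds:
        row: dict[str, object] = {
            "guild_id": g.guild_id,
            "functional_group": g.functional_group.value,
            "uses_don": g.uses_don,
        }
        for name, prefix in zip(_RANGE_FIELDS, ("vmax", "km", "mu", "kmo2", "yield")):
            tr: TraitRange = getattr(g, name)
            row[f"{prefix}_lo"] = tr.low
            row[f"{prefix}_hi"] = tr.high
        row["temp_lo"], row["temp_hi"] = g.temp_window
        row["ki_nh3"] = "" if g.ki_nh3 is None else g.ki_nh3
        row["phylogeny"] = g.phylogeny
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def default_guilds() -> list[GuildTraits]:
    """The 11 default guilds: AOB(1)-AOB(7), AOA, NOB(1)-NOB(3)."""
    return load_trait_table()


def mean_traits(guild: GuildTraits, analog_index: int = 0) -> GuildAnalog:
    """Point analog at the midpoint of every trait range."""
    return GuildAnalog(
        parent_guild=guild.guild_id,
        analog_index=analog_index,
        functional_group=guild.functional_group,
        vmax_substrate=guild.vmax_substrate.mean,
        km_substrate=guild.km_substrate.mean,
        mu_max=guild.mu_max.mean,
        km_o2=guild.km_o2.mean,
        yield_co2_per_n=guild.yield_co2_per_n.mean,
        temp_window=guild.temp_window,
        ki_nh3=guild.ki_nh3,
    )


def sample_analogs(
    guild: GuildTraits, n: int, seed: int | np.random.Generator
) -> list[GuildAnalog]:
    """Draw ``n`` stochastic analogs of ``guild``, each trait independent.

    Reproducible: an integer seed always yields the same draws.
    """
    if n < 1:
        raise ValueError(f"number of analogs must be >= 1, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = {name: getattr(guild, name).sample(rng, n) for name in _RANGE_FIELDS}
    return [
        GuildAnalog(
            parent_guild=guild.guild_id,
            analog_index=i,
            functional_group=guild.functional_group,
            vmax_substrate=float(draws["vmax_substrate"][i]),
            km_substrate=float(draws["km_substrate"][i]),
            mu_max=float(draws["mu_max"][i]),
            km_o2=float(draws["km_o2"][i]),
            yield_co2_per_n=float(draws["yield_co2_per_n"][i]),
            temp_window=guild.temp_window,
            ki_nh3=guild.ki_nh3,
        )
        for i in range(n)
    ]
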