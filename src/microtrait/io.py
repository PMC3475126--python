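"""Configuration loading, result writers, and run manifests."""

from __future__ import annotations

import dataclasses
import json
import time as _time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dynamics import SolverOptions, TimeSeriesResult
from .environment import POOLS
from .scenarios import SCENARIOS, ScenarioConfig
from .traits import Distribution

__all__ = ["ConfigError", "load_config", "write_results", "RunManifest", "dump_config"]

_CONFIG_KEYS = {f.name for f in dataclasses.fields(ScenarioConfig)}
_SOLVER_KEYS = {f.name for f in dataclasses.fields(SolverOptions)}


class ConfigError(ValueError):
    """Schema violation in a scenario configuration file."""


def load_config(path: str | Path) -> ScenarioConfig:
    """Load and validate a YAML scenario config; unknown keys are rejected."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    if "scenario_id" not in raw:
        raise ConfigError("missing required key: scenario_id")
    if raw["scenario_id"] not in SCENARIOS:
        raise ConfigError(
            f"scenario_id: unknown scenario {raw['scenario_id']!r}; "
            f"choose from {sorted(SCENARIOS)}"
        )
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    kwargs = dict(raw)
    if "solver" in kwargs:
        sv = kwargs["solver"]
        bad = set(sv) - _SOLVER_KEYS
        if bad:
            raise ConfigError(f"solver: unknown keys {sorted(bad)}")
        kwargs["solver"] = SolverOptions(**sv)
    if "distribution" in kwargs:
        kwargs["distribution"] = Distribution(kwargs["distribution"])
    for key in ("ph_values", "temperatures_c", "pulse_times", "pulse_amounts"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    try:
        return ScenarioConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def dump_config(config: ScenarioConfig, path: str | Path) -> None:
    d = asdict(config)
    d["distribution"] = config.distribution.value
    for key in ("ph_values", "temperatures_c", "pulse_times", "pulse_amounts"):
        d[key] = list(d[key])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


@dataclass
class RunManifest:
    """Reproducibility record: config snapshot, seed, version, outputs."""

    config: dict
    seed: int
    version: str
    wall_time_s: float
    outputs: list[str]

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))


def result_to_frame(result: TimeSeriesResult) -> pd.DataFrame:
    """Long-format (time, variable, guild, value) table of a run."""
    rows = []
    t = result.time
    for i, p in enumerate(POOLS):
        rows.append(pd.DataFrame({
            "time": t, "variable": p, "guild": "", "value": result.pools[:, i],
        }))
    per_analog = {
        "b_total": result.b_total,
        "nh3_ox_rate": result.nh3_ox_rate,
        "no2_ox_rate": result.no2_ox_rate,
        "n2o_hydrox_rate": result.n2o_hydrox_rate,
        "n2o_detox_rate": result.n2o_detox_rate,
    }
    for var, arr in per_analog.items():
        for j, a in enumerate(result.analogs):
            rows.append(pd.DataFrame({
                "time": t, "variable": var, "guild": a.label, "value": arr[:, j],
            }))
    return pd.concat(rows, ignore_index=True)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    return str(obj)


def write_results(
    payload,
    out_dir: str | Path,
    config: ScenarioConfig | None = None,
    start_time: float | None = None,
) -> list[str]:
    """Write scenario output to ``out_dir``: long-format series for every
    TimeSeriesResult, a JSON summary of everything else, and a RunManifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    def emit(obj, prefix: str):
        if isinstance(obj, TimeSeriesResult):
            f = out / f"{prefix or 'series'}.tsv"
            result_to_frame(obj).to_csv(f, sep="\t", index=False, float_format="%.12g")
            written.append(f.name)
            return f"file:{f.name}"
        if isinstance(obj, dict):
            return {str(k): emit(v, f"{prefix}_{k}" if prefix else str(k)) for k, v in obj.items()}
        if isinstance(obj, list):
            return [emit(v, f"{prefix}_{i}") for i, v in enumerate(obj)]
        return obj

    summary = emit(payload, "")
    sf = out / "summary.json"
    sf.write_text(json.dumps(summary, indent=2, default=_json_default))
    written.append(sf.name)

    cfg_dict = {}
    seed = 0
    if config is not None:
        cfg_dict = json.loads(json.dumps(asdict(config), default=_json_default))
        seed = config.seed
    manifest = RunManifest(
        config=cfg_dict,
        seed=seed,
        version=__version__,
        wall_time_s=0.0 if start_time is None else _time.time() - start_time,
        outputs=sorted(written),
    )
    mf = out / "manifest.json"
    manifest.write(mf)
    written.append(mf.name)
    return written
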