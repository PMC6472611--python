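"""Structured run-configuration files, output serialization and run manifests.

Configs are YAML with four flat sections -- ``scenario``, ``production``,
``preferences``, ``behavior`` -- every key optional and defaulted; unknown
keys are rejected with their location.  Outputs are small, diff-able CSV
tables with a fixed column order, plus a JSON manifest listing each file's
SHA-256 digest and echoing the configuration, so a run can be verified as
reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .diffusion import BehavioralParams
from .errors import ConfigurationError
from .scenarios import (
    EnsembleSummary,
    PreferenceParams,
    ProductionParams,
    ScenarioConfig,
    Trajectory,
)

__all__ = [
    "RunManifest",
    "load_config",
    "save_config",
    "config_to_dict",
    "config_from_dict",
    "write_outputs",
]

_SECTIONS = {
    "production": ProductionParams,
    "preferences": PreferenceParams,
    "behavior": BehavioralParams,
}

# scenario-level keys are every ScenarioConfig field except the nested sections
_SCENARIO_KEYS = tuple(
    f.name for f in dataclasses.fields(ScenarioConfig) if f.name not in _SECTIONS
)


def _coerce(section: str, key: str, value, target_type):
    if value is None:
        return None
    try:
        if target_type is bool:
            if not isinstance(value, bool):
                raise TypeError
            return value
        if target_type is int:
            if isinstance(value, bool) or int(value) != value:
                raise TypeError
            return int(value)
        if target_type is float:
            if isinstance(value, bool):
                raise TypeError
            return float(value)
        if target_type is tuple:
            return tuple(value)
    except (TypeError, ValueError):
        raise ConfigurationError(
            f"{section}.{key}: expected {target_type.__name__}, got {value!r}"
        ) from None
    return value


def _build_section(name: str, cls, data: dict):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in fields:
            raise ConfigurationError(f"unknown key {name}.{key}")
        f = fields[key]
        if f.name == "shock":
            kwargs[key] = tuple(value) if value is not None else None
            continue
        target = f.type if isinstance(f.type, type) else None
        if target is None:
            hints = {"int": int, "float": float, "bool": bool}
            base = str(f.type).split("[")[0].strip()
            target = hints.get(base, tuple if "tuple" in str(f.type) else None)
        kwargs[key] = _coerce(name, key, value, target) if target else value
    return cls(**kwargs)


def config_from_dict(data: dict) -> ScenarioConfig:
    """Build a validated ScenarioConfig from a nested plain dict."""
    data = dict(data or {})
    kwargs = {}
    for section, cls in _SECTIONS.items():
        raw = data.pop(section, {}) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"section {section!r} must be a mapping")
        kwargs[section] = _build_section(section, cls, raw)
    scenario = data.pop("scenario", {}) or {}
    if not isinstance(scenario, dict):
        raise ConfigurationError("section 'scenario' must be a mapping")
    if data:
        raise ConfigurationError(f"unknown top-level key {sorted(data)[0]!r}")
    for key in scenario:
        if key not in _SCENARIO_KEYS:
            raise ConfigurationError(f"unknown key scenario.{key}")
    fields = {f.name: f for f in dataclasses.fields(ScenarioConfig)}
    for key, value in scenario.items():
        f = fields[key]
        if key == "shock":
            kwargs[key] = tuple(value) if value is not None else None
        elif f.default is not dataclasses.MISSING and isinstance(f.default, bool):
            kwargs[key] = _coerce("scenario", key, value, bool)
        elif f.default is not dataclasses.MISSING and isinstance(f.default, int):
            kwargs[key] = _coerce("scenario", key, value, int)
        elif f.default is not dataclasses.MISSING and isinstance(f.default, float):
            kwargs[key] = _coerce("scenario", key, value, float)
        else:
            kwargs[key] = value
    return ScenarioConfig(**kwargs)


def config_to_dict(config: ScenarioConfig) -> dict:
    """Nested plain-dict form of a config (round-trips through YAML)."""
    out: dict = {"scenario": {}}
    for key in _SCENARIO_KEYS:
        value = getattr(config, key)
        out["scenario"][key] = list(value) if isinstance(value, tuple) else value
    for section, _ in _SECTIONS.items():
        sec = dataclasses.asdict(getattr(config, section))
        out[section] = {
            k: (list(v) if isinstance(v, tuple) else v) for k, v in sec.items()
        }
    return out


def load_config(path: str | Path) -> ScenarioConfig:
    """Load and validate a YAML config; an empty file yields the full defaults."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"config root must be a mapping: {path}")
    return config_from_dict(data)


def save_config(config: ScenarioConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


@dataclass(frozen=True)
class RunManifest:
    """Echo of the run: config, master seed, and per-file SHA-256 digests."""

    master_seed: int
    config: dict
    files: dict


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# fixed, documented column orders
_TRAJECTORY_COLUMNS = [
    "year", "season_index",
    "maize_annual", "pigeonpea_annual", "biomass_annual",
    "maize_perennial", "pigeonpea_perennial", "biomass_perennial",
    "U_a", "U_p", "rel_diff", "Pa", "Pa_avg3",
    "N", "A", "D", "adopter_share", "T", "L", "C",
    "promoted", "adopted", "disadopted", "readopted", "seed_cap",
]
_ENSEMBLE_COLUMNS = ["year", "mean", "min", "max"]


def write_outputs(result, out_dir: str | Path, name: str | None = None) -> RunManifest:
    """Write a trajectory, ensemble summary or table to CSV plus a manifest.

    Floats are written with ``repr`` (shortest round-trip) so identical runs
    produce byte-identical files; the manifest is written last.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if isinstance(result, Trajectory):
        name = name or "trajectory"
        frame = result.frame[_TRAJECTORY_COLUMNS]
        config = config_to_dict(result.config)
        seed = result.config.master_seed
    elif isinstance(result, EnsembleSummary):
        name = name or "ensemble"
        frame = result.frame[_ENSEMBLE_COLUMNS]
        config = {"n_iterations": result.n_iterations}
        seed = result.master_seed
    elif isinstance(result, pd.DataFrame):
        name = name or "table"
        frame = result
        config = {}
        seed = -1
    else:
        raise ConfigurationError(f"cannot serialise result of type {type(result).__name__}")

    csv_path = out_dir / f"{name}.csv"
    frame.to_csv(csv_path, index=False, float_format=lambda x: repr(float(x)))
    manifest = RunManifest(
        master_seed=seed,
        config=config,
        files={csv_path.name: _sha256(csv_path)},
    )
    with open(out_dir / f"{name}_manifest.json", "w") as fh:
        json.dump(dataclasses.asdict(manifest), fh, indent=2, sort_keys=True)
    return manifest
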