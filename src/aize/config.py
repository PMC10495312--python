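"""YAML/JSON (de)serialization of strategy and observer configuration."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from .fields import NormativeModel, ScotomaSpec
from .observer import ERROR_CONDITIONS, ErrorCondition, ObserverConfig
from .pmf import LikelihoodShape, PriorSpec
from .strategy import StrategyConfig, WeightPolicy

__all__ = [
    "strategy_config_to_dict",
    "strategy_config_from_dict",
    "observer_config_from_dict",
    "load_strategy_config",
    "save_strategy_config",
    "condition_from_name",
]

_NESTED = {
    "weight_policy": WeightPolicy,
    "prior": PriorSpec,
    "likelihood": LikelihoodShape,
    "normative": NormativeModel,
}


def strategy_config_to_dict(cfg: StrategyConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["sigma_db_clamp"] = list(d["sigma_db_clamp"])
    d["clamp_range"] = list(d["clamp_range"])
    return d


def _build(cls, data: dict):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


def strategy_config_from_dict(data: dict) -> StrategyConfig:
    data = dict(data)
    for key, cls in _NESTED.items():
        if key in data and isinstance(data[key], dict):
            data[key] = _build(cls, data[key])
    for key in ("sigma_db_clamp", "clamp_range"):
        if key in data:
            data[key] = tuple(data[key])
    return _build(StrategyConfig, data)


def observer_config_from_dict(data: dict) -> ObserverConfig:
    return _build(ObserverConfig, dict(data))


def load_strategy_config(path) -> StrategyConfig:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return strategy_config_from_dict(data)


def save_strategy_config(cfg: StrategyConfig, path) -> None:
    path = Path(path)
    d = strategy_config_to_dict(cfg)
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d))


def condition_from_name(name: str) -> ErrorCondition:
    for cond in ERROR_CONDITIONS:
        if cond.label == name:
            return cond
    raise ValueError(f"unknown error condition {name!r}")
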