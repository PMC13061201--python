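"""YAML configuration loading for augmentation, phantom and training configs.

Each loader maps a YAML mapping field-for-field onto the corresponding
dataclass; unknown keys raise a :class:`ConfigError` so typos fail loudly.
"""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path
from typing import Any, Type, TypeVar

import yaml

from .augment import SASConfig
from .synthetic import PhantomSpec
from .trainer import TrainConfig

__all__ = ["ConfigError", "load_yaml", "sas_config_from_dict",
           "phantom_spec_from_dict", "train_config_from_dict"]

T = TypeVar("T")


class ConfigError(ValueError):
    """Invalid or malformed configuration."""


def load_yaml(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return data


def _from_dict(cls: Type[T], data: dict[str, Any], **overrides: Any) -> T:
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    merged = {**data, **{k: v for k, v in overrides.items() if v is not None}}
    try:
        return cls(**merged)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {cls.__name__}: {exc}") from exc


def sas_config_from_dict(data: dict[str, Any], **overrides: Any) -> SASConfig:
    data = dict(data)
    if "noise_types" in data:
        data["noise_types"] = tuple(data["noise_types"])
    return _from_dict(SASConfig, data, **overrides)


def phantom_spec_from_dict(data: dict[str, Any], **overrides: Any) -> PhantomSpec:
    data = dict(data)
    if "center" in data and data["center"] is not None:
        data["center"] = tuple(data["center"])
    return _from_dict(PhantomSpec, data, **overrides)


def train_config_from_dict(data: dict[str, Any], **overrides: Any) -> TrainConfig:
    data = dict(data)
    if isinstance(data.get("sas"), dict):
        data["sas"] = sas_config_from_dict(data["sas"])
    return _from_dict(TrainConfig, data, **overrides)
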