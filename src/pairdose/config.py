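"""YAML configuration loading for experiments and simulations.

A config file is a nested mapping whose sections mirror the dataclasses:
``scenario``-level keys at the top, then ``simulate:``, ``encoders:``
(with ``drug:``, ``dose:``, ``cell:`` blocks), ``global:``, ``local:``,
``aggregator:``. Unknown keys raise immediately rather than being ignored.
"""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path
from typing import Any, Mapping, Type, TypeVar

import yaml

from .aggregation import AggregatorConfig
from .encoders import CellEncoderConfig, DoseEmbedderConfig, DrugEncoderConfig
from .evaluation import ExperimentConfig
from .global_model import GlobalModelConfig
from .io_types import ConfigurationError
from .local_model import LocalGCNConfig
from .synthetic import SyntheticConfig

__all__ = ["load_experiment_config", "load_synthetic_config", "build_dataclass"]

T = TypeVar("T")


def build_dataclass(cls: Type[T], data: Mapping[str, Any] | None) -> T:
    data = dict(data or {})
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) {sorted(unknown)} for {cls.__name__}; known: {sorted(known)}"
        )
    for f in fields(cls):
        if f.name in data and isinstance(data[f.name], list):
            data[f.name] = tuple(data[f.name])
    return cls(**data)


def load_synthetic_config(path: str | Path) -> SyntheticConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return build_dataclass(SyntheticConfig, raw.get("simulate", raw))


def load_experiment_config(path: str | Path) -> ExperimentConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    encoders = raw.pop("encoders", {}) or {}
    sections = {
        "synthetic": build_dataclass(SyntheticConfig, raw.pop("simulate", None)),
        "global_cfg": build_dataclass(GlobalModelConfig, raw.pop("global", None)),
        "local_cfg": build_dataclass(LocalGCNConfig, raw.pop("local", None)),
        "aggregator_cfg": build_dataclass(AggregatorConfig, raw.pop("aggregator", None)),
        "dose_cfg": build_dataclass(DoseEmbedderConfig, encoders.get("dose")),
        "drug_cfg": build_dataclass(DrugEncoderConfig, encoders.get("drug")),
        "cell_cfg": build_dataclass(CellEncoderConfig, encoders.get("cell")),
    }
    if "variants" in raw and isinstance(raw["variants"], list):
        raw["variants"] = tuple(raw["variants"])
    known = {f.name for f in fields(ExperimentConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(
            f"unknown top-level key(s) {sorted(unknown)}; known: {sorted(known)}"
        )
    return ExperimentConfig(**raw, **sections)
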