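"""Run configuration: strict YAML parsing, nested dataclasses, hashing.

Unknown keys are rejected rather than ignored — silent typos in a
config file are the main reproducibility hazard in a multi-stage
pipeline.  The config hash (sha256 over the canonical JSON form) is
embedded in every artifact a command writes, so two artifacts with
equal hashes were produced under identical configurations.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .exceptions import ConfigurationError
from .model import ModelConfig
from .preprocess import PreprocessConfig
from .synthetic import SynthConfig
from .training import TrainConfig


def _build(dc_cls, data: dict, context: str):
    if not isinstance(data, dict):
        raise ConfigurationError(f"{context}: expected a mapping")
    names = {f.name for f in dataclasses.fields(dc_cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigurationError(
            f"{context}: unknown keys {sorted(unknown)}; valid: {sorted(names)}")
    coerced = {}
    for f in dataclasses.fields(dc_cls):
        if f.name not in data:
            continue
        value = data[f.name]
        if isinstance(value, list):
            value = tuple(value)
        coerced[f.name] = value
    try:
        return dc_cls(**coerced)
    except (TypeError, ConfigurationError) as exc:
        raise ConfigurationError(f"{context}: {exc}") from exc


@dataclass(frozen=True)
class RunConfig:
    synth: SynthConfig = field(default_factory=SynthConfig)
    n_validation: int = 50
    n_test: int = 50
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    data_root: str | None = None
    perturbation: str = "none"
    intensity_shift: float = 0.5

    @staticmethod
    def from_dict(data: dict) -> "RunConfig":
        if not isinstance(data, dict):
            raise ConfigurationError("run config must be a mapping")
        known = {"synth", "n_validation", "n_test", "preprocess", "model",
                 "train", "data_root", "perturbation", "intensity_shift"}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown top-level keys "
                                     f"{sorted(unknown)}; valid: {sorted(known)}")
        kwargs = {}
        for key, cls in (("synth", SynthConfig), ("preprocess", PreprocessConfig),
                         ("model", ModelConfig), ("train", TrainConfig)):
            if key in data:
                kwargs[key] = _build(cls, data[key], key)
        for key in ("n_validation", "n_test", "data_root", "perturbation",
                    "intensity_shift"):
            if key in data:
                kwargs[key] = data[key]
        return RunConfig(**kwargs)

    @staticmethod
    def from_yaml(path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return RunConfig.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def config_hash(config: RunConfig) -> str:
    canonical = json.dumps(config.to_dict(), sort_keys=True, default=list)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]
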