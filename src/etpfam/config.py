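"""Declarative run configuration with schema validation.

A YAML file (or plain dict) is validated against a strict schema — unknown
keys are rejected — and every run writes a resolved snapshot of the config it
actually used next to its outputs.  Defaults echo the full-scale protocol
(window lengths 32/64/128 with step 4, lr grid 1e-4..1e-6, patience 5,
F=1100 / Fb=550); scaled-down runs override them explicitly.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .errors import ConfigurationError


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class EmbedderConfig(_Strict):
    name: str = "synthetic"
    dim: int = Field(default=16, ge=1)
    seed: int = 0


class WindowConfig(_Strict):
    length: int = Field(default=32, ge=1)
    step: int = Field(default=4, ge=1)
    samples_per_seq: int = Field(default=1, ge=1)


class BaseGridConfig(_Strict):
    windows: list[int] = [32, 64, 128]
    lrs: list[float] = [1e-4, 1e-5, 1e-6]
    seeds: list[int] = [0]
    F: int = Field(default=1100, ge=1)
    Fb: int = Field(default=550, ge=1)
    patience: int = Field(default=5, ge=1)
    max_epochs: int = Field(default=50, ge=1)
    batch_size: int = Field(default=256, ge=1)

    @field_validator("windows", "lrs", "seeds")
    @classmethod
    def _nonempty(cls, v):
        if not v:
            raise ValueError("grid lists must be non-empty")
        return v


class EnsembleConfig(_Strict):
    strategy: str = "lwf_perceptron"
    method: str = "swc"
    max_members: int = Field(default=10, ge=1)
    error_threshold: float = Field(default=0.20, gt=0, le=1)
    seed: int = 0


class RunConfig(_Strict):
    embedder: EmbedderConfig = EmbedderConfig()
    window: WindowConfig = WindowConfig()
    base_grid: BaseGridConfig = BaseGridConfig()
    ensemble: EnsembleConfig = EnsembleConfig()


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load + validate a YAML config; ``overrides`` (nested dict) wins."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    for key, sub in (overrides or {}).items():
        data.setdefault(key, {}).update(sub)
    try:
        return RunConfig(**data)
    except Exception as exc:  # pydantic ValidationError
        raise ConfigurationError(str(exc)) from exc


def dump_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=True)
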