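"""Experiment configuration, seeding, and run manifests.

A run is fully described by an :class:`ExperimentConfig`: the environment,
the encoder choice and its parameters, cycle count, Monte-Carlo sample count
and a top-level seed.  Configurations round-trip losslessly through YAML;
a manifest (config + seed + result summary) reproduces a run bit-for-bit.

The top-level seed deterministically spawns independent substreams (via
``numpy.random.SeedSequence``) so that adding a diagnostic that consumes
randomness does not perturb the main trajectory.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .environment import EnvironmentConfig

__all__ = [
    "ExperimentConfig",
    "load_config",
    "save_config",
    "write_manifest",
    "spawn_rngs",
]

ENCODERS = ("identity", "discretize", "filter", "select")
GOALS = ("inference", "reconstruction")


@dataclass(frozen=True)
class ExperimentConfig:
    """Complete description of one simulation run."""

    environment: EnvironmentConfig = field(default_factory=EnvironmentConfig)
    encoder: str = "identity"
    goal: str = "inference"
    n_levels: int = 3            # discretize
    beta: float = 0.1            # filter entropy weight
    threshold_fraction: float = 0.5   # select
    window: int = 10                  # select
    n_cycles: int = 500
    mc_samples: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.encoder not in ENCODERS:
            raise ValueError(f"encoder must be one of {ENCODERS}, got {self.encoder!r}")
        if self.goal not in GOALS:
            raise ValueError(f"goal must be one of {GOALS}, got {self.goal!r}")
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")
        if self.mc_samples < 1:
            raise ValueError("mc_samples must be >= 1")
        if self.n_cycles < 0:
            raise ValueError("n_cycles must be nonnegative")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["environment"] = dataclasses.asdict(self.environment)
        return d


_ENV_FIELDS = {f.name: f for f in dataclasses.fields(EnvironmentConfig)}
_EXP_FIELDS = {f.name: f for f in dataclasses.fields(ExperimentConfig)}


def _typed(name: str, value, expected, where: str):
    if expected is float and isinstance(value, (int, float)) and not isinstance(value, bool):
        return float(value)
    if expected is int:
        if isinstance(value, bool) or not isinstance(value, int):
            raise TypeError(f"{where}.{name}: expected integer, got {value!r}")
        return value
    if not isinstance(value, expected):
        raise TypeError(f"{where}.{name}: expected {expected.__name__}, got {value!r}")
    return value


def config_from_dict(data: dict) -> ExperimentConfig:
    """Build a validated config from a plain mapping; unknown keys rejected."""
    if not isinstance(data, dict):
        raise TypeError("config root must be a mapping")
    data = dict(data)
    env_data = dict(data.pop("environment", {}))
    unknown = set(env_data) - set(_ENV_FIELDS)
    if unknown:
        raise ValueError(f"unknown environment field(s): {sorted(unknown)}")
    env_kwargs = {}
    for name, value in env_data.items():
        expected = str if name == "mode" else float
        env_kwargs[name] = _typed(name, value, expected, "environment")
    env = EnvironmentConfig(**env_kwargs)

    unknown = set(data) - (set(_EXP_FIELDS) - {"environment"})
    if unknown:
        raise ValueError(f"unknown config field(s): {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        f = _EXP_FIELDS[name]
        expected = {"str": str, "int": int, "float": float}[f.type] \
            if isinstance(f.type, str) else f.type
        kwargs[name] = _typed(name, value, expected, "config")
    return ExperimentConfig(environment=env, **kwargs)


def load_config(path) -> ExperimentConfig:
    """Read and validate a YAML experiment configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data or {})


def save_config(config: ExperimentConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def write_manifest(config: ExperimentConfig, results: dict, path) -> None:
    """Write a JSON manifest pairing the full configuration with a summary
    of results, sufficient to reproduce the run."""
    payload = {"config": config.to_dict(), "results": results}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def spawn_rngs(seed: int, n: int = 1) -> list[np.random.Generator]:
    """Derive ``n`` independent generators from one top-level seed."""
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n)]
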