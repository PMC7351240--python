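"""Run configuration: validated, defaulted, round-trippable (YAML/JSON).

A :class:`RunConfig` names a preset and circuit plus optional rate and pool
overrides; it is the single object the command-line entry points consume,
and the manifest written next to every output records it together with the
seed and package version so any result can be regenerated bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .experiments import PRESETS, get_preset
from .network import CircuitKind, RateSet

__all__ = ["RunConfig", "load_config", "save_config"]

_RATE_FIELDS = set(RateSet.__dataclass_fields__)
_POOL_FIELDS = {"P_X", "P_Y", "P_XY", "RNAP", "Rib"}


@dataclass
class RunConfig:
    preset: str = "generic"
    circuit: str = "parallel"
    rate_overrides: dict[str, float] = field(default_factory=dict)
    pool_overrides: dict[str, int] = field(default_factory=dict)
    n_runs: int = 1000
    base_seed: int = 0
    t_max: float | None = None  # None -> preset default
    out_dir: str = "results"
    verbose: bool = False

    def __post_init__(self) -> None:
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; choose from {sorted(PRESETS)}")
        CircuitKind(self.circuit)
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.t_max is not None and self.t_max <= 0:
            raise ValueError("t_max must be > 0")
        for k, v in self.rate_overrides.items():
            if k not in _RATE_FIELDS:
                raise ValueError(f"unknown rate override {k!r}; known: {sorted(_RATE_FIELDS)}")
            if v is not None and v < 0:
                raise ValueError(f"rate override {k!r} must be >= 0, got {v}")
        for k, v in self.pool_overrides.items():
            if k not in _POOL_FIELDS:
                raise ValueError(f"unknown pool override {k!r}; known: {sorted(_POOL_FIELDS)}")
            if v < 0:
                raise ValueError(f"pool override {k!r} must be >= 0")

    @property
    def resolved_t_max(self) -> float:
        return self.t_max if self.t_max is not None else get_preset(self.preset).t_max

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML or JSON config file; unknown keys are rejected loudly."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file {path} does not exist")
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}; known: {sorted(known)}")
    return RunConfig(**data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    path = Path(path)
    doc = cfg.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=2))
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
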