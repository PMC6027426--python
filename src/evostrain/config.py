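"""Run-configuration file handling.

A run is described by one YAML file: model paths, the rate reaction ids, the
target mode and objectives, and the GA parameters. Every field can be
overridden from the CLI; the effective configuration is echoed into the run
summary so any run is reproducible from its summary alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .errors import ConfigurationError
from .ga_core import GAConfig
from .model_io import DEFAULT_EXCLUDED_SUBSYSTEMS

__all__ = ["RunConfig", "load_config"]

_GA_FIELDS = {f for f in GAConfig.__dataclass_fields__}


@dataclass
class RunConfig:
    model: str
    product: str
    substrate: str
    biomass: Optional[str] = None          #: default: the model's objective
    databank: Optional[str] = None
    reference_fluxes: Optional[str] = None  #: default: wild-type FBA
    mode: str = "reaction"
    objectives: Sequence[str] = ("bpcy",)
    weights: Optional[dict] = None
    predictor: str = "mimbl"
    tie_break: str = "max"
    compress: bool = True
    lump: bool = True
    excluded_subsystems: Sequence[str] = DEFAULT_EXCLUDED_SUBSYSTEMS
    outdir: str = "evostrain_out"
    ga: GAConfig = field(default_factory=GAConfig)

    def validate_paths(self, base: Path) -> None:
        for name in ("model", "databank", "reference_fluxes"):
            value = getattr(self, name)
            if value is None:
                continue
            p = Path(value)
            if not p.is_absolute():
                p = base / p
                setattr(self, name, str(p))
            if not p.exists():
                raise ConfigurationError(f"{name} file not found: {p}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["objectives"] = list(self.objectives)
        d["excluded_subsystems"] = list(self.excluded_subsystems)
        return d


def load_config(path: str | Path, overrides: Optional[dict] = None) -> RunConfig:
    """Load a YAML run configuration; CLI overrides take precedence."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path} does not contain a mapping")
    for key, value in (overrides or {}).items():
        if value is None:
            continue
        if key in _GA_FIELDS:
            raw.setdefault("ga", {})[key] = value
        else:
            raw[key] = value
    ga_raw = raw.pop("ga", {}) or {}
    unknown_ga = set(ga_raw) - _GA_FIELDS
    if unknown_ga:
        raise ConfigurationError(f"unknown GA fields: {sorted(unknown_ga)}")
    known = {f for f in RunConfig.__dataclass_fields__} - {"ga"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
    missing = {"model", "product", "substrate"} - set(raw)
    if missing:
        raise ConfigurationError(f"missing required config fields: {sorted(missing)}")
    cfg = RunConfig(ga=GAConfig(**ga_raw), **raw)
    cfg.validate_paths(path.parent)
    return cfg
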