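"""Run configuration: nested blocks, strict validation, resolved-copy output."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Union

from .model import ModelParameters, parameters_from_dict
from .solver import StepControl

__all__ = ["GridConfig", "FitConfig", "SynthConfig", "RunConfig", "load_config"]


@dataclass(frozen=True)
class GridConfig:
    n_cells: int = 900
    dt_max: float = 0.5
    dt_init: Optional[float] = None
    max_halvings: int = 40
    rel_change_cap: float = 0.05
    front_cells_cap: float = 1.0

    def step_control(self) -> StepControl:
        return StepControl(
            dt_max=self.dt_max,
            dt_init=self.dt_init,
            max_halvings=self.max_halvings,
            rel_change_cap=self.rel_change_cap,
            front_cells_cap=self.front_cells_cap,
        )


@dataclass(frozen=True)
class FitConfig:
    stage1_fields: tuple = ("kappa0", "kf", "Fh")
    stage2_fields: tuple = ("kb", "Fc")
    bounds_span: float = 30.0
    maxfev_per_stage: int = 200


@dataclass(frozen=True)
class SynthConfig:
    cadence: float = 1.0 / 3.0
    t_end: float = 160.0
    cv: float = 0.02
    floor: float = 0.01
    n_replicates: int = 3


@dataclass(frozen=True)
class RunConfig:
    model: ModelParameters = field(default_factory=ModelParameters)
    grid: GridConfig = field(default_factory=GridConfig)
    fit: FitConfig = field(default_factory=FitConfig)
    synth: SynthConfig = field(default_factory=SynthConfig)
    t_end: float = 160.0
    sample_every: float = 1.0 / 3.0
    seed: int = 0

    def resolved_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["fit"]["stage1_fields"] = list(d["fit"]["stage1_fields"])
        d["fit"]["stage2_fields"] = list(d["fit"]["stage2_fields"])
        return d

    def write_resolved(self, path: Union[str, Path]) -> str:
        """Write the fully resolved config as JSON; return its sha256 hash."""
        text = json.dumps(self.resolved_dict(), indent=2, sort_keys=True) + "\n"
        Path(path).write_text(text)
        return hashlib.sha256(text.encode()).hexdigest()


def _build_block(cls, data: dict[str, Any], block: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - names)
    if unknown:
        raise ValueError(f"unknown keys in [{block}]: {', '.join(unknown)}")
    for key in ("stage1_fields", "stage2_fields"):
        if key in data:
            data[key] = tuple(data[key])
    return cls(**data)


def config_from_dict(data: dict[str, Any]) -> RunConfig:
    """Build a fully validated RunConfig from nested mappings.

    Unknown keys anywhere (top level or inside a block) are rejected before
    any computation runs.
    """
    data = dict(data)
    top_names = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(data) - top_names)
    if unknown:
        raise ValueError(f"unknown top-level config keys: {', '.join(unknown)}")
    kwargs: dict[str, Any] = {}
    if "model" in data:
        kwargs["model"] = parameters_from_dict(data.pop("model"))
    for name, cls in (("grid", GridConfig), ("fit", FitConfig), ("synth", SynthConfig)):
        if name in data:
            kwargs[name] = _build_block(cls, dict(data.pop(name)), name)
    kwargs.update(data)
    return RunConfig(**kwargs)


def load_config(path: Union[str, Path]) -> RunConfig:
    """Read a TOML or JSON run config (by suffix)."""
    path = Path(path)
    if path.suffix.lower() == ".toml":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    else:
        with open(path) as fh:
            data = json.load(fh)
    return config_from_dict(data)
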