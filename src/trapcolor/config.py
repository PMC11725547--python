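"""Run configuration: one hierarchical YAML file, strictly validated.

Defaults encode the constants the whole package runs on — the RGB→XYZ
matrix white, the fluid properties of air in water, the trap geometry,
and the inlet-air ramp — so a run with no config file reproduces the
reference conditions.  Unknown keys are rejected rather than ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

from .colorimetry import ReferenceWhite, default_white
from .hydraulics import FluidPair
from .synth_video import SyntheticScene
from .trap_sim import RampSchedule, TrapSpec

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Validated configuration for every command."""

    white: ReferenceWhite = field(default_factory=default_white)
    fluids: FluidPair = field(default_factory=FluidPair)
    trap: TrapSpec = field(default_factory=TrapSpec)
    ramp: RampSchedule = field(default_factory=RampSchedule)
    scene: SyntheticScene = field(default_factory=SyntheticScene)
    seed: int = 0

    def describe(self) -> dict[str, Any]:
        """Flat dict of every effective parameter, for run logging."""
        out: dict[str, Any] = {"seed": self.seed}
        for group in ("white", "fluids", "trap", "ramp", "scene"):
            obj = getattr(self, group)
            for f in fields(obj):
                out[f"{group}.{f.name}"] = getattr(obj, f.name)
        return out


_SECTIONS = {
    "white": ReferenceWhite,
    "fluids": FluidPair,
    "trap": TrapSpec,
    "ramp": RampSchedule,
    "scene": SyntheticScene,
}


def _build(cls, section: str, data: dict[str, Any]):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown keys in config section '{section}': {sorted(unknown)}")
    # tuples arrive from YAML as lists
    data = {k: tuple(v) if isinstance(v, list) else v for k, v in data.items()}
    return cls(**data)


def load_config(path=None) -> RunConfig:
    """Load a YAML config; a missing path yields pure defaults."""
    cfg = RunConfig()
    if path is None:
        return cfg
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return cfg
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a mapping")
    unknown = set(raw) - set(_SECTIONS) - {"seed"}
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    for section, cls in _SECTIONS.items():
        if section in raw:
            kwargs[section] = _build(cls, section, raw[section] or {})
    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])
    return RunConfig(**kwargs)
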