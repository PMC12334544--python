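"""Declarative run configuration (YAML), validated against a strict schema.

Config is data, never code: coefficient functions are selected by preset
name plus a parameters block, so runs are portable and auditable.  Unknown
keys are rejected.  The resolved config and its hash are embedded in every
output bundle for provenance.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import presets as _presets
from .ibm import LatticeConfig
from .pde import Grid, SolverConfig

__all__ = ["RunConfig", "load_config", "config_hash", "ConfigError"]


class ConfigError(ValueError):
    pass


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PresetBlock(_Strict):
    name: str
    growth: str | None = None           # range_expansion only
    drift_variant: str | None = None    # go_or_grow only
    parameters: dict[str, float] = Field(default_factory=dict)


class GridBlock(_Strict):
    x_min: float = 0.0
    x_max: float = 50.0
    y_min: float = 0.0
    y_max: float = 1.0
    n_x: int = 500
    n_y: int = 49


class SolverBlock(_Strict):
    rtol: float = 1e-6
    atol: float = 1e-9
    max_step: float = 0.1
    t_end: float = 10.0
    save_every: float = 0.1
    limiter: str = "koren"


class IBMBlock(_Strict):
    site_capacity: int = 100
    dt: float = 0.01
    n_steps: int = 100
    save_every: int = 10
    n_reps: int = 1
    seed: int = 0


class OutputBlock(_Strict):
    directory: str = "."
    formats: list[str] = Field(default_factory=lambda: ["hdf5", "json"])


class RunConfig(_Strict):
    preset: PresetBlock
    grid: GridBlock = Field(default_factory=GridBlock)
    solver: SolverBlock = Field(default_factory=SolverBlock)
    ibm: IBMBlock = Field(default_factory=IBMBlock)
    output: OutputBlock = Field(default_factory=OutputBlock)

    # ---- constructors ------------------------------------------------
    def build_preset(self) -> _presets.Preset:
        kwargs = {}
        if self.preset.name == "range_expansion" and self.preset.growth:
            kwargs["growth"] = self.preset.growth
        if self.preset.name == "go_or_grow" and self.preset.drift_variant:
            kwargs["drift_variant"] = self.preset.drift_variant
        if self.preset.parameters:
            try:
                kwargs["params"] = _presets.PresetParameters(**self.preset.parameters)
            except TypeError as err:
                raise ConfigError(f"bad preset parameters: {err}") from err
        return _presets.preset_by_name(self.preset.name, **kwargs)

    def build_grid(self) -> Grid:
        g = self.grid
        return Grid(x_min=g.x_min, x_max=g.x_max, y_min=g.y_min, y_max=g.y_max,
                    n_x=g.n_x, n_y=g.n_y)

    def build_solver_config(self) -> SolverConfig:
        import numpy as np
        s = self.solver
        n_saves = int(round(s.t_end / s.save_every))
        save_times = np.linspace(0.0, s.t_end, n_saves + 1)
        return SolverConfig(rtol=s.rtol, atol=s.atol, max_step=s.max_step,
                            save_times=save_times, limiter=s.limiter)

    def build_lattice(self) -> LatticeConfig:
        g, b = self.grid, self.ibm
        return LatticeConfig(x_min=g.x_min, x_max=g.x_max, y_min=g.y_min,
                             y_max=g.y_max, n_x=g.n_x, n_y=g.n_y, dt=b.dt,
                             site_capacity=b.site_capacity)

    def canonical_json(self) -> str:
        return json.dumps(self.model_dump(), sort_keys=True, separators=(",", ":"))


def config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(cfg.canonical_json().encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    try:
        return RunConfig(**raw)
    except ValidationError as err:
        locs = "; ".join(
            ".".join(str(p) for p in e["loc"]) + f": {e['msg']}" for e in err.errors()
        )
        raise ConfigError(f"{path}: {locs}") from err
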