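"""Experiment configuration: validation, loading, normalization.

A config declares everything a run needs — model, per-parameter sampling
specs, initial state, time grid, sample size, seed, level count, key
parameters — so that a finished run is reproducible from its manifest
alone.  Validation is strict (unknown keys rejected, all problems reported
at once) and a normalized copy with every default filled in is written
beside the outputs.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from ._errors import ConfigError
from .models import available_models
from .sampling import ParameterSpec

__all__ = ["ExperimentConfig", "ParameterConfig", "load_config"]


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ParameterConfig(_StrictModel):
    baseline: float | None = None
    dist: Literal["uniform", "normal"] = "uniform"
    var_pct: float | None = None
    min: float | None = None
    max: float | None = None
    sd: float | None = None
    nonnegative: bool = False

    @model_validator(mode="after")
    def _check(self) -> "ParameterConfig":
        if self.var_pct is None and (self.min is None or self.max is None):
            raise ValueError("either var_pct (with baseline) or min+max is required")
        if self.var_pct is not None and self.baseline is None:
            raise ValueError("var_pct requires a baseline")
        if self.min is not None and self.max is not None and self.min >= self.max:
            raise ValueError(f"min {self.min} must be < max {self.max}")
        return self

    def to_spec(self, name: str) -> ParameterSpec:
        bounds = (self.min, self.max) if self.min is not None and self.max is not None else None
        return ParameterSpec(
            name=name,
            baseline=self.baseline,
            distribution=self.dist,
            variation_pct=self.var_pct,
            bounds=bounds,
            sd=self.sd,
            nonnegative=self.nonnegative,
        )


class TimeGridConfig(_StrictModel):
    t_ini: float = 0.0
    t_end: float
    points: int = Field(ge=2)
    explicit: list[float] | None = None

    @model_validator(mode="after")
    def _check(self) -> "TimeGridConfig":
        if self.explicit is None and not self.t_ini < self.t_end:
            raise ValueError(f"t_ini {self.t_ini} must be < t_end {self.t_end}")
        return self


class SolverConfig(_StrictModel):
    method: str = "LSODA"
    rtol: float = Field(default=1e-8, gt=0)
    atol: float = Field(default=1e-10, gt=0)


class PlotConfig(_StrictModel):
    scale: Literal["linear", "log"] = "linear"
    formats: list[str] = ["png"]
    log_floor: float = 1e-3


class BifurcationConfig(_StrictModel):
    parameter: str
    min: float
    max: float
    points: int = Field(default=101, ge=3)


class ExperimentConfig(_StrictModel):
    model: str
    parameters: dict[str, ParameterConfig]
    n: int = Field(ge=2)
    seed: int  # mandatory: every run must be reproducible
    time_grid: TimeGridConfig
    initial_state: list[float] | None = None
    r: int = Field(default=4, ge=2)
    alpha: float = Field(default=0.01, gt=0, lt=1)
    key_parameters: list[str] = []
    combinations: list[str] = []
    scatter_times: list[float] = []
    bifurcation: list[BifurcationConfig] = []
    solver: SolverConfig = SolverConfig()
    plot: PlotConfig = PlotConfig()
    output_dir: str = "cscflow_out"

    @model_validator(mode="after")
    def _check(self) -> "ExperimentConfig":
        if self.model not in available_models():
            raise ValueError(
                f"unknown model {self.model!r}; available: {available_models()}"
            )
        for key in self.key_parameters:
            if key not in self.parameters:
                raise ValueError(f"key parameter {key!r} has no sampling spec")
        for b in self.bifurcation:
            pass  # parameter membership is checked against the model at run time
        return self

    def specs(self) -> list[ParameterSpec]:
        return [cfg.to_spec(name) for name, cfg in self.parameters.items()]

    def normalized_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(mode="json"), sort_keys=False)


def load_config(path) -> ExperimentConfig:
    """Load and validate a YAML experiment config.

    All validation problems are reported together; unknown keys are
    rejected.  The output directory is resolved relative to the config
    file's location.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed YAML in {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    try:
        cfg = ExperimentConfig.model_validate(raw)
    except ValidationError as exc:
        problems = "; ".join(
            f"{'.'.join(str(x) for x in err['loc'])}: {err['msg']}" for err in exc.errors()
        )
        raise ConfigError(f"invalid config {path}: {problems}") from exc
    out = Path(cfg.output_dir)
    if not out.is_absolute():
        # resolved against the invocation directory, so shipped (read-only)
        # configs write their bundles next to the caller
        cfg = cfg.model_copy(update={"output_dir": str((Path.cwd() / out).resolve())})
    return cfg
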