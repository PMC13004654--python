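"""Run configuration: JSON/YAML schema, validation, parameter resolution.

A config supplies exactly one parameter source — a named preset, the 14
inline constants, or a calibration spec — plus optional per-command blocks.
Unknown keys are rejected so that a typo cannot silently fall back to a
default.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .calibration import CalibrationSpec, build_design, get_preset
from .model import HormoneState, ModelParameters

__all__ = ["RunConfig", "load_config", "params_to_dict", "params_from_dict"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class InlineConstants(_Strict):
    k1: float
    k2: float
    k3: float
    k4: float
    k5: float
    k6: float
    Kd1: float
    Kd3: float
    Kd5: float
    Kd7: float
    n1: float
    n3: float
    n5: float
    n7: float


class CalibrationBlock(_Strict):
    target_state: tuple[float, float, float] = (1.0, 1.0, 15.0)  # TRH, TSH, TH
    saturation_fraction: float = 0.1
    half_lives: tuple[float, float, float] = (0.1, 1.0, 144.0)   # TRH, TSH, TH hours
    hill_coefficients: tuple[float, float, float, float]         # n1, n3, n5, n7


class SimulateBlock(_Strict):
    init: tuple[float, float, float] = (1.0, 1.0, 15.0)
    t_end: float = 1000.0
    n_out: int = 200


class SensitivityBlock(_Strict):
    delta: float = 0.1


class PopulationBlock(_Strict):
    varied: dict[str, float] = Field(default_factory=lambda: {"k1": 0.2})
    n_individuals: int = 500
    seed: int = 0


class OutputBlock(_Strict):
    directory: str = "."
    format: str = "csv"  # csv | json

    @model_validator(mode="after")
    def _check_format(self):
        if self.format not in ("csv", "json"):
            raise ValueError(f"output format must be csv or json, got {self.format!r}")
        return self


class RunConfig(_Strict):
    """Validated run configuration with exactly one parameter source."""

    preset: Optional[str] = None
    constants: Optional[InlineConstants] = None
    calibration: Optional[CalibrationBlock] = None
    simulate: SimulateBlock = Field(default_factory=SimulateBlock)
    sensitivity: SensitivityBlock = Field(default_factory=SensitivityBlock)
    population: PopulationBlock = Field(default_factory=PopulationBlock)
    output: OutputBlock = Field(default_factory=OutputBlock)

    @model_validator(mode="after")
    def _exactly_one_source(self):
        sources = [s for s in (self.preset, self.constants, self.calibration) if s is not None]
        if len(sources) != 1:
            raise ValueError(
                "exactly one parameter source required: preset | constants | calibration"
            )
        return self

    def resolve_parameters(self) -> ModelParameters:
        if self.preset is not None:
            return get_preset(self.preset)
        if self.constants is not None:
            return ModelParameters.from_constants(**self.constants.model_dump())
        assert self.calibration is not None
        c = self.calibration
        spec = CalibrationSpec(
            target_state=HormoneState(*c.target_state),
            saturation_fraction=c.saturation_fraction,
            half_lives=c.half_lives,
            hill_coefficients=c.hill_coefficients,
        )
        return build_design(spec)


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a JSON or YAML config file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return RunConfig.model_validate(data)


def params_to_dict(params: ModelParameters) -> dict[str, float]:
    """The 14 constants as a plain dict (round-trips via params_from_dict)."""
    return params.as_dict()


def params_from_dict(data: dict[str, float]) -> ModelParameters:
    return ModelParameters.from_constants(**data)
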