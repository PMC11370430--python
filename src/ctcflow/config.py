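"""YAML scenario/model configuration with schema validation.

Files carry SI units and an explicit ``schema_version``; unknown keys
are rejected so typos fail loudly. Seeds are mandatory for scenario
configs - nothing in a run may default its randomness silently.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

SCHEMA_VERSION = 1


class CellGroup(BaseModel):
    model_config = ConfigDict(extra="forbid")

    shape: Literal["biconcave", "sphere"] = "biconcave"
    phenotype: str = "rbc"
    count: int = Field(1, ge=0)
    diameter: float = Field(8e-6, gt=0)
    refinement: int = Field(2, ge=1)
    stiffness_multiplier: float = Field(1.0, gt=0)


class Driving(BaseModel):
    model_config = ConfigDict(extra="forbid")

    body_force: Optional[tuple[float, float, float]] = None   # N/m^3
    re_target: Optional[float] = None
    shear_rate: Optional[float] = None                        # 1/s
    wall_velocity: Optional[float] = None                     # m/s

    @model_validator(mode="after")
    def _one_of(self):
        given = [v is not None for v in
                 (self.body_force, self.re_target, self.shear_rate,
                  self.wall_velocity)]
        if sum(given) != 1:
            raise ValueError("exactly one driving mechanism must be given")
        return self


class ScenarioConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    schema_version: int
    geometry: Literal["pipe", "shear_box", "wedge", "micropost"]
    preset: Literal["desk", "paper"] = "desk"
    hct: float = Field(0.0, ge=0.0, le=0.5)
    d_rbc: Optional[float] = Field(None, gt=0)
    dx: float = Field(0.5e-6, gt=0)
    dt: float = Field(0.5e-7, gt=0)
    duration: float = Field(..., gt=0)          # s
    record_interval: float = Field(..., gt=0)   # s
    orientation: Literal["A", "B"] = "A"
    seed: int
    driving: Driving
    cells: list[CellGroup] = Field(default_factory=list)
    layout_file: Optional[str] = None           # micropost coordinates

    @model_validator(mode="after")
    def _intervals(self):
        if self.record_interval < self.dt:
            raise ValueError("record_interval must be >= dt")
        if self.schema_version != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported schema_version {self.schema_version}")
        return self


class ModelConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    schema_version: int
    kind: Literal["cnn", "rnn", "baseline"]
    epochs: int = Field(50, gt=0)
    batch_size: int = Field(32, gt=0)
    learning_rate: float = Field(1e-3, gt=0)
    dropout: float = Field(0.3, ge=0, lt=1)
    hidden: int = Field(32, gt=0)
    sequence_length: int = Field(128, gt=1)
    split: tuple[float, float, float] = (0.7, 0.15, 0.15)
    seed: int

    @model_validator(mode="after")
    def _checks(self):
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.schema_version != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported schema_version {self.schema_version}")
        return self

    def to_model_spec(self):
        from .ml import ModelSpec
        return ModelSpec(kind=self.kind, epochs=self.epochs,
                         batch_size=self.batch_size,
                         learning_rate=self.learning_rate,
                         dropout=self.dropout, hidden=self.hidden,
                         seed=self.seed)


def load_config(path) -> ScenarioConfig | ModelConfig:
    """Load and validate a YAML configuration file.

    Scenario files are recognized by a ``geometry`` key, classifier files
    by ``kind``. Schema violations raise with the offending keys listed.
    """
    path = Path(path)
    data = yaml.safe_load(path.read_text())
    if not isinstance(data, dict):
        raise ValueError(f"{path} does not contain a mapping")
    if "schema_version" not in data:
        raise ValueError("config must declare schema_version")
    if "geometry" in data:
        return ScenarioConfig.model_validate(data)
    if "kind" in data:
        return ModelConfig.model_validate(data)
    raise ValueError("config must contain either 'geometry' or 'kind'")


def dump_config(config: ScenarioConfig | ModelConfig, path) -> None:
    Path(path).write_text(
        yaml.safe_dump(config.model_dump(mode="json"), sort_keys=True))
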