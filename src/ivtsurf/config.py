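"""Run configuration: validated JSON/YAML schema for the pipeline and CLI.

All physics is deterministic; the ``seed`` only controls synthetic test
fixtures (random cubic IV curves).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .models import ModelParams, make_model


class ModelBlock(BaseModel):
    model_config = ConfigDict(extra="forbid", protected_namespaces=())

    name: str = "ord"
    variant: str = "endo"
    scales: dict[str, float] = Field(default_factory=dict)
    C_m_pF: float = 200.0

    @field_validator("name")
    @classmethod
    def _known_model(cls, v):
        if v not in ("ord", "toy"):
            raise ValueError(f"unknown model {v!r}")
        return v


class StimulusBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    amplitude_AF: float = -80.0
    duration_ms: float = 0.5
    onset_ms: float = 0.0


class ProtocolBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    bcl_ms: float = 800.0
    n_beats: int = 1000
    stimulus: StimulusBlock = Field(default_factory=StimulusBlock)


class GridBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    T_step_ms: float = 2.0
    V_min_mV: float = -100.0
    V_max_mV: float = 50.0
    V_step_mV: float = 2.0
    t_vc_ms: float = 1.0


class AnalysisBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    t_vc_thresholds_ms: float = 5.0
    na_eps_AF: float = 0.05
    zero_crossing_tol_AF: float = 1e-3


class RunConfig(BaseModel):
    """Top-level pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid", protected_namespaces=())

    model: ModelBlock = Field(default_factory=ModelBlock)
    protocol: ProtocolBlock = Field(default_factory=ProtocolBlock)
    grid: GridBlock = Field(default_factory=GridBlock)
    analysis: AnalysisBlock = Field(default_factory=AnalysisBlock)
    out_dir: str = "ivtsurf_out"
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        return cls.model_validate(data)

    def make_model(self):
        params = ModelParams(
            conductance_scales=self.model.scales,
            cell_variant=self.model.variant,
            C_m_pF=self.model.C_m_pF,
        )
        return make_model(self.model.name, params)

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
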