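"""Validated run configuration for the analysis pipeline.

YAML on disk, validated into pydantic models (unknown keys are rejected
with the offending key named).  Numeric inputs carry explicit unit
suffixes (_uM, _M, _s) in their field names, and a run is reproducible
from its config plus seed alone.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, field_validator

__all__ = ["InstrumentConfig", "RunConfig", "load_config"]


class InstrumentConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    dead_time_s: float = 2.7e-3
    regime: str = "balanced"          # "balanced" (2000+9000 pts) or "fine" (10000+9000 pts)
    noise_sd: float = 0.003           # intensity units

    @field_validator("regime")
    @classmethod
    def _check_regime(cls, v):
        if v not in ("balanced", "fine"):
            raise ValueError(f"regime must be 'balanced' or 'fine', got {v!r}")
        return v


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    seed: int = 1
    out_dir: str = "flipkin_run"
    scenarios: list[str] = ["HM", "NM"]
    nt_uM: float = 0.3                 # duplex after mixing (stopped flow)
    pt_series_uM: list[float] = [1.5, 3.0, 4.5, 7.5]
    titration_nt_uM: float = 1.0
    k1_M: float = 3e9                  # fixed bimolecular constant, M^-1 s^-1
    convention: str = "final_state"
    instrument: InstrumentConfig = InstrumentConfig()
    n_boot: int = 0                    # 0 disables the bootstrap stage
    group_size: int = 4

    @field_validator("scenarios")
    @classmethod
    def _check_scenarios(cls, v):
        for s in v:
            if s.upper() not in ("HM", "NM", "G448D"):
                raise ValueError(f"unknown scenario {s!r}")
        return [s.upper() for s in v]

    @field_validator("convention")
    @classmethod
    def _check_convention(cls, v):
        if v not in ("final_state", "total_bound"):
            raise ValueError(f"unknown convention {v!r}")
        return v


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)
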