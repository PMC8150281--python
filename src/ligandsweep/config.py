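"""Run configuration: JSON schema validation with aggregated errors."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, Field, ValidationError, field_validator, model_validator

from .errors import ConfigurationError
from .simulate import MISMATCH_ALLELES, AlleleSpec, SimConfig

__all__ = ["RescueConfig", "RunConfig", "validate_config"]


class RescueConfig(BaseModel):
    """Strict/relaxed thresholds and the high-input arm of the rescue analysis."""

    alpha_strict: float = Field(default=0.01, gt=0.0, le=1.0)
    alpha_relaxed: float = Field(default=0.05, gt=0.0, le=1.0)
    high_input_scale: float = Field(default=9.0, gt=0.0)
    #: offset added to the simulation seed for the high-input score noise,
    #: emulating an independent MS acquisition of the same material
    high_score_seed_offset: int = 104729

    @model_validator(mode="after")
    def _ordered(self) -> "RescueConfig":
        if self.alpha_strict >= self.alpha_relaxed:
            raise ValueError("alpha_strict must be smaller than alpha_relaxed")
        return self


class RunConfig(BaseModel):
    """Configuration of an end-to-end replay run."""

    sim: SimConfig = Field(default_factory=SimConfig)
    alphas: list[float] = Field(default_factory=lambda: [0.001, 0.01, 0.05])
    mismatch_alleles: list[AlleleSpec] = Field(
        default_factory=lambda: [a.model_copy() for a in MISMATCH_ALLELES]
    )
    rescue: RescueConfig = Field(default_factory=RescueConfig)
    profile_seed: Optional[int] = None
    chance_mc_samples: int = Field(default=20000, ge=1000)
    plot: bool = False

    @field_validator("alphas")
    @classmethod
    def _alphas_ok(cls, v: list[float]) -> list[float]:
        if not v:
            raise ValueError("alphas must not be empty")
        if any(not 0.0 < a <= 1.0 for a in v):
            raise ValueError("each alpha must lie in the half-open interval (0, 1]")
        if any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("alphas must be strictly ascending")
        return v

    def resolved_profile_seed(self) -> int:
        return self.sim.seed if self.profile_seed is None else self.profile_seed


def validate_config(config_file) -> RunConfig:
    """Parse and validate a JSON run configuration, filling defaults.

    All schema violations are reported together (pydantic aggregates them),
    wrapped in a :class:`ConfigurationError`.
    """
    path = Path(config_file)
    try:
        payload = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ConfigurationError(f"cannot parse {path}: {exc}") from exc
    try:
        return RunConfig.model_validate(payload)
    except ValidationError as exc:
        problems = "; ".join(
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}" for err in exc.errors()
        )
        raise ConfigurationError(f"invalid configuration {path}: {problems}") from exc
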