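"""Run configuration: every analysis threshold in one validated, auditable object."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class RunConfig(BaseModel):
    """All tunables of a pipeline run. Unknown keys are rejected.

    The configured values are echoed verbatim into every output artifact
    (CSV header comment + QC JSON) so a result can always be traced back to
    the exact thresholds that produced it.
    """

    model_config = ConfigDict(extra="forbid")

    pixel_size: float = Field(gt=0, default=0.65)  # µm / pixel
    gate_k: float = Field(gt=0, default=6.0)
    gate_min_cells: int = Field(ge=1, default=200)
    sphere_d_min: float = Field(gt=0, default=50.0)   # µm
    sphere_d_max: float = Field(gt=0, default=250.0)  # µm
    sphere_sf_min: float = Field(gt=0, le=1.0, default=0.5)
    neutral_role: str = "dmso"
    full_effect_role: str = "deab"
    control_aggregation: str = "median"
    mask_fraction: float = Field(gt=0, lt=1, default=0.5)
    hit_reduction_pct: float = Field(gt=0, default=25.0)
    t_fast: float = 75.0
    t_rebound: float = 25.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def config_hash(self) -> str:
        """Short stable hash of the full configuration, for audit trails."""
        canon = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]
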