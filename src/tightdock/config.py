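"""Declarative pipeline configuration with schema validation."""

from __future__ import annotations

from pathlib import Path

import yaml  # type: ignore[import-untyped]
from pydantic import BaseModel, ConfigDict, Field

__all__ = ["PipelineConfig", "ImagingStageConfig", "FramesStageConfig",
           "RelaxStageConfig", "load_config"]


class ImagingStageConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_free: int = Field(20, ge=0)
    n_tight: int = Field(20, ge=0)
    n_loose: int = Field(20, ge=0)
    pixel_size_nm: float = Field(0.5, gt=0)
    membrane_thickness_nm: float = Field(4.0, gt=0)
    interface_thickening_nm: float = Field(0.6, ge=0)
    noise_sigma: float = Field(0.05, ge=0)
    classification_threshold: float = Field(0.6, gt=0)
    smoothing_sigma_px: float = Field(1.0, ge=0)
    min_prominence_frac: float = Field(0.1, ge=0, le=1)
    min_separation_nm: float = Field(1.0, gt=0)
    line_width_px: int = Field(5, ge=1)


class FramesStageConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_membranes: int = Field(2, ge=1, le=2)
    n_lipids_per_leaflet: int = Field(100, ge=4)
    thickness_nm: float = Field(4.0, gt=0)
    intermembrane_distance_nm: float = Field(0.5, gt=0)
    mean_tilt_cos_inner: float = Field(0.8, ge=0, le=1)
    mean_tilt_cos_outer: float = Field(0.8, ge=0, le=1)
    positional_noise_nm: float = Field(0.0, ge=0)
    n_gap_waters: int = Field(0, ge=0)
    electrostatics_cutoff_nm: float = Field(1.2, gt=0)
    charges: dict[str, float] = Field(
        default_factory=lambda: {"P": -1.0, "N": 1.0, "chain": 0.0, "water": 0.0}
    )


class RelaxStageConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_replicas: int = Field(500, ge=1)
    duration_ns: float = Field(1.0, gt=0)
    sampling_interval_ns: float = Field(0.001, gt=0)
    noise_sigma: float = Field(0.05, ge=0)
    tau_tilt_ns: float = Field(0.05, gt=0)
    tau_area_ns: float = Field(0.15, gt=0)
    tau_thickness_ns: float = Field(0.40, gt=0)
    n_bootstrap: int = Field(1000, ge=1)
    support_threshold: float = Field(0.95, gt=0, le=1)


class PipelineConfig(BaseModel):
    """Full pipeline settings; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    out_dir: Path = Path("tightdock_out")
    seed: int = 0
    imaging: ImagingStageConfig = Field(default_factory=ImagingStageConfig)
    frames: FramesStageConfig = Field(default_factory=FramesStageConfig)
    relax: RelaxStageConfig = Field(default_factory=RelaxStageConfig)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(raw)
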