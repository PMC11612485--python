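"""Validated run configuration (YAML in, YAML out).

A run's resolved configuration is written beside its outputs so that
(inputs, config) -> outputs is fully reproducible; all stochastic stages
carry explicit seeds.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class DetectionParams(BaseModel):
    """Detection-chain parameters (defaults follow common puncta-counting
    conventions: in-ROI Otsu, 8-connectivity, 0.05-20 µm² size gate)."""

    model_config = ConfigDict(extra="forbid")

    smoothing_sigma_px: float = Field(1.0, ge=0)
    threshold_method: Literal["otsu", "fixed"] = "otsu"
    offset_factor: float = Field(1.0, gt=0)
    fixed_threshold: Optional[float] = None
    min_area_um2: float = Field(0.05, gt=0)
    max_area_um2: float = Field(20.0, gt=0)
    connectivity: Literal[4, 8] = 8
    overlap_cutoff: float = Field(0.5, gt=0, le=1)
    bridge_radius_um: float = Field(0.3, ge=0)
    declump_min_distance_um: float = Field(0.6, ge=0)
    gfp_dilate_px: int = Field(1, ge=0)

    @model_validator(mode="after")
    def _check(self):
        if self.min_area_um2 >= self.max_area_um2:
            raise ValueError("min_area_um2 must be < max_area_um2")
        if self.threshold_method == "fixed" and self.fixed_threshold is None:
            raise ValueError("fixed threshold method needs fixed_threshold")
        return self


class SimulateParams(BaseModel):
    model_config = ConfigDict(extra="forbid")

    preset: str
    n_subjects_per_group: int = Field(10, ge=2)
    images_per_subject: int = Field(5, ge=1)
    base_seed: int = Field(0, ge=0)


class StatsParams(BaseModel):
    model_config = ConfigDict(extra="forbid")

    measure: str = "red_only_density"
    comparisons: Optional[list[tuple[str, str]]] = None
    youngest_group: Optional[str] = None


class RunConfig(BaseModel):
    """End-to-end run: simulate (or read) images, detect, aggregate, test."""

    model_config = ConfigDict(extra="forbid")

    pixel_size_um: Optional[float] = Field(None, gt=0)
    channels: Optional[list[str]] = None
    input_dir: Optional[str] = None
    simulate: Optional[SimulateParams] = None
    detection: DetectionParams = DetectionParams()
    stats: StatsParams = StatsParams()
    out_dir: str = "results"

    @model_validator(mode="after")
    def _check(self):
        if self.simulate is None:
            if self.input_dir is None:
                raise ValueError("either simulate or input_dir is required")
            if self.pixel_size_um is None and self.channels is None:
                # sidecars may still provide them; defer to read time
                pass
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))
        return path
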