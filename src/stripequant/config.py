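"""Pipeline configuration.

All tunable parameters of the quantification pipeline live in one validated
model so that every run can be serialized alongside its outputs.  Positions
and widths are expressed in percent egg length (%EL): 0 at the anterior tip
of the embryo mask, 100 at the posterior tip.
"""

from __future__ import annotations

from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, field_validator


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


class PipelineConfig(BaseModel):
    """Parameters controlling segmentation, band extraction, profiling,
    stripe calling and group comparison.

    Channel indices refer to pages of the multi-page TIFF (0-based).
    """

    model_config = {"extra": "forbid"}

    target_channel: int = Field(0, ge=0, description="stripe gene channel (e.g. ftz)")
    control_channel: Optional[int] = Field(
        None, description="internal control channel (e.g. eve); QC only"
    )
    nuclear_channel: int = Field(1, ge=0, description="nuclear stain channel")

    dv_fraction: float = Field(
        0.10, gt=0.0, le=1.0,
        description="fraction of the dorsal-ventral extent kept in the central band",
    )
    bins: int = Field(100, ge=20, description="AP profile bins (1/bins egg lengths each)")
    smooth_window: int = Field(3, ge=1, description="moving-average window, in bins")
    background_percentile: float = Field(5.0, ge=0.0, le=50.0)
    peak_prominence: float = Field(
        0.05, gt=0.0, lt=1.0, description="peak prominence threshold, fraction of profile max"
    )
    boundary_fraction: float = Field(
        0.2, gt=0.0, lt=1.0, description="outer stripe boundary at this fraction of peak height"
    )
    expected_stripes: int = Field(7, ge=1)
    reference_centers: Optional[list[float]] = Field(
        None, description="expected stripe centers, %EL; enables fallback windows"
    )
    fallback_halfwidth: float = Field(
        2.5, gt=0.0, description="half-width of fallback stripe windows, %EL"
    )
    anterior: Literal["left", "right", "auto"] = "left"
    alpha: float = Field(0.05, gt=0.0, lt=1.0)
    seed: int = Field(0, ge=0)

    @field_validator("smooth_window")
    @classmethod
    def _odd_window(cls, v: int) -> int:
        if v % 2 == 0:
            raise ValueError("smooth_window must be odd (centered moving average)")
        return v

    @field_validator("reference_centers")
    @classmethod
    def _centers_valid(cls, v):
        if v is None:
            return v
        if any(not (0.0 < c < 100.0) for c in v):
            raise ValueError("reference_centers must lie strictly inside (0, 100) %EL")
        if any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("reference_centers must be strictly increasing")
        return v

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        try:
            data = yaml.safe_load(text) or {}
            return cls(**data)
        except Exception as exc:  # noqa: BLE001 - re-raised as config error
            raise ConfigError(f"invalid pipeline config: {exc}") from exc
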