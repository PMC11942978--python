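"""Run configuration: every threshold and range the analysis uses,
with the method's published values as defaults, loadable from TOML."""

from __future__ import annotations

import tomllib
from pathlib import Path
from typing import Literal

from pydantic import BaseModel, Field


class ShapeConfig(BaseModel):
    solbiati_benign: float = Field(2.0, gt=0)
    solbiati_malignant: float = Field(1.5, gt=0)
    thickness_mm: float = Field(10.0, gt=0)


class ContourConfig(BaseModel):
    step: int = Field(12, ge=1)
    probe_half_length: int = Field(10, ge=1)
    band_half_width: int = Field(1, ge=0)


class DopplerConfig(BaseModel):
    hsv_lower: tuple[int, int, int] = (0, 1, 1)
    hsv_upper: tuple[int, int, int] = (180, 255, 255)
    low_vasc_threshold: float = Field(25.0, gt=0)
    position_threshold: float = Field(0.5, gt=0)


class ElastoConfig(BaseModel):
    hard_classes: tuple[str, ...] = ("green", "blue")
    hard_threshold: float = Field(40.0, gt=0)
    paper_literal_translation: bool = False
    strip_color_scale: bool = True


class RunConfig(BaseModel):
    modality: Literal["bmode", "doppler", "elasto", "auto"] = "auto"
    px_per_mm: float = Field(10.0, gt=0)
    shape: ShapeConfig = ShapeConfig()
    contour: ContourConfig = ContourConfig()
    doppler: DopplerConfig = DopplerConfig()
    elasto: ElastoConfig = ElastoConfig()

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            return cls.model_validate(tomllib.load(fh))

    def snapshot(self) -> dict:
        """Flat JSON-safe copy embedded in each report for auditability."""
        return self.model_dump(mode="json")
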