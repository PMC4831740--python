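"""Pipeline configuration: detector parameters, fit options, paths."""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

from .errors import ValidationError

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Everything needed to run the staining-analysis pipeline end to end.

    Detector defaults follow the standard three-stage edge protocol for
    contrast-staining line profiles: 10-px profile bands, sigma = 4 px
    Gaussian filtering, |gradient| < 0.01 /mm zero tolerance, −0.2 /mm
    front trigger, 0.1 mm neighbourhood averaging and depth increments.
    """

    manifest: str = "manifest.json"
    output_dir: str = "ctstain_out"
    width_px: int = 10
    sigma_px: float = 4.0
    zero_tol: float = 0.01          # |gradient| ~ 0 tolerance, 1/mm
    drop_tol: float = 0.2           # front trigger, 1/mm
    window_mm: float = 0.1          # neighbourhood-average window
    increment_mm: float = 0.1       # depth-series step
    max_depth_mm: float = 2.5
    reference_depth_mm: float = 1.0  # depth for the bulk saturation fit
    saturation_levels: tuple[float, ...] = (0.90, 0.95, 0.99)
    normalisation: str = "cohort"   # "cohort" (global max) or "stain"
    area_method: str = "otsu"
    area_threshold: float | None = None
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        bad = []
        for name in ("sigma_px", "zero_tol", "drop_tol", "window_mm",
                     "increment_mm", "max_depth_mm", "reference_depth_mm"):
            if getattr(self, name) <= 0:
                bad.append(name)
        if self.width_px < 1:
            bad.append("width_px")
        levels = tuple(self.saturation_levels)
        if (not levels or any(not 0 < f < 1 for f in levels)
                or list(levels) != sorted(set(levels))):
            bad.append("saturation_levels")
        if self.normalisation not in ("cohort", "stain"):
            bad.append("normalisation")
        if self.area_method not in ("otsu", "fixed"):
            bad.append("area_method")
        if self.area_method == "fixed" and self.area_threshold is None:
            bad.append("area_threshold")
        if bad:
            raise ValidationError(f"invalid config fields: {', '.join(sorted(set(bad)))}")
        self.saturation_levels = levels

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config fields: {', '.join(sorted(unknown))}")
        if "saturation_levels" in data:
            data["saturation_levels"] = tuple(data["saturation_levels"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["saturation_levels"] = list(self.saturation_levels)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
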