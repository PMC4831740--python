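"""Shrinkage morphometry: threshold segmentation and normalised areas.

Contrast agents osmotically shrink soft-tissue samples; the standard
readout is the cross-sectional area of a mid-sample slice, normalised to
its unstained (day-0) value.  Segmentation is plain intensity
thresholding (Otsu by default) followed by keeping the largest connected
component and filling holes — stained samples have bright rims and dim
cores that naive thresholding would hollow out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label

from .errors import SegmentationError, ValidationError
from .profiles import SliceImage

__all__ = [
    "AreaSeries",
    "segment_cross_section",
    "cross_sectional_area",
    "normalise_area_series",
    "measure_area_series",
]


@dataclass(frozen=True)
class AreaSeries:
    """Per-day cross-sectional areas, normalised to the day-0 area."""

    table: pd.DataFrame  # columns: day, area_mm2, normalized_area
    sample_id: str = ""
    stain: str = "other"

    def __post_init__(self):
        t = self.table
        if not {"day", "area_mm2", "normalized_area"} <= set(t.columns):
            raise ValidationError("table must have day/area_mm2/normalized_area")
        if (t["area_mm2"] <= 0).any():
            raise ValidationError("areas must be positive")
        day0 = t.loc[t["day"] == 0, "normalized_area"]
        if day0.empty or not np.isclose(day0.iloc[0], 1.0):
            raise ValidationError("normalized area at day 0 must be exactly 1")


def segment_cross_section(
    sl: SliceImage, method: str = "otsu", threshold: float | None = None
) -> np.ndarray:
    """Binary mask of the sample cross-section.

    ``method='otsu'`` picks the threshold from the intensity histogram;
    ``method='fixed'`` uses the supplied ``threshold``.  Foreground is
    everything above threshold; only the largest connected component is
    kept and its holes are filled.
    """
    if method == "fixed":
        if threshold is None:
            raise ValidationError("fixed method requires a threshold")
        thr = float(threshold)
    elif method == "otsu":
        thr = float(threshold_otsu(sl.pixels))
    else:
        raise ValidationError(f"unknown method {method!r}")
    fg = sl.pixels > thr
    if not fg.any():
        raise SegmentationError(f"empty foreground at threshold {thr:.4g}")
    lab = label(fg, connectivity=2)
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    mask = lab == int(np.argmax(counts))
    return ndimage.binary_fill_holes(mask)


def cross_sectional_area(mask: np.ndarray, pixel_size_mm: float) -> float:
    """Area of a binary mask in mm²: pixel count × pixel_size²."""
    if pixel_size_mm <= 0:
        raise ValidationError("pixel_size_mm must be positive")
    n = int(np.count_nonzero(mask))
    if n == 0:
        raise ValidationError("mask is empty")
    return n * pixel_size_mm**2


def normalise_area_series(
    areas_by_day: dict[int, float], sample_id: str = "", stain: str = "other"
) -> AreaSeries:
    """Divide each day's area by the day-0 (unstained) area."""
    if 0 not in areas_by_day:
        raise ValidationError("day 0 area is required for normalisation")
    a0 = areas_by_day[0]
    if a0 <= 0:
        raise ValidationError("day 0 area must be positive")
    days = sorted(areas_by_day)
    table = pd.DataFrame(
        {
            "day": days,
            "area_mm2": [areas_by_day[d] for d in days],
            "normalized_area": [areas_by_day[d] / a0 for d in days],
        }
    )
    return AreaSeries(table=table, sample_id=sample_id, stain=stain)


def measure_area_series(
    slices: list[SliceImage], method: str = "otsu", threshold: float | None = None
) -> AreaSeries:
    """Segment each slice of one sample's day series and normalise to day 0."""
    if not slices:
        raise ValidationError("no slices supplied")
    ids = {(s.sample_id, s.stain) for s in slices}
    if len(ids) > 1:
        raise ValidationError(f"slices mix sample identities: {sorted(ids)}")
    areas = {}
    for sl in slices:
        mask = segment_cross_section(sl, method=method, threshold=threshold)
        areas[sl.day] = cross_sectional_area(mask, sl.pixel_size_mm)
    sid, stain = next(iter(ids))
    return normalise_area_series(areas, sample_id=sid, stain=stain)
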