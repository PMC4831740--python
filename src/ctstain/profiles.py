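"""Line-profile extraction, normalisation and gradient-threshold detectors.

The measurement unit throughout is a width-averaged line profile through the
centre of a transverse CT slice.  Sample edges and stain fronts are located
on the Gaussian-filtered profile by walking away from gradient extrema to
the first point where the gradient is approximately zero — the three-stage
edge rule used for contrast-staining studies of soft tissue:

1. filter the normalised profile with a Gaussian kernel (sigma = 4 px);
2. locate the maximum (minimum) intensity gradient;
3. the edge is the next point toward the sample centre where the absolute
   gradient falls below a small tolerance (default 0.01 per mm).

Stain fronts are found the same way, starting from a detected edge and
triggering on the first inward gradient below −0.2 per mm.

Gradient thresholds are interpreted per millimetre of the position axis on
the filtered normalised profile.  Because profiles are finely sampled
(7.5 um default), the |gradient| < tol band can fall between two samples;
the walks therefore also accept an exact sign change of the gradient,
taking the sample nearer zero.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .errors import DetectionError, NoEdgeError, ValidationError

__all__ = [
    "SliceImage",
    "LineProfile",
    "EdgePair",
    "FrontLocation",
    "extract_line_profile",
    "normalise_cohort",
    "smooth_profile",
    "gradient_per_mm",
    "detect_sample_edges",
    "neighbourhood_average",
    "detect_stain_front",
    "to_depth_series",
]

STAINS = ("I2KI", "PTA", "PMA", "other")


@dataclass(frozen=True)
class SliceImage:
    """A 2D grayscale tomographic slice with physical pixel size."""

    pixels: np.ndarray
    pixel_size_mm: float
    sample_id: str = ""
    stain: str = "other"
    day: int = 0

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.size == 0:
            raise ValidationError("pixels must be a non-empty 2D array")
        if self.pixel_size_mm <= 0:
            raise ValidationError("pixel_size_mm must be positive")
        if self.stain not in STAINS:
            raise ValidationError(f"stain must be one of {STAINS}")
        if self.day < 0:
            raise ValidationError("day must be >= 0")
        object.__setattr__(self, "pixels", px)


@dataclass(frozen=True)
class LineProfile:
    """Width-averaged intensity versus position (mm) along a slice diameter."""

    positions_mm: np.ndarray
    values: np.ndarray
    width_px: int = 10
    sample_id: str = ""
    stain: str = "other"
    day: int = 0
    normalised: bool = False

    def __post_init__(self):
        pos = np.asarray(self.positions_mm, dtype=float)
        val = np.asarray(self.values, dtype=float)
        if pos.shape != val.shape or pos.ndim != 1:
            raise ValidationError("positions and values must be 1D and the same length")
        if pos.size >= 2:
            d = np.diff(pos)
            if np.any(d <= 0) or not np.allclose(d, d[0], rtol=1e-6, atol=1e-12):
                raise ValidationError("positions must be strictly increasing and uniform")
        object.__setattr__(self, "positions_mm", pos)
        object.__setattr__(self, "values", val)

    @property
    def spacing_mm(self) -> float:
        return float(self.positions_mm[1] - self.positions_mm[0])

    def __len__(self) -> int:
        return self.positions_mm.size


@dataclass(frozen=True)
class EdgePair:
    """Positions of the two sample edges on the profile axis."""

    left_mm: float
    right_mm: float

    def __post_init__(self):
        if not self.left_mm < self.right_mm:
            raise ValidationError("left edge must lie left of the right edge")

    @property
    def width_mm(self) -> float:
        return self.right_mm - self.left_mm


@dataclass(frozen=True)
class FrontLocation:
    """Depth of a stain-front edge measured inward from a sample edge."""

    depth_mm: float
    side: str
    found: bool
    capped: bool = False  # True when the front ran past the sample half-width


def extract_line_profile(
    sl: SliceImage, row="centre", width_px: int = 10
) -> LineProfile:
    """Mean intensity over a ``width_px``-row band centred on ``row``.

    Positions are millimetres from the image's left edge.
    """
    if width_px < 1:
        raise ValidationError("width_px must be >= 1")
    nrow, ncol = sl.pixels.shape
    r = nrow // 2 if row == "centre" else int(row)
    lo = r - width_px // 2
    hi = lo + width_px
    if lo < 0 or hi > nrow:
        raise ValidationError(
            f"band rows [{lo}, {hi}) exceed image bounds (nrow={nrow})"
        )
    vals = sl.pixels[lo:hi, :].mean(axis=0)
    pos = np.arange(ncol) * sl.pixel_size_mm
    return LineProfile(
        positions_mm=pos,
        values=vals,
        width_px=width_px,
        sample_id=sl.sample_id,
        stain=sl.stain,
        day=sl.day,
    )


def normalise_cohort(profiles: list[LineProfile]) -> list[LineProfile]:
    """Divide every profile by the single maximum over the whole cohort.

    Mirrors the study-wide normalisation in which all line profiles of a
    staining experiment share one global maximum, so intensities are
    comparable across samples, stains and days.  At least one returned
    value equals exactly 1.0.
    """
    if not profiles:
        raise ValidationError("cannot normalise an empty cohort")
    gmax = max(float(np.max(p.values)) for p in profiles)
    if gmax <= 0:
        raise ValidationError("cohort maximum intensity is not positive")
    return [
        replace(p, values=p.values / gmax, normalised=True) for p in profiles
    ]


def smooth_profile(p: LineProfile, sigma_px: float = 4.0) -> LineProfile:
    """Gaussian smoothing (kernel truncated at 4 sigma, edge replication)."""
    if sigma_px <= 0:
        raise ValidationError("sigma_px must be positive")
    radius = int(4.0 * sigma_px + 0.5)
    if len(p) < 2 * radius + 1:
        raise ValidationError(
            f"profile of {len(p)} points is shorter than the kernel support "
            f"({2 * radius + 1} points)"
        )
    sm = gaussian_filter1d(p.values, sigma_px, mode="nearest", truncate=4.0)
    return replace(p, values=sm)


def gradient_per_mm(p: LineProfile) -> np.ndarray:
    """Intensity gradient in (normalised intensity)/mm.

    Central differences in the interior, one-sided at the two ends.
    """
    if len(p) < 3:
        raise ValidationError("need at least 3 points for a gradient")
    return np.gradient(p.values, p.spacing_mm)


def _walk_to_zero(grad: np.ndarray, start: int, stop: int, step: int, zero_tol: float):
    """First index from start (exclusive) toward stop where |grad| < zero_tol
    or the gradient changes sign (taking the sample nearer zero).  Returns
    None if no such point exists before ``stop``."""
    prev = start
    for i in range(start + step, stop + step, step):
        if abs(grad[i]) < zero_tol:
            return i
        if grad[i] * grad[prev] < 0:
            return i if abs(grad[i]) <= abs(grad[prev]) else prev
        prev = i
    return None


def detect_sample_edges(
    p: LineProfile, zero_tol: float = 0.01, sigma_px: float = 4.0
) -> EdgePair:
    """Locate the two sample edges on a background–sample–background profile.

    The profile is filtered (``sigma_px``), the global maximum of the
    gradient marks the rising (left) boundary and the global minimum the
    falling (right) boundary; each edge is the next point toward the sample
    centre where |gradient| drops below ``zero_tol`` (per mm).
    """
    sm = smooth_profile(p, sigma_px)
    grad = gradient_per_mm(sm)
    imax = int(np.argmax(grad))
    imin = int(np.argmin(grad))
    if grad[imax] <= zero_tol or grad[imin] >= -zero_tol:
        raise NoEdgeError(
            "no gradient extremum exceeds zero_tol; profile appears flat"
        )
    if imax >= imin:
        raise DetectionError(
            "gradient maximum is not left of the minimum; cannot identify edges"
        )
    n = len(p)
    ileft = _walk_to_zero(grad, imax, n - 1, +1, zero_tol)
    iright = _walk_to_zero(grad, imin, 0, -1, zero_tol)
    if ileft is None or iright is None:
        raise DetectionError("gradient never returned to zero inside the sample")
    if ileft >= iright:
        raise DetectionError("detected edges cross; detection failed")
    return EdgePair(
        left_mm=float(p.positions_mm[ileft]),
        right_mm=float(p.positions_mm[iright]),
    )


def neighbourhood_average(p: LineProfile, window_mm: float = 0.1) -> LineProfile:
    """Boxcar mean over a centred ``window_mm`` window, truncated at the ends.

    Removes short-length-scale tissue variability before intensities are
    read off at fixed depths.  The half-width is ``floor((window/2)/Δ)``
    samples; a window narrower than the sample spacing is the identity.
    """
    if window_mm < 0:
        raise ValidationError("window_mm must be non-negative")
    k = int((window_mm / 2.0) / p.spacing_mm)
    if k == 0:
        return p
    n = len(p)
    csum = np.concatenate(([0.0], np.cumsum(p.values)))
    lo = np.maximum(np.arange(n) - k, 0)
    hi = np.minimum(np.arange(n) + k, n - 1)
    out = (csum[hi + 1] - csum[lo]) / (hi - lo + 1)
    return replace(p, values=out)


def detect_stain_front(
    p: LineProfile,
    edges: EdgePair,
    side: str = "left",
    drop_tol: float = 0.2,
    zero_tol: float = 0.01,
    sigma_px: float = 4.0,
) -> FrontLocation:
    """Locate the stain-front edge inward of a detected sample edge.

    Moving from the given edge toward the sample centre on the filtered
    profile, the first point whose inward gradient is below ``−drop_tol``
    triggers the front; the next point inward with |gradient| < ``zero_tol``
    is the front edge.  ``found=False`` when no point passes ``drop_tol``
    (bulk-stained or unstained sample, where no sharp front exists).  A
    front that runs past the sample half-width is capped there and flagged.
    """
    if side not in ("left", "right"):
        raise ValidationError("side must be 'left' or 'right'")
    sm = smooth_profile(p, sigma_px)
    grad = gradient_per_mm(sm)
    pos = p.positions_mm
    ileft = int(np.searchsorted(pos, edges.left_mm))
    iright = int(np.searchsorted(pos, edges.right_mm))
    if not (0 <= ileft < iright < len(p)):
        raise ValidationError("edges lie outside the profile")
    imid = (ileft + iright) // 2
    half_width = edges.width_mm / 2.0

    if side == "left":
        idx = range(ileft, imid + 1)
        inward = grad
        step = +1
        edge_mm = edges.left_mm
    else:
        idx = range(iright, imid - 1, -1)
        inward = -grad
        step = -1
        edge_mm = edges.right_mm

    trigger = None
    for i in idx:
        if inward[i] < -drop_tol:
            trigger = i
            break
    if trigger is None:
        return FrontLocation(depth_mm=float("nan"), side=side, found=False)

    ifront = _walk_to_zero(grad, trigger, imid, step, zero_tol)
    if ifront is None:
        return FrontLocation(depth_mm=half_width, side=side, found=True, capped=True)
    depth = abs(float(pos[ifront]) - edge_mm)
    return FrontLocation(depth_mm=depth, side=side, found=True)


def to_depth_series(
    profiles_by_day: dict[int, LineProfile],
    edges_by_day: dict[int, EdgePair],
    increment_mm: float = 0.1,
    max_depth_mm: float | None = None,
    window_mm: float = 0.1,
) -> pd.DataFrame:
    """Neighbourhood-averaged intensity at fixed depths from each edge, per day.

    For every depth increment inward of each detected edge the
    neighbourhood-averaged intensity is linearly interpolated and the two
    sides averaged.  Depths beyond a day's sample half-width are missing
    (NaN), not zero, so downstream fits can exclude them.  Returns a tidy
    frame with columns (sample_id, stain, day, depth_mm, intensity_left,
    intensity_right, intensity).
    """
    if not profiles_by_day:
        raise ValidationError("no profiles supplied")
    ids = {(p.sample_id, p.stain) for p in profiles_by_day.values()}
    if len(ids) > 1:
        raise ValidationError(f"profiles mix sample identities: {sorted(ids)}")
    if set(profiles_by_day) != set(edges_by_day):
        raise ValidationError("profiles and edges must cover the same days")

    if max_depth_mm is None:
        max_depth_mm = max(e.width_mm for e in edges_by_day.values()) / 2.0
    depths = np.arange(0.0, max_depth_mm + increment_mm / 2, increment_mm)

    rows = []
    for day in sorted(profiles_by_day):
        p = profiles_by_day[day]
        e = edges_by_day[day]
        avg = neighbourhood_average(p, window_mm)
        half = e.width_mm / 2.0
        left = np.interp(e.left_mm + depths, avg.positions_mm, avg.values)
        right = np.interp(e.right_mm - depths, avg.positions_mm, avg.values)
        valid = depths <= half
        left = np.where(valid, left, np.nan)
        right = np.where(valid, right, np.nan)
        for d, lv, rv in zip(depths, left, right):
            pair = [v for v in (lv, rv) if not np.isnan(v)]
            rows.append(
                {
                    "sample_id": p.sample_id,
                    "stain": p.stain,
                    "day": day,
                    "depth_mm": float(d),
                    "intensity_left": lv,
                    "intensity_right": rv,
                    "intensity": float(np.mean(pair)) if pair else np.nan,
                }
            )
    return pd.DataFrame(rows)
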