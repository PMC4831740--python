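"""Staining-kinetics models: saturation curves, optimal times, front propagation.

Three one-dimensional models summarise how contrast agents move through
near-cylindrical soft-tissue samples:

* **Saturation curve** — normalised intensity at a fixed depth rises as
  ``I(t) = I0 + (Imax − I0)(1 − e^{−k t})`` where ``I0`` is the unstained
  intensity, ``Imax`` the asymptote and ``k`` (1/days) the rate, which is
  tied to the local stain concentration ramp-up.  Note the *negative*
  exponent: only a decaying exponential saturates, and only this sign is
  consistent with published fitted constants for I2KI/PTA/PMA staining
  (e.g. 99/87/98% of Imax reached after 4 days).
* **Optimal staining time** — inverting the per-depth saturation fits at a
  saturation level ``f`` gives times that grow exponentially with depth,
  ``t_stain(x) = A e^{c x}``; ``A`` (days) is the surface time and ``c``
  (1/mm) the depth penalty.
* **Front propagation** — for agents with a sharp stain front, the front
  depth follows ``x(t) = C (1 − e^{−K t})``; ``C`` (mm) is the asymptotic
  penetration depth and hence an upper limit on the radius of a sample
  that can ever be stained through.

All fits are unweighted nonlinear least squares; 95% confidence intervals
come from the linearised parameter covariance with a t-quantile on the
residual degrees of freedom.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import FitError, ValidationError

__all__ = [
    "SaturationFit",
    "StainTimeModel",
    "FrontModel",
    "fit_saturation",
    "saturation_fraction",
    "saturation_time",
    "fit_depth_profile",
    "fit_staining_time_model",
    "predict_staining_time",
    "fit_front_model",
    "max_penetration_depth",
    "predict_front_depth",
]


def _confidence_intervals(params, pcov, n, alpha=0.05):
    """Linearised (Wald) CIs: estimate ± t_{1−α/2, n−p} · SE."""
    p = len(params)
    if pcov is None or not np.all(np.isfinite(pcov)) or n <= p:
        return None
    se = np.sqrt(np.diag(pcov))
    tq = stats.t.ppf(1 - alpha / 2, df=n - p)
    return tuple((float(v - tq * s), float(v + tq * s)) for v, s in zip(params, se))


@dataclass(frozen=True)
class SaturationFit:
    """Fitted saturation curve ``I(t) = I0 + (Imax − I0)(1 − e^{−k t})``."""

    I0: float
    Imax: float
    k: float                      # 1/days
    ci: tuple | None = None       # ((lo, hi) per parameter) at 95%
    residual_norm: float = 0.0
    n: int = 0
    depth_mm: float | str = "bulk"
    stain: str = "other"

    def __post_init__(self):
        if not (0 <= self.I0 < self.Imax):
            raise ValidationError("need 0 <= I0 < Imax")
        if self.k <= 0:
            raise ValidationError("need k > 0")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return self.I0 + (self.Imax - self.I0) * (1.0 - np.exp(-self.k * t))


@dataclass(frozen=True)
class StainTimeModel:
    """Optimal staining time versus depth, ``t_stain(x) = A e^{c x}``."""

    A: float                      # days
    c: float                      # 1/mm
    saturation_level: float = 0.9
    ci: tuple | None = None
    residual_norm: float = 0.0
    n: int = 0

    def __post_init__(self):
        if self.A <= 0 or self.c <= 0:
            raise ValidationError("need A > 0 and c > 0")
        if not 0 < self.saturation_level < 1:
            raise ValidationError("saturation_level must be in (0, 1)")


@dataclass(frozen=True)
class FrontModel:
    """Stain-front depth versus time, ``x(t) = C (1 − e^{−K t})``."""

    C: float                      # mm
    K: float                      # 1/days
    ci: tuple | None = None
    residual_norm: float = 0.0
    n: int = 0
    stain: str = "other"

    def __post_init__(self):
        if self.C <= 0 or self.K <= 0:
            raise ValidationError("need C > 0 and K > 0")


def _saturation_model(t, I0, Imax, k):
    return I0 + (Imax - I0) * (1.0 - np.exp(-k * t))


def fit_saturation(times, intensities, depth_mm="bulk", stain="other") -> SaturationFit:
    """Least-squares fit of the saturation curve to an intensity time series.

    Initialisation: I0 from the first intensity, Imax from the maximum,
    k = 1/day; bounds keep 0 <= I0, Imax <= 1.5 and k > 0.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValidationError("times and intensities must be 1D and matched")
    if np.unique(t).size < 3:
        raise ValidationError("need at least 3 distinct timepoints")
    if np.ptp(y) < 1e-12:
        raise FitError(
            "intensity series is constant; k is unidentifiable",
            diagnostics={"ptp": float(np.ptp(y))},
        )
    y0 = float(np.clip(y[np.argmin(t)], 0.0, 1.5))
    ymax = float(np.clip(np.max(y), y0 + 1e-3, 1.5))
    p0 = [y0, ymax, 1.0]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, pcov = optimize.curve_fit(
                _saturation_model,
                t,
                y,
                p0=p0,
                bounds=([0.0, 0.0, 1e-9], [1.5, 1.5, np.inf]),
                maxfev=10000,
            )
    except RuntimeError as exc:
        raise FitError(f"saturation fit did not converge: {exc}",
                       diagnostics={"p0": p0, "n": t.size}) from exc
    I0, Imax, k = (float(v) for v in popt)
    if not I0 < Imax:
        raise FitError("fit degenerate: I0 >= Imax",
                       diagnostics={"I0": I0, "Imax": Imax})
    resid = y - _saturation_model(t, *popt)
    return SaturationFit(
        I0=I0, Imax=Imax, k=k,
        ci=_confidence_intervals(popt, pcov, t.size),
        residual_norm=float(np.linalg.norm(resid)),
        n=int(t.size), depth_mm=depth_mm, stain=stain,
    )


def saturation_fraction(fit: SaturationFit, t: float) -> float:
    """Intensity at time ``t`` as a fraction of the fitted maximum Imax."""
    if t < 0:
        raise ValidationError("t must be non-negative")
    return float(fit(t) / fit.Imax)


def saturation_time(fit: SaturationFit, f: float) -> float:
    """Time at which intensity reaches the fraction ``f`` of Imax.

    Closed-form inverse ``t = −(1/k) ln(1 − (f·Imax − I0)/(Imax − I0))``.
    The level is a fraction of the *absolute* maximum intensity, so targets
    at or below I0 are already met (returns 0 with a warning) and targets
    at or above Imax are unreachable.
    """
    target = f * fit.Imax
    if target >= fit.Imax:
        raise ValidationError(
            f"target f*Imax = {target:.4g} is >= Imax = {fit.Imax:.4g}: unreachable"
        )
    if target <= fit.I0:
        warnings.warn(
            "target intensity is at or below I0; already satisfied at t = 0",
            stacklevel=2,
        )
        return 0.0
    return -math.log(1.0 - (target - fit.I0) / (fit.Imax - fit.I0)) / fit.k


def fit_depth_profile(depth_series: pd.DataFrame, min_days: int = 3
                      ) -> dict[float, SaturationFit]:
    """Independent saturation fit at every depth increment of a depth series.

    ``depth_series`` is the tidy (day, depth_mm, intensity) table produced
    by :func:`ctstain.profiles.to_depth_series`.  Depths with fewer than
    ``min_days`` valid days, or whose fit fails, are excluded from the
    returned mapping.  Raises if every depth fails.
    """
    required = {"day", "depth_mm", "intensity"}
    if not required <= set(depth_series.columns):
        raise ValidationError(f"depth series must have columns {sorted(required)}")
    stain = depth_series["stain"].iloc[0] if "stain" in depth_series else "other"
    fits: dict[float, SaturationFit] = {}
    for depth, grp in depth_series.groupby("depth_mm"):
        sub = grp.dropna(subset=["intensity"])
        if sub["day"].nunique() < min_days:
            continue
        try:
            fits[float(depth)] = fit_saturation(
                sub["day"].to_numpy(float),
                sub["intensity"].to_numpy(float),
                depth_mm=float(depth),
                stain=stain,
            )
        except FitError:
            continue
    if not fits:
        raise FitError("saturation fit failed at every depth")
    return fits


def _stain_time_model(x, A, c):
    return A * np.exp(c * x)


def fit_staining_time_model(depths_mm, times_days, f: float) -> StainTimeModel:
    """Fit ``t_stain = A e^{c x}`` to per-depth saturation times.

    Nonlinear least squares on the original (linear) scale, initialised
    from the log-linear regression ``ln t = ln A + c x``.
    """
    x = np.asarray(depths_mm, dtype=float)
    t = np.asarray(times_days, dtype=float)
    if x.shape != t.shape or x.ndim != 1:
        raise ValidationError("depths and times must be 1D and matched")
    if x.size < 3:
        raise ValidationError("need at least 3 (depth, time) pairs")
    if np.unique(x).size < 2:
        raise ValidationError("need at least 2 distinct depths")
    if np.any(t <= 0):
        raise ValidationError("staining times must be positive")
    slope, intercept = np.polyfit(x, np.log(t), 1)
    p0 = [math.exp(intercept), max(slope, 1e-6)]
    try:
        popt, pcov = optimize.curve_fit(
            _stain_time_model, x, t, p0=p0, maxfev=10000
        )
    except RuntimeError as exc:
        raise FitError(f"staining-time fit did not converge: {exc}") from exc
    A, c = (float(v) for v in popt)
    resid = t - _stain_time_model(x, *popt)
    return StainTimeModel(
        A=A, c=c, saturation_level=f,
        ci=_confidence_intervals(popt, pcov, x.size),
        residual_norm=float(np.linalg.norm(resid)),
        n=int(x.size),
    )


def predict_staining_time(m: StainTimeModel, depth_mm: float) -> float:
    """Predicted staining time (days) to reach the model's saturation level
    at ``depth_mm`` into the sample: ``A e^{c x}``."""
    if depth_mm < 0:
        raise ValidationError("depth_mm must be non-negative")
    return m.A * math.exp(m.c * depth_mm)


def _front_model(t, C, K):
    return C * (1.0 - np.exp(-K * t))


def fit_front_model(times_days, front_depths_mm, stain="other") -> FrontModel:
    """Fit ``x = C (1 − e^{−K t})`` to detected front depths over time.

    Missing-front days (NaN depths) are excluded.  Initialisation:
    C = 1.2 × max depth, K = 1 / mean(t).
    """
    t = np.asarray(times_days, dtype=float)
    x = np.asarray(front_depths_mm, dtype=float)
    if t.shape != x.shape or t.ndim != 1:
        raise ValidationError("times and depths must be 1D and matched")
    ok = np.isfinite(x) & np.isfinite(t)
    t, x = t[ok], x[ok]
    if t.size < 3:
        raise FitError(
            "fewer than 3 valid front observations",
            diagnostics={"n_valid": int(t.size)},
        )
    tbar = float(np.mean(t[t > 0])) if np.any(t > 0) else 1.0
    p0 = [1.2 * float(np.max(x)) if np.max(x) > 0 else 1.0, 1.0 / tbar]
    try:
        popt, pcov = optimize.curve_fit(_front_model, t, x, p0=p0, maxfev=10000)
    except RuntimeError as exc:
        raise FitError(f"front fit did not converge: {exc}",
                       diagnostics={"p0": p0}) from exc
    C, K = (float(v) for v in popt)
    resid = x - _front_model(t, *popt)
    return FrontModel(
        C=C, K=K,
        ci=_confidence_intervals(popt, pcov, t.size),
        residual_norm=float(np.linalg.norm(resid)),
        n=int(t.size), stain=stain,
    )


def max_penetration_depth(m: FrontModel) -> float:
    """Asymptotic front depth C (mm): the upper radius limit of a sample
    that the stain can ever penetrate through."""
    return m.C


def predict_front_depth(m: FrontModel, t: float) -> float:
    """Front depth (mm) after ``t`` days: ``C (1 − e^{−K t})``."""
    if t < 0:
        raise ValidationError("t must be non-negative")
    return m.C * (1.0 - math.exp(-m.K * t))
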