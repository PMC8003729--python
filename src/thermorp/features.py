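"""Per-curve characteristics of a finger rewarming trace.

From each cleaned series eleven characteristics are computed. Four are static:
baseline temperature ``t_base``, post-cooling temperature ``t_0``, recording
``duration``, and the recovery percentage
``R% = 100 * (t_end - t_0) / (t_base - t_0)``. Plateau-related quantities are
the end temperature ``t_end`` and the time needed to reach it. Five more
describe the sigmoid shape of the rise (maximum rewarming slope, half-recovery
temperature and time, and the lower/upper lag times from the tangent
construction); these are only defined for S-shaped curves. For horizontal
curves — which defeat sigmoid analysis — the substitute half-recovery level
``t_50* = (t_end - t_0)/2 + t_0`` and a binary curve-type label replace the
sigmoid quantities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .series import SeriesError, TemperatureSeries

S_SHAPED = "S_shaped"
HORIZONTAL = "horizontal"

#: Column order of the per-finger features table.
FEATURE_COLUMNS = [
    "subject_id",
    "hand",
    "finger",
    "t_base",
    "t_0",
    "t_end",
    "time_to_t_end",
    "t_50",
    "time_to_t_50",
    "lower_lag",
    "upper_lag",
    "slope_rew",
    "R_pct",
    "t_50_star",
    "curve_type",
    "duration",
]


class FeatureError(ValueError):
    """Series unsuitable for feature extraction."""


@dataclass(frozen=True)
class FeatureConfig:
    """Tunable rules of the feature extractor.

    plateau_window : minutes at the end of the recording averaged to give t_end.
    plateau_epsilon : °C band around t_end defining "plateau attained".
    slope_window : samples per sliding least-squares window for the max slope.
    r_pct_threshold, slope_threshold : S-shaped classification criterion —
        a curve is S-shaped iff R% >= r_pct_threshold and the maximum windowed
        slope >= slope_threshold °C/min.
    """

    plateau_window: float = 2.0
    plateau_epsilon: float = 0.5
    slope_window: int = 5
    r_pct_threshold: float = 30.0
    slope_threshold: float = 0.2


DEFAULT_CONFIG = FeatureConfig()


@dataclass(frozen=True)
class CurveFeatures:
    """The eleven per-curve characteristics (sigmoid fields None if horizontal)."""

    t_base: float
    t_0: float
    t_end: float
    time_to_t_end: float
    duration: float
    R_pct: float
    t_50_star: float
    curve_type: str
    t_50: float | None = None
    time_to_t_50: float | None = None
    lower_lag: float | None = None
    upper_lag: float | None = None
    slope_rew: float | None = None


@dataclass(frozen=True)
class StaticFeatures:
    t_base: float
    t_0: float
    t_end: float
    time_to_t_end: float
    duration: float
    R_pct: float
    t_50_star: float


@dataclass(frozen=True)
class SigmoidFeatures:
    t_50: float
    time_to_t_50: float
    lower_lag: float
    upper_lag: float
    slope_rew: float


def _plateau(tau: np.ndarray, temps: np.ndarray, cfg: FeatureConfig) -> tuple[float, float]:
    """End temperature (mean of the final window) and first time the series
    enters and remains within ``plateau_epsilon`` of it."""
    t_end = float(temps[tau >= tau[-1] - cfg.plateau_window].mean())
    outside = np.abs(temps - t_end) > cfg.plateau_epsilon
    if outside.any():
        last = np.flatnonzero(outside)[-1]
        if last + 1 >= tau.size:
            # never settles inside the band; plateau attained only at the end
            return t_end, float(tau[-1])
        return t_end, float(tau[last + 1])
    return t_end, float(tau[0])


def compute_static_features(
    series: TemperatureSeries, config: FeatureConfig = DEFAULT_CONFIG
) -> StaticFeatures:
    """Static characteristics: t_base, t_0, t_end, time to t_end, duration, R%, t_50*."""
    t_base = float(series.baseline_temps().mean())
    tau, temps = series.rewarming()
    t_0 = float(temps[0])
    if t_base <= t_0:
        raise FeatureError(
            f"t_base ({t_base:.2f}) <= t_0 ({t_0:.2f}): no cooling response, R% undefined"
        )
    t_end, time_to_t_end = _plateau(tau, temps, config)
    r_pct = 100.0 * (t_end - t_0) / (t_base - t_0)
    t_50_star = (t_end - t_0) / 2.0 + t_0
    return StaticFeatures(
        t_base=t_base,
        t_0=t_0,
        t_end=t_end,
        time_to_t_end=time_to_t_end,
        duration=float(tau[-1]),
        R_pct=r_pct,
        t_50_star=t_50_star,
    )


def max_windowed_slope(
    tau: np.ndarray, temps: np.ndarray, window: int
) -> tuple[float, float, float]:
    """Largest least-squares slope over a sliding window of ``window`` samples.

    Returns ``(slope, t_center, value_at_center)`` where the value is taken
    from the fitted line at the window center. Ties break toward the earliest
    window.
    """
    n = tau.size
    if window > n:
        raise FeatureError(f"slope window ({window}) longer than series ({n})")
    tw = np.lib.stride_tricks.sliding_window_view(tau, window)
    yw = np.lib.stride_tricks.sliding_window_view(temps, window)
    tm = tw.mean(axis=1, keepdims=True)
    ym = yw.mean(axis=1, keepdims=True)
    denom = ((tw - tm) ** 2).sum(axis=1)
    slopes = ((tw - tm) * (yw - ym)).sum(axis=1) / denom
    i = int(np.argmax(slopes))  # argmax returns the first maximum
    return float(slopes[i]), float(tm[i, 0]), float(ym[i, 0])


def _crossing_time(tau: np.ndarray, temps: np.ndarray, level: float) -> float:
    """First time the trace reaches ``level``, linearly interpolated."""
    above = temps >= level
    if above[0]:
        return float(tau[0])
    if not above.any():
        raise FeatureError(f"series never reaches level {level:.2f} °C")
    i = int(np.argmax(above))
    t0, t1 = tau[i - 1], tau[i]
    y0, y1 = temps[i - 1], temps[i]
    return float(t0 + (level - y0) / (y1 - y0) * (t1 - t0))


def fit_sigmoid_features(
    series: TemperatureSeries, config: FeatureConfig = DEFAULT_CONFIG
) -> SigmoidFeatures:
    """Sigmoid characteristics of an S-shaped rewarming curve.

    The maximum rewarming slope is the largest sliding-window least-squares
    slope. The lag times come from the classical tangent construction: the
    tangent at the point of maximum slope is intersected with the horizontal
    levels ``t_0`` (lower lag) and ``t_end`` (upper lag). The caller is
    responsible for only passing curves classified as S-shaped.
    """
    static = compute_static_features(series, config)
    tau, temps = series.rewarming()
    slope, t_star, y_star = max_windowed_slope(tau, temps, config.slope_window)
    if slope <= 0:
        raise FeatureError("non-positive maximum slope; curve is not rising")
    level = (static.t_0 + static.t_end) / 2.0
    time_to_t_50 = _crossing_time(tau, temps, level)
    lower_lag = t_star + (static.t_0 - y_star) / slope
    upper_lag = t_star + (static.t_end - y_star) / slope
    return SigmoidFeatures(
        t_50=level,
        time_to_t_50=time_to_t_50,
        lower_lag=lower_lag,
        upper_lag=upper_lag,
        slope_rew=slope,
    )


def classify_curve(
    series: TemperatureSeries, config: FeatureConfig = DEFAULT_CONFIG
) -> str:
    """Label a curve S-shaped or horizontal.

    S-shaped requires both a substantial recovery (R% above threshold) and a
    clear rising phase (maximum windowed slope above threshold); anything
    else — flat or drifting traces included — is horizontal.
    """
    static = compute_static_features(series, config)
    tau, temps = series.rewarming()
    if config.slope_window > tau.size:
        raise FeatureError("series shorter than the slope window")
    slope, _, _ = max_windowed_slope(tau, temps, config.slope_window)
    if static.R_pct >= config.r_pct_threshold and slope >= config.slope_threshold:
        return S_SHAPED
    return HORIZONTAL


def compute_features(
    series: TemperatureSeries, config: FeatureConfig = DEFAULT_CONFIG
) -> CurveFeatures:
    """All per-curve characteristics; sigmoid fields are None for horizontal curves."""
    static = compute_static_features(series, config)
    curve_type = classify_curve(series, config)
    sig = fit_sigmoid_features(series, config) if curve_type == S_SHAPED else None
    return CurveFeatures(
        t_base=static.t_base,
        t_0=static.t_0,
        t_end=static.t_end,
        time_to_t_end=static.time_to_t_end,
        duration=static.duration,
        R_pct=static.R_pct,
        t_50_star=static.t_50_star,
        curve_type=curve_type,
        t_50=sig.t_50 if sig else None,
        time_to_t_50=sig.time_to_t_50 if sig else None,
        lower_lag=sig.lower_lag if sig else None,
        upper_lag=sig.upper_lag if sig else None,
        slope_rew=sig.slope_rew if sig else None,
    )


def features_frame(
    series: Iterable[TemperatureSeries], config: FeatureConfig = DEFAULT_CONFIG
) -> pd.DataFrame:
    """One-row-per-finger features table for a collection of labelled series."""
    rows = []
    for s in series:
        if s.label is None:
            raise SeriesError("series must be labelled (subject_id, hand, finger)")
        f = compute_features(s, config)
        rows.append(
            {
                "subject_id": s.label[0],
                "hand": s.label[1],
                "finger": s.label[2],
                **{k: getattr(f, k) for k in (
                    "t_base", "t_0", "t_end", "time_to_t_end", "t_50",
                    "time_to_t_50", "lower_lag", "upper_lag", "slope_rew",
                    "R_pct", "t_50_star", "curve_type", "duration",
                )},
            }
        )
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)
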