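"""Per-finger temperature time series and ROI extraction from thermal frame stacks.

A rewarming recording is represented as a :class:`TemperatureSeries`: finger
temperature (°C) against time (minutes) covering a pre-cooling baseline window,
the cold-water challenge, and the passive rewarming phase. Series either come
from a simulator or are extracted from thermal video frames by averaging pixels
inside elliptical regions of interest drawn over the middle phalanx of each
finger.

Coordinate convention for ROIs: pixel ``(0, 0)`` is the top-left corner of the
frame, ``x`` increases rightward (columns), ``y`` increases downward (rows),
and the ellipse rotation angle is measured counter-clockwise in this x/y frame.
A pixel belongs to an ellipse when its *center* satisfies the standard ellipse
inequality after rotating into the ellipse frame.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

HANDS = ("L", "R")
FINGERS = (2, 3, 4, 5)  # index..little finger, ulnar four per hand

#: CSV column order used for all series files.
SERIES_COLUMNS = ["subject_id", "hand", "finger", "time_min", "temp_C"]


class SeriesError(ValueError):
    """Invalid temperature series."""


class ROIError(ValueError):
    """Invalid region of interest."""


class ArtefactError(ValueError):
    """Series too corrupted to clean."""


@dataclass(frozen=True)
class EllipseROI:
    """Elliptical region of interest over one finger's middle phalanx.

    Parameters
    ----------
    center_x, center_y : float
        Ellipse center in pixel coordinates (x rightward, y downward).
    semi_axis_x, semi_axis_y : float
        Semi-axes in pixels, along the ellipse's own axes before rotation.
    rotation_deg : float
        Counter-clockwise rotation of the ellipse axes, degrees.
    label : tuple
        ``(hand, finger)`` identifier, unique within a stack.
    """

    center_x: float
    center_y: float
    semi_axis_x: float
    semi_axis_y: float
    rotation_deg: float = 0.0
    label: tuple = ("L", 2)

    def __post_init__(self) -> None:
        if not (self.semi_axis_x > 0 and self.semi_axis_y > 0):
            raise ROIError(f"ROI {self.label}: semi-axes must be positive")

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean mask of pixels whose centers fall inside the ellipse."""
        ny, nx = shape
        y, x = np.mgrid[0:ny, 0:nx].astype(float)
        theta = np.deg2rad(self.rotation_deg)
        dx = x - self.center_x
        dy = y - self.center_y
        # rotate the point into the ellipse frame (inverse of a CCW rotation)
        xp = dx * np.cos(theta) + dy * np.sin(theta)
        yp = -dx * np.sin(theta) + dy * np.cos(theta)
        return (xp / self.semi_axis_x) ** 2 + (yp / self.semi_axis_y) ** 2 <= 1.0

    def to_dict(self) -> dict:
        return {
            "center_x": float(self.center_x),
            "center_y": float(self.center_y),
            "semi_axis_x": float(self.semi_axis_x),
            "semi_axis_y": float(self.semi_axis_y),
            "rotation_deg": float(self.rotation_deg),
            "hand": self.label[0],
            "finger": int(self.label[1]),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EllipseROI":
        return cls(
            center_x=d["center_x"],
            center_y=d["center_y"],
            semi_axis_x=d["semi_axis_x"],
            semi_axis_y=d["semi_axis_y"],
            rotation_deg=d.get("rotation_deg", 0.0),
            label=(d.get("hand", "L"), int(d.get("finger", 2))),
        )


@dataclass(frozen=True)
class TemperatureSeries:
    """One finger's temperature trace.

    Attributes
    ----------
    times : ndarray
        Minutes from the start of the recording, strictly increasing.
    temps : ndarray
        Temperature in °C, same length as ``times``.
    label : tuple or None
        ``(subject_id, hand, finger)``.
    baseline_window : (float, float) or None
        Time interval (min) of the pre-cooling baseline segment.
    cooling_end : float or None
        Time (min) at which the cold challenge ends; rewarming time is
        measured from here.
    """

    times: np.ndarray
    temps: np.ndarray
    label: tuple | None = None
    baseline_window: tuple[float, float] | None = None
    cooling_end: float | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        temps = np.asarray(self.temps, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "temps", temps)
        if times.ndim != 1 or temps.ndim != 1 or times.size != temps.size:
            raise SeriesError("times and temps must be 1-D arrays of equal length")
        if times.size == 0:
            raise SeriesError("empty series")
        if not np.all(np.diff(times) > 0):
            raise SeriesError("times must be strictly increasing")
        if not (np.all(np.isfinite(times)) and np.all(np.isfinite(temps))):
            raise SeriesError("times and temps must be finite")
        if (
            self.baseline_window is not None
            and self.cooling_end is not None
            and not self.baseline_window[1] <= self.cooling_end
        ):
            raise SeriesError("baseline window must precede the end of cooling")

    def __len__(self) -> int:
        return self.times.size

    # -- segment accessors -------------------------------------------------
    def baseline_temps(self) -> np.ndarray:
        if self.baseline_window is None:
            raise SeriesError("series has no baseline window")
        lo, hi = self.baseline_window
        m = (self.times >= lo) & (self.times < hi)
        if not m.any():
            raise SeriesError("baseline window contains no samples")
        return self.temps[m]

    def rewarming(self) -> tuple[np.ndarray, np.ndarray]:
        """Post-cooling segment as ``(tau, temps)``, tau in minutes from cooling end."""
        if self.cooling_end is None:
            raise SeriesError("series has no cooling_end; cannot locate rewarming phase")
        m = self.times >= self.cooling_end
        if not m.any():
            raise SeriesError("no post-cooling samples")
        return self.times[m] - self.cooling_end, self.temps[m]

    def with_temps(self, temps: np.ndarray) -> "TemperatureSeries":
        return dataclasses.replace(self, temps=np.asarray(temps, dtype=float))

    def to_frame(self) -> pd.DataFrame:
        sid, hand, finger = self.label if self.label is not None else ("", "", "")
        return pd.DataFrame(
            {
                "subject_id": sid,
                "hand": hand,
                "finger": finger,
                "time_min": self.times,
                "temp_C": self.temps,
            }
        )


# ---------------------------------------------------------------------------
# ROI extraction
# ---------------------------------------------------------------------------

def extract_series(
    stack: np.ndarray,
    timestamps: Sequence[float],
    rois: Sequence[EllipseROI],
    *,
    subject_id: str = "",
    baseline_window: tuple[float, float] | None = None,
    cooling_end: float | None = None,
) -> list[TemperatureSeries]:
    """Average each frame over every elliptical ROI, one series per ROI.

    ``stack`` is ``(n_frames, height, width)`` of temperatures in °C. The
    per-frame value is the arithmetic mean of the pixels whose centers fall
    inside the (rotated) ellipse.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ROIError("stack must be a 3-D array (frames, height, width)")
    timestamps = np.asarray(timestamps, dtype=float)
    if timestamps.size != stack.shape[0]:
        raise ROIError(
            f"{stack.shape[0]} frames but {timestamps.size} timestamps"
        )
    labels = [r.label for r in rois]
    if len(set(labels)) != len(labels):
        raise ROIError("ROI labels must be unique within a stack")
    out = []
    for roi in rois:
        mask = roi.mask(stack.shape[1:])
        if not mask.any():
            raise ROIError(f"ROI {roi.label} covers no pixel centers in the frame")
        values = stack[:, mask].mean(axis=1)
        out.append(
            TemperatureSeries(
                times=timestamps,
                temps=values,
                label=(subject_id, roi.label[0], roi.label[1]),
                baseline_window=baseline_window,
                cooling_end=cooling_end,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Artefact cleaning
# ---------------------------------------------------------------------------

def clean_artefacts(
    series: TemperatureSeries,
    *,
    window: int = 5,
    threshold: float = 3.0,
    max_fraction: float = 0.2,
) -> tuple[TemperatureSeries, int]:
    """Remove isolated spikes from a series by a rolling-median rule.

    A sample is an artefact when it deviates from the centered rolling median
    (window of ``window`` samples, shrunk at the edges) by more than
    ``threshold`` °C. Flagged samples are replaced by linear interpolation of
    the surrounding clean samples; flagged samples at the boundary take the
    nearest clean value. Returns the cleaned series and the artefact count.

    Raises
    ------
    ArtefactError
        If more than ``max_fraction`` of the samples are flagged.
    """
    temps = pd.Series(series.temps)
    med = temps.rolling(window, center=True, min_periods=1).median().to_numpy()
    flagged = np.abs(series.temps - med) > threshold
    count = int(flagged.sum())
    if count == 0:
        return series, 0
    if count > max_fraction * len(series):
        raise ArtefactError(
            f"{count}/{len(series)} samples flagged as artefacts "
            f"(> {max_fraction:.0%}); series unusable"
        )
    good = ~flagged
    cleaned = series.temps.copy()
    # np.interp holds the nearest clean value constant beyond the ends
    cleaned[flagged] = np.interp(
        series.times[flagged], series.times[good], series.temps[good]
    )
    return series.with_temps(cleaned), count


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_series_csv(series: Iterable[TemperatureSeries], path: str | Path) -> None:
    """Write series to a long-format CSV (subject_id, hand, finger, time_min, temp_C)."""
    frames = [s.to_frame() for s in series]
    pd.concat(frames, ignore_index=True)[SERIES_COLUMNS].to_csv(path, index=False)


def read_series_csv(
    path: str | Path,
    *,
    baseline_window: tuple[float, float] | None = None,
    cooling_end: float | None = None,
) -> list[TemperatureSeries]:
    """Read a long-format series CSV back into :class:`TemperatureSeries` objects.

    The CSV stores only the trace; the protocol timing (baseline window and
    cooling end) is supplied by the caller, typically from the run config.
    """
    df = pd.read_csv(path)
    missing = set(SERIES_COLUMNS) - set(df.columns)
    if missing:
        raise SeriesError(f"series CSV missing columns: {sorted(missing)}")
    out = []
    for (sid, hand, finger), grp in df.groupby(
        ["subject_id", "hand", "finger"], sort=False
    ):
        grp = grp.sort_values("time_min")
        out.append(
            TemperatureSeries(
                times=grp["time_min"].to_numpy(),
                temps=grp["temp_C"].to_numpy(),
                label=(sid, hand, int(finger)),
                baseline_window=baseline_window,
                cooling_end=cooling_end,
            )
        )
    return out


def write_frame_stack(
    tiff_path: str | Path,
    yaml_path: str | Path,
    stack: np.ndarray,
    timestamps: Sequence[float],
    rois: Sequence[EllipseROI],
) -> None:
    """Write a frame stack as multi-page float TIFF plus a YAML sidecar."""
    tifffile.imwrite(
        str(tiff_path),
        np.asarray(stack, dtype=np.float64),
        photometric="minisblack",
    )
    sidecar = {
        "timestamps_min": [float(t) for t in timestamps],
        "rois": [r.to_dict() for r in rois],
    }
    Path(yaml_path).write_text(yaml.safe_dump(sidecar, sort_keys=False))


def read_frame_stack(
    tiff_path: str | Path, yaml_path: str | Path
) -> tuple[np.ndarray, np.ndarray, list[EllipseROI]]:
    """Read a multi-page TIFF stack and its YAML sidecar."""
    stack = np.asarray(tifffile.imread(str(tiff_path)), dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    sidecar = yaml.safe_load(Path(yaml_path).read_text())
    timestamps = np.asarray(sidecar["timestamps_min"], dtype=float)
    rois = [EllipseROI.from_dict(d) for d in sidecar["rois"]]
    return stack, timestamps, rois


def read_csv_frames(paths: Sequence[str | Path]) -> np.ndarray:
    """Read plain numeric CSV matrices (one file per frame) into a stack."""
    frames = [np.loadtxt(p, delimiter=",", ndmin=2) for p in paths]
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise ROIError(f"frames have inconsistent shapes: {sorted(shapes)}")
    return np.stack(frames)
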