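"""Saccade extraction from spherical-treadmill rotation traces.

The sphere tracker reports per-frame rotation increments about three axes:
x (parallel to the screen; forward/backward walking), y (perpendicular;
sideways) and z (vertical; whole-body turns).  Saccades are isolated by
smoothing each axis, suppressing cross-axis coupling with
``sign(z) * max(0, |z| - |x| - |y|)``, and taking signed local extrema
above a threshold.  Peaks are then sign-coded toward the more-biological
stimulus of the trial's condition and labeled by period.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.signal

from .config import AnalysisParams, TimelineSpec
from .presentation import TrialSchedule, center_x_profile, stimulus_angle_at

logger = logging.getLogger(__name__)

#: Default 0-based column indices of the lab-frame delta-rotation vector in
#: FicTrac's headerless .dat output (columns 6-8 in its 1-based layout).
FICTRAC_COLUMN_MAP = {"rot_x": 5, "rot_y": 6, "rot_z": 7}

PLAIN_COLUMNS = ("rot_x", "rot_y", "rot_z")


@dataclass
class RotationTrace:
    """Per-frame x/y/z rotation increments (radians/frame) at ``fps``."""

    rot: np.ndarray  # (n, 3)
    fps: float = 120.0

    def __post_init__(self) -> None:
        self.rot = np.asarray(self.rot, dtype=float)
        if self.rot.ndim != 2 or self.rot.shape[1] != 3:
            raise ValueError("rot must have shape (n_frames, 3)")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if not np.all(np.isfinite(self.rot)):
            raise ValueError("rotation increments must be finite")

    @property
    def n_frames(self) -> int:
        return self.rot.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(self.n_frames),
                "rot_x": self.rot[:, 0],
                "rot_y": self.rot[:, 1],
                "rot_z": self.rot[:, 2],
            }
        )


def read_trace(
    source: str | Path | pd.DataFrame,
    column_map: dict[str, int] | None = None,
    fps: float = 120.0,
    z_sign: float = 1.0,
) -> RotationTrace:
    """Read a rotation trace from plain CSV or FicTrac-style delimited output.

    Plain CSV carries a header with ``rot_x, rot_y, rot_z`` columns;
    headerless comma-separated output is read through ``column_map``
    (defaulting to the published FicTrac column order).  ``z_sign`` lets the
    caller normalize camera handedness so that positive z is a leftward
    turn of the animal.
    """
    if isinstance(source, pd.DataFrame):
        df = source
        missing = set(PLAIN_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        rot = df[list(PLAIN_COLUMNS)].to_numpy(dtype=float)
    else:
        path = Path(source)
        text = path.read_text().strip()
        if not text:
            raise ValueError(f"{path}: empty trace file")
        first = text.splitlines()[0]
        if any(name in first for name in PLAIN_COLUMNS):
            df = pd.read_csv(path)
            missing = set(PLAIN_COLUMNS) - set(df.columns)
            if missing:
                raise ValueError(f"{path}: missing columns {sorted(missing)}")
            for name in PLAIN_COLUMNS:
                bad = pd.to_numeric(df[name], errors="coerce").isna() & df[name].notna()
                if bad.any():
                    line = int(bad.idxmax()) + 2  # header + 1-based
                    raise ValueError(f"{path}: non-numeric value in {name} at line {line}")
            rot = df[list(PLAIN_COLUMNS)].to_numpy(dtype=float)
        else:
            cmap = column_map or FICTRAC_COLUMN_MAP
            rows = []
            for lineno, line in enumerate(text.splitlines(), start=1):
                parts = [p.strip() for p in line.split(",")]
                try:
                    rows.append([float(parts[cmap[k]]) for k in PLAIN_COLUMNS])
                except (ValueError, IndexError) as exc:
                    raise ValueError(f"{path}: cannot parse line {lineno}: {exc}") from exc
            rot = np.asarray(rows, dtype=float)
    if np.isnan(rot).any():
        raise ValueError("trace contains missing values")
    rot = rot.copy()
    rot[:, 2] *= z_sign
    return RotationTrace(rot=rot, fps=fps)


def smooth(trace: RotationTrace, params: AnalysisParams | None = None) -> RotationTrace:
    """Low-pass each axis with the study's Butterworth filter.

    Zero-phase (forward-backward) by default so peak timing stays aligned
    with stimulus events; ``filter_mode='causal'`` applies a single forward
    pass instead.
    """
    params = params or AnalysisParams()
    b, a = scipy.signal.butter(params.butter_order, params.butter_critical)
    min_len = 3 * max(len(a), len(b))
    if trace.n_frames <= min_len:
        raise ValueError(f"trace too short to filter (need > {min_len} frames)")
    if params.filter_mode == "zero_phase":
        rot = scipy.signal.filtfilt(b, a, trace.rot, axis=0)
    else:
        rot = scipy.signal.lfilter(b, a, trace.rot, axis=0)
    return replace(trace, rot=rot)


@dataclass
class SaccadeSignal:
    """Signed scalar turn signal after cross-axis suppression (rad/frame)."""

    values: np.ndarray
    fps: float

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.shape[0]) / self.fps


def saccade_signal(trace: RotationTrace) -> SaccadeSignal:
    """Isolate pure turning: ``sign(z) * max(0, |z| - |x| - |y|)``.

    Z peaks with low concurrent x and y components survive; rotation
    coupled with forward or sideways walking is suppressed to zero, with
    the original sign of z reapplied to what remains.
    """
    x, y, z = trace.rot[:, 0], trace.rot[:, 1], trace.rot[:, 2]
    mag = np.maximum(0.0, np.abs(z) - np.abs(x) - np.abs(y))
    return SaccadeSignal(values=np.sign(z) * mag, fps=trace.fps)


def find_peaks(signal: SaccadeSignal | np.ndarray, threshold: float, fps: float | None = None) -> pd.DataFrame:
    """Signed local extrema strictly beyond ``+-threshold``.

    A peak is a strict local extremum (greater in magnitude than both
    neighbors); plateaus count once, at their first sample; no minimum
    inter-peak distance is imposed.  Returns a frame-indexed table with
    columns ``index, time_s, value`` sorted by time.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if isinstance(signal, SaccadeSignal):
        values, fps = signal.values, signal.fps
    else:
        values = np.asarray(signal, dtype=float)
        fps = fps if fps is not None else 1.0

    rows = []
    for sign in (1.0, -1.0):
        v = values * sign
        locs, props = scipy.signal.find_peaks(v, height=threshold, plateau_size=1)
        left = props["left_edges"]
        heights = v[left]
        for i, h in zip(left, heights):
            if h > threshold:  # strict
                rows.append((int(i), i / fps, float(values[i])))
    df = pd.DataFrame(rows, columns=["index", "time_s", "value"])
    return df.sort_values("time_s", ignore_index=True)


def extract_saccades(trace: RotationTrace, params: AnalysisParams | None = None) -> pd.DataFrame:
    """Full trace-to-peaks pipeline: smooth, suppress, threshold."""
    params = params or AnalysisParams()
    sig = saccade_signal(smooth(trace, params))
    thr = params.peak_threshold
    if params.threshold_units == "per_second":
        thr = thr / trace.fps
    return find_peaks(sig, thr)


def code_peaks(
    peaks: pd.DataFrame,
    schedule: TrialSchedule,
    spec: TimelineSpec | None = None,
    params: AnalysisParams | None = None,
    subject_id: str = "s0",
    trial_id: str = "t0",
    angle_profile: np.ndarray | None = None,
) -> pd.DataFrame:
    """Sign peaks toward the more-biological stimulus and label periods.

    During-stimulus peaks are coded by the presentation's side assignment
    (+1 toward the more-biological stimulus); the following pause keeps the
    same coding.  Heights are reported in degrees/second.  Peaks before the
    first presentation are dropped with a log entry.
    """
    spec = spec or TimelineSpec()
    params = params or AnalysisParams()
    to_deg_s = params.camera_fps * 180.0 / np.pi
    if angle_profile is None:
        angle_profile = center_x_profile(spec)

    rows = []
    dropped = 0
    for _, pk in peaks.iterrows():
        t, v = float(pk["time_s"]), float(pk["value"])
        period, k = schedule.period_at(t)
        if period in ("habituation", "after"):
            dropped += 1
            continue
        side_a, _ = schedule.sides_at(k)
        raw_sign = "L" if v > 0 else "R"
        coded = 1 if raw_sign == side_a else -1
        angle = (
            stimulus_angle_at(schedule, spec, t, profile=angle_profile)
            if period == "during"
            else float("nan")
        )
        rows.append(
            {
                "subject_id": subject_id,
                "trial_id": trial_id,
                "condition": schedule.condition,
                "time_s": t,
                "presentation_index": k,
                "period": period,
                "raw_sign": raw_sign,
                "coded_sign": coded,
                "height_deg_s": coded * abs(v) * to_deg_s,
                "abs_height_deg_s": abs(v) * to_deg_s,
                "stimulus_angle_deg": angle,
            }
        )
    if dropped:
        logger.info("dropped %d peaks outside the presentation span", dropped)
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id", "trial_id", "condition", "time_s", "presentation_index",
            "period", "raw_sign", "coded_sign", "height_deg_s", "abs_height_deg_s",
            "stimulus_angle_deg",
        ],
    )
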