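"""Digitized joint tracks of a walking spider and their decomposition.

The seed of every stimulus is a per-frame table of 2-D anatomical point
positions (eyes, pedicel, spinneret, and three joints per leg) with
visibility flags for points occluded by the body.  Tracks are rescaled so
the stimulus occupies a fixed on-screen box, then decomposed into a global
center trajectory plus center-relative per-dot displacement steps — the
representation from which the scrambled and random displays are built.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: Anatomical roles of the three per-leg points, proximal to distal.
LEG_POINT_ROLES = ("patella_femur", "metatarsus_tibia", "tarsus")

#: Body (non-leg) points digitized on the spider.
BODY_POINT_LABELS = ("eyes", "pedicel", "spinneret")


@dataclass
class JointTrackSet:
    """Labeled per-frame 2-D point positions with visibility flags.

    positions has shape ``(n_frames, n_points, 2)`` in stimulus-local
    pixels; entries where ``visible`` is False may be NaN.
    """

    labels: list[str]
    leg_ids: list[int | None]
    positions: np.ndarray
    visible: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.visible = np.asarray(self.visible, dtype=bool)
        if self.positions.ndim != 3 or self.positions.shape[2] != 2:
            raise ValueError("positions must have shape (n_frames, n_points, 2)")
        if self.positions.shape[:2] != self.visible.shape:
            raise ValueError("positions and visible shapes disagree")
        if len(self.labels) != self.positions.shape[1]:
            raise ValueError("labels length must equal n_points")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if not np.all(np.isfinite(self.positions[self.visible])):
            raise ValueError("positions must be finite wherever visible")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_points(self) -> int:
        return self.positions.shape[1]

    def filled_positions(self) -> np.ndarray:
        """Positions with invisible gaps filled by per-point linear interpolation.

        Gaps interior to the track are interpolated frame-linearly per
        coordinate; leading/trailing gaps hold the nearest visible value.
        A point never visible stays NaN.
        """
        filled = self.positions.copy()
        frames = np.arange(self.n_frames)
        for p in range(self.n_points):
            vis = self.visible[:, p]
            if vis.all():
                continue
            if not vis.any():
                continue
            for c in (0, 1):
                filled[~vis, p, c] = np.interp(
                    frames[~vis], frames[vis], self.positions[vis, p, c]
                )
        return filled

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (frame, label, leg_id, x_px, y_px, visible)."""
        rows = []
        for f in range(self.n_frames):
            for p, label in enumerate(self.labels):
                rows.append(
                    (
                        f,
                        label,
                        self.leg_ids[p] if self.leg_ids[p] is not None else pd.NA,
                        self.positions[f, p, 0],
                        self.positions[f, p, 1],
                        bool(self.visible[f, p]),
                    )
                )
        return pd.DataFrame(rows, columns=["frame", "label", "leg_id", "x_px", "y_px", "visible"])


def load_joint_tracks(table: pd.DataFrame | str | Path) -> JointTrackSet:
    """Build a :class:`JointTrackSet` from a long-format point table.

    The table needs columns ``frame, label, x_px, y_px`` (``leg_id`` and
    ``visible`` optional).  Rows with missing coordinates, explicit
    ``visible=False``, or absent (frame, label) combinations become
    invisible points.  Frames must be contiguous from 0 and (frame, label)
    pairs unique.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table)
    required = {"frame", "label", "x_px", "y_px"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")

    frames = np.sort(table["frame"].unique())
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    if frames[0] != 0 or not np.array_equal(frames, np.arange(len(frames))):
        raise ValueError(f"frame indices must be contiguous from 0, got {frames.tolist()}")
    if table.duplicated(subset=["frame", "label"]).any():
        dup = table[table.duplicated(subset=["frame", "label"], keep=False)]
        raise ValueError(f"duplicate (frame, label) rows: {dup[['frame', 'label']].values.tolist()[:4]}")

    labels = list(dict.fromkeys(table["label"]))  # first-appearance order
    leg_ids: list[int | None] = []
    for label in labels:
        sub = table.loc[table["label"] == label]
        if "leg_id" in sub.columns and sub["leg_id"].notna().any():
            leg_ids.append(int(sub["leg_id"].dropna().iloc[0]))
        else:
            leg_ids.append(None)

    n_frames, n_points = len(frames), len(labels)
    positions = np.full((n_frames, n_points, 2), np.nan)
    visible = np.zeros((n_frames, n_points), dtype=bool)
    col = {label: i for i, label in enumerate(labels)}
    for _, row in table.iterrows():
        f, p = int(row["frame"]), col[row["label"]]
        x, y = row["x_px"], row["y_px"]
        vis = bool(row["visible"]) if "visible" in table.columns and pd.notna(row["visible"]) else True
        if pd.isna(x) or pd.isna(y):
            vis = False
        if vis:
            positions[f, p] = (float(x), float(y))
        visible[f, p] = vis
    return JointTrackSet(labels=labels, leg_ids=leg_ids, positions=positions, visible=visible)


def bounding_box(tracks: JointTrackSet, frames: tuple[int, ...] | None = None) -> tuple[float, float, float, float]:
    """(xmin, xmax, ymin, ymax) over visible points of the given frames (default all)."""
    if frames is None:
        mask = tracks.visible
        pos = tracks.positions
    else:
        mask = tracks.visible[list(frames)]
        pos = tracks.positions[list(frames)]
    pts = pos[mask]
    if pts.size == 0:
        raise ValueError("no visible points in requested frames")
    return pts[:, 0].min(), pts[:, 0].max(), pts[:, 1].min(), pts[:, 1].max()


def rescale_to_box(
    tracks: JointTrackSet,
    w_px: float = 170.0,
    h_px: float = 60.0,
    reference_frames: tuple[int, ...] = (0,),
) -> JointTrackSet:
    """Rescale so the reference frames' bounding box spans ``w_px x h_px``.

    One anisotropic scale per axis, constant over frames, so that relative
    geometry per axis is preserved and leg extension in non-reference frames
    may exceed the box slightly.  The box is also re-centered on the
    reference bounding-box center.
    """
    xmin, xmax, ymin, ymax = bounding_box(tracks, reference_frames)
    if xmax - xmin <= 0 or ymax - ymin <= 0:
        raise ValueError("degenerate (zero-extent) bounding box")
    sx = w_px / (xmax - xmin)
    sy = h_px / (ymax - ymin)
    cx, cy = (xmin + xmax) / 2, (ymin + ymax) / 2
    positions = tracks.positions.copy()
    positions[..., 0] = (positions[..., 0] - cx) * sx
    positions[..., 1] = (positions[..., 1] - cy) * sy
    return replace(tracks, positions=positions)


@dataclass
class DisplacementField:
    """Global center trajectory plus center-relative per-dot motion.

    ``center_path`` is the per-frame bounding-box center of the visible
    dots; ``start_local`` the frame-0 center-relative positions (gaps
    interpolated); ``local_steps[t]`` the center-relative displacement from
    frame ``t`` to ``t+1``.  Integrating the steps from ``start_local`` and
    re-adding ``center_path`` reconstructs the source track.
    """

    center_path: np.ndarray  # (n_frames, 2)
    start_local: np.ndarray  # (n_points, 2)
    local_steps: np.ndarray  # (n_frames - 1, n_points, 2)

    @property
    def n_frames(self) -> int:
        return self.center_path.shape[0]

    def integrate(self, start_local: np.ndarray | None = None) -> np.ndarray:
        """Positions from integrating local steps (optionally from other starts)."""
        start = self.start_local if start_local is None else np.asarray(start_local, float)
        local = np.concatenate(
            [start[None], start[None] + np.cumsum(self.local_steps, axis=0)], axis=0
        )
        return local + self.center_path[:, None, :]


def center_path_of(tracks: JointTrackSet) -> np.ndarray:
    """Per-frame bounding-box center of the visible dots."""
    centers = np.empty((tracks.n_frames, 2))
    for f in range(tracks.n_frames):
        vis = tracks.visible[f]
        if not vis.any():
            raise ValueError(f"frame {f} has no visible points")
        pts = tracks.positions[f, vis]
        centers[f, 0] = (pts[:, 0].min() + pts[:, 0].max()) / 2
        centers[f, 1] = (pts[:, 1].min() + pts[:, 1].max()) / 2
    return centers


def decompose(tracks: JointTrackSet, missing: str = "interpolate") -> DisplacementField:
    """Split a track into center trajectory and center-relative dot steps.

    ``missing='interpolate'`` (default) linearly fills invisible gaps so
    every dot's local path is defined on all frames; ``'drop-dot'`` drops
    points that are ever invisible.
    """
    if missing not in ("interpolate", "drop-dot"):
        raise ValueError("missing must be 'interpolate' or 'drop-dot'")
    center = center_path_of(tracks)
    if missing == "drop-dot":
        keep = tracks.visible.all(axis=0)
        filled = tracks.positions[:, keep]
    else:
        filled = tracks.filled_positions()
        keep = ~np.isnan(filled).any(axis=(0, 2))  # drop never-visible points
        filled = filled[:, keep]
    local = filled - center[:, None, :]
    return DisplacementField(
        center_path=center,
        start_local=local[0].copy(),
        local_steps=np.diff(local, axis=0),
    )
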