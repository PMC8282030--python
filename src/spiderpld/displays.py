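"""Point-light display constructors: biological, scrambled, random.

All three displays share the same global center trajectory and the same
per-transition motion statistics as the source walk; they differ in what
configural information survives:

* biological — a dot at each digitized anatomical location;
* scrambled — first-frame dot positions randomized inside the stimulus box,
  every dot then replaying its original center-relative path (semirigid
  motion without configuration);
* random — original first frame, per-transition step magnitudes preserved
  but directions redrawn uniformly, dots confined to the stimulus box by
  rejection sampling (neither configuration nor semirigidity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracks import JointTrackSet, decompose

DOT_KINDS = ("biological", "scrambled", "random")


@dataclass
class DotDisplay:
    """Per-frame dot positions of one point-light stimulus (local pixels)."""

    kind: str
    labels: list[str]
    positions: np.ndarray  # (n_frames, n_dots, 2)
    visible: np.ndarray  # (n_frames, n_dots) bool
    center_path: np.ndarray  # (n_frames, 2)
    variant_index: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in DOT_KINDS:
            raise ValueError(f"kind must be one of {DOT_KINDS}")
        self.positions = np.asarray(self.positions, dtype=float)
        self.visible = np.asarray(self.visible, dtype=bool)

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_dots(self) -> int:
        return self.positions.shape[1]

    def mirrored(self) -> "DotDisplay":
        """Reflection about the vertical axis (x -> -x)."""
        pos = self.positions.copy()
        pos[..., 0] *= -1
        cp = self.center_path.copy()
        cp[:, 0] *= -1
        return DotDisplay(
            kind=self.kind,
            labels=list(self.labels),
            positions=pos,
            visible=self.visible.copy(),
            center_path=cp,
            variant_index=self.variant_index,
            seed=self.seed,
        )

    def to_frame(self) -> pd.DataFrame:
        n_f, n_d = self.positions.shape[:2]
        f_idx = np.repeat(np.arange(n_f), n_d)
        d_idx = np.tile(np.arange(n_d), n_f)
        return pd.DataFrame(
            {
                "display_frame": f_idx,
                "dot_id": d_idx,
                "label": [self.labels[d] for d in d_idx],
                "x_px": self.positions.reshape(-1, 2)[:, 0],
                "y_px": self.positions.reshape(-1, 2)[:, 1],
                "visible": self.visible.reshape(-1),
            }
        )


def make_biological(tracks: JointTrackSet) -> DotDisplay:
    """One dot per anatomical point per frame, positions as tracked."""
    field = decompose(tracks)
    return DotDisplay(
        kind="biological",
        labels=list(tracks.labels),
        positions=tracks.positions.copy(),
        visible=tracks.visible.copy(),
        center_path=field.center_path,
    )


def make_scrambled(
    tracks: JointTrackSet,
    seed: int | None = None,
    w_px: float = 170.0,
    h_px: float = 60.0,
    variant_index: int | None = None,
    starts: np.ndarray | None = None,
) -> DotDisplay:
    """Randomize first-frame dot positions, replay the original dot paths.

    Starting positions are drawn uniformly inside the ``w_px x h_px`` box
    (center-relative); each dot then repeats its biological center-relative
    displacement sequence, and the global center trajectory is re-added, so
    per-dot paths and overall translation match the biological display
    exactly.  ``starts`` overrides the random draw (used for testing).
    """
    field = decompose(tracks)
    n_points = field.start_local.shape[0]
    if starts is None:
        rng = np.random.default_rng(seed)
        starts = np.column_stack(
            [
                rng.uniform(-w_px / 2, w_px / 2, size=n_points),
                rng.uniform(-h_px / 2, h_px / 2, size=n_points),
            ]
        )
    positions = field.integrate(start_local=starts)
    keep = _kept_point_mask(tracks)
    return DotDisplay(
        kind="scrambled",
        labels=[l for l, k in zip(tracks.labels, keep) if k],
        positions=positions,
        visible=tracks.visible[:, keep].copy(),
        center_path=field.center_path,
        variant_index=variant_index,
        seed=seed,
    )


def make_random(
    tracks: JointTrackSet,
    seed: int | None = None,
    w_px: float = 170.0,
    h_px: float = 60.0,
    variant_index: int | None = None,
    max_redraws: int = 10_000,
) -> DotDisplay:
    """Keep per-step magnitudes of the biological display, randomize directions.

    Starts from the full first frame of the biological display; every
    transition preserves that dot's biological step length with direction
    drawn uniformly on [0, 2pi).  A draw whose landing point leaves the
    center-relative ``w_px x h_px`` rectangle is rejected and redrawn, up to
    ``max_redraws`` times per (dot, transition) before raising.
    """
    rng = np.random.default_rng(seed)
    field = decompose(tracks)
    keep = _kept_point_mask(tracks)
    labels = [l for l, k in zip(tracks.labels, keep) if k]
    magnitudes = np.linalg.norm(field.local_steps, axis=2)  # (n_frames-1, n_points)
    n_trans, n_points = magnitudes.shape
    half_w, half_h = w_px / 2, h_px / 2
    eps = 1e-9

    local = np.empty((n_trans + 1, n_points, 2))
    local[0] = field.start_local
    for t in range(n_trans):
        prev = local[t]
        m = magnitudes[t]
        pending = np.ones(n_points, dtype=bool)
        cand = np.empty_like(prev)
        draws = 0
        while pending.any():
            if draws >= max_redraws:
                bad = int(np.flatnonzero(pending)[0])
                raise RuntimeError(
                    f"rejection budget ({max_redraws}) exhausted for dot "
                    f"{labels[bad]!r} at transition {t}"
                )
            theta = rng.uniform(0.0, 2 * np.pi, size=int(pending.sum()))
            step = np.column_stack([np.cos(theta), np.sin(theta)]) * m[pending, None]
            trial = prev[pending] + step
            cand[pending] = trial
            inside = (np.abs(cand[:, 0]) <= half_w + eps) & (np.abs(cand[:, 1]) <= half_h + eps)
            pending = pending & ~inside
            draws += 1
        local[t + 1] = cand
    positions = local + field.center_path[:, None, :]
    return DotDisplay(
        kind="random",
        labels=labels,
        positions=positions,
        visible=tracks.visible[:, keep].copy(),
        center_path=field.center_path,
        variant_index=variant_index,
        seed=seed,
    )


def _kept_point_mask(tracks: JointTrackSet) -> np.ndarray:
    """Points retained by decompose (ever-visible ones)."""
    filled = tracks.filled_positions()
    return ~np.isnan(filled).any(axis=(0, 2))


def local_steps_of(display: DotDisplay) -> np.ndarray:
    """Center-relative per-transition displacements of a dot display."""
    local = display.positions - display.center_path[:, None, :]
    return np.diff(local, axis=0)
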