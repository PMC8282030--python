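"""Screen-space presentation assembly and trial scheduling.

A presentation replays the stimulus in three movement blocks separated by
static pauses while translating it from off-screen toward the screen
center, where it disappears progressively behind a central occluder.  A
trial is a habituation period followed by ten presentation/pause cycles
with a semi-random left/right entry pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import (
    CONDITION_PAIRS,
    N_VARIANTS,
    SIDE_PATTERNS,
    ScheduleParams,
    TimelineSpec,
)
from .displays import DotDisplay
from .shapes import Ellipse, FrameShapes, ShapeDisplay


def resample_indices(n_src: int, n_out: int) -> np.ndarray:
    """Nearest-frame resampling of ``n_src`` source frames onto ``n_out`` slots."""
    if n_src < 2 or n_out < 2:
        raise ValueError("need at least 2 frames on both sides")
    return np.round(np.linspace(0, n_src - 1, n_out)).astype(int)


def frame_plan(spec: TimelineSpec, n_src: int) -> tuple[np.ndarray, np.ndarray]:
    """Per display frame: source-frame index and a moving/static flag.

    Movement blocks replay the resampled source frames; pauses hold the
    last frame of the preceding block.
    """
    block = resample_indices(n_src, spec.move_block_frames)
    src: list[int] = []
    moving: list[bool] = []
    for b in range(spec.n_move_blocks):
        src.extend(block.tolist())
        moving.extend([True] * spec.move_block_frames)
        if b < spec.n_move_blocks - 1:
            src.extend([int(block[-1])] * spec.pause_frames)
            moving.extend([False] * spec.pause_frames)
    return np.asarray(src), np.asarray(moving)


def _travel_cumulative(spec: TimelineSpec, walk_x: np.ndarray | None, n_src: int) -> np.ndarray:
    """Cumulative along-walk travel per display frame (arbitrary units).

    With ``walk_x`` (the source center-path x) the profile follows the
    digitized walking speed; without it, travel is uniform across moving
    frames.  Pauses contribute zero.
    """
    src, moving = frame_plan(spec, n_src)
    inc = np.zeros(spec.total_frames)
    if walk_x is None:
        inc[moving] = 1.0
        inc[0] = 0.0
    else:
        direction = np.sign(walk_x[-1] - walk_x[0]) or 1.0
        for f in range(1, spec.total_frames):
            if moving[f] and moving[f - 1]:
                inc[f] = (walk_x[src[f]] - walk_x[src[f - 1]]) * direction
        inc = np.maximum(inc, 0.0)  # guard against sway reversals
    return np.cumsum(inc)


def center_x_profile(spec: TimelineSpec, walk_x: np.ndarray | None = None, n_src: int | None = None) -> np.ndarray:
    """Unsigned screen-center distance of the stimulus per display frame (px).

    Scaled so the stimulus' leading box edge reaches the screen edge exactly
    at ``entry_offscreen_frames`` and the center reaches 0 on the last frame.
    """
    n_src = n_src if n_src is not None else spec.move_block_frames
    cum = _travel_cumulative(spec, walk_x, n_src)
    total = cum[-1]
    e = spec.entry_offscreen_frames
    remaining = total - cum[e]
    if remaining <= 0:
        raise ValueError("no travel left after the off-screen entry frames")
    edge = spec.screen_width_px / 2 + spec.stim_width_px / 2
    s = edge / remaining
    return s * (total - cum)


def px_to_deg(x_px: float | np.ndarray, spec: TimelineSpec) -> float | np.ndarray:
    """Visual angle (degrees) of a horizontal screen offset from center."""
    return np.degrees(np.arctan(np.asarray(x_px) * spec.pixel_mm / spec.view_distance_mm))


@dataclass
class ScreenPresentation:
    """One composed presentation in screen coordinates (origin: screen center)."""

    side: str
    spec: TimelineSpec
    center_x: np.ndarray  # signed stimulus-center x per display frame
    onscreen: np.ndarray  # bool: any part of the ideal stimulus box on screen
    positions: np.ndarray | None = None  # dots: (total_frames, n_dots, 2)
    dot_visible: np.ndarray | None = None
    shape_frames: list[FrameShapes] | None = None

    @property
    def n_frames(self) -> int:
        return self.center_x.shape[0]

    def mirrored(self) -> "ScreenPresentation":
        other = "L" if self.side == "R" else "R"
        pos = None
        if self.positions is not None:
            pos = self.positions.copy()
            pos[..., 0] *= -1
        shapes = None
        if self.shape_frames is not None:
            shapes = [_mirror_frame(fr) for fr in self.shape_frames]
        return ScreenPresentation(
            side=other,
            spec=self.spec,
            center_x=-self.center_x,
            onscreen=self.onscreen.copy(),
            positions=pos,
            dot_visible=None if self.dot_visible is None else self.dot_visible.copy(),
            shape_frames=shapes,
        )


def _mirror_frame(fr: FrameShapes) -> FrameShapes:
    flip = np.array([-1.0, 1.0])
    return FrameShapes(
        segments=[(p0 * flip, p1 * flip, w) for p0, p1, w in fr.segments],
        ellipses=[
            Ellipse(center=e.center * flip, a=e.a, b=e.b, angle=np.pi - e.angle)
            for e in fr.ellipses
        ],
    )


def compose_presentation(
    display: DotDisplay | ShapeDisplay, spec: TimelineSpec, side: str,
    use_walk_speed: bool = False,
) -> ScreenPresentation:
    """Assemble the timed, side-assigned screen frames of one stimulus.

    The stimulus enters fully off-screen on ``side``, translates toward the
    center through the movement blocks (static during pauses, each block
    re-anchored in x over the current position), and ends centered behind
    the occluder.  A right-side presentation is the mirror image of the
    left-side one.

    Global translation is constant-speed within movement blocks (the walk's
    net translation spread evenly), which pins the screen-edge crossing to
    exactly ``entry_offscreen_frames``; pass ``use_walk_speed=True`` to
    follow the digitized frame-by-frame walking speed instead.
    """
    if side not in ("L", "R"):
        raise ValueError("side must be 'L' or 'R'")
    n_src = display.n_frames
    src, _ = frame_plan(spec, n_src)
    walk_x = display.center_path[:, 0]
    x_abs = center_x_profile(spec, walk_x=walk_x if use_walk_speed else None, n_src=n_src)

    # natural side: the side whose inward motion matches the walk direction
    direction = np.sign(walk_x[-1] - walk_x[0]) or 1.0
    natural = "R" if direction < 0 else "L"
    sign = 1.0 if natural == "R" else -1.0
    center_x = sign * x_abs

    half_w = spec.stim_width_px / 2
    onscreen = (x_abs - half_w) <= spec.screen_width_px / 2 + 1e-9

    if isinstance(display, DotDisplay):
        local = display.positions - display.center_path[:, None, :] * np.array([1.0, 0.0])
        pos = local[src].copy()
        pos[..., 0] += center_x[:, None]
        vis_src = display.visible[src]
        on_x = np.abs(pos[..., 0]) <= spec.screen_width_px / 2 + 1e-9
        on_y = np.abs(pos[..., 1]) <= spec.screen_height_px / 2 + 1e-9
        occluded = np.abs(pos[..., 0]) < spec.occluder_halfwidth_px
        dot_visible = vis_src & on_x & on_y & ~occluded
        out = ScreenPresentation(
            side=natural, spec=spec, center_x=center_x, onscreen=onscreen,
            positions=pos, dot_visible=dot_visible,
        )
    else:
        frames = []
        for f in range(spec.total_frames):
            dx = center_x[f] - display.center_path[src[f], 0]
            frames.append(_translate_frame(display.frames[src[f]], dx))
        out = ScreenPresentation(
            side=natural, spec=spec, center_x=center_x, onscreen=onscreen, shape_frames=frames
        )
    if side != natural:
        out = out.mirrored()
    return out


def _translate_frame(fr: FrameShapes, dx: float) -> FrameShapes:
    off = np.array([dx, 0.0])
    return FrameShapes(
        segments=[(p0 + off, p1 + off, w) for p0, p1, w in fr.segments],
        ellipses=[Ellipse(center=e.center + off, a=e.a, b=e.b, angle=e.angle) for e in fr.ellipses],
    )


# ---------------------------------------------------------------------------
# trial scheduling


class VariantPoolError(RuntimeError):
    """A subject has exhausted the pre-generated randomizations of a kind."""


class VariantAssigner:
    """Draw stimulus-variant indices without replacement per subject and kind.

    Guarantees the cross-trial rule that one subject never sees the same
    randomization of a stochastic stimulus in two different trials.
    """

    def __init__(self, seed: int | None = None, n_variants: int = N_VARIANTS) -> None:
        self.rng = np.random.default_rng(seed)
        self.n_variants = n_variants
        self._remaining: dict[tuple[str, str], list[int]] = {}

    def draw(self, subject_id: str, kind: str) -> int:
        key = (subject_id, kind)
        pool = self._remaining.setdefault(key, list(range(self.n_variants)))
        if not pool:
            raise VariantPoolError(
                f"subject {subject_id!r} exhausted the {self.n_variants} variants of {kind!r}"
            )
        i = int(self.rng.integers(len(pool)))
        return pool.pop(i)


@dataclass(frozen=True)
class TrialSchedule:
    """The timed plan of one trial."""

    condition: str
    side_pattern: str  # entry side of the more-biological stimulus, per presentation
    habituation_s: float = 300.0
    n_presentations: int = 10
    inter_stimulus_s: float = 30.0
    presentation_s: float = 9.0
    variant_indices: dict = field(default_factory=dict)  # kind -> tuple per presentation
    pattern_id: int | None = None

    def __post_init__(self) -> None:
        if self.condition not in CONDITION_PAIRS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if len(self.side_pattern) != self.n_presentations:
            raise ValueError("side_pattern length must equal n_presentations")
        if set(self.side_pattern) - {"L", "R"}:
            raise ValueError("side_pattern may contain only 'L' and 'R'")

    @property
    def cycle_s(self) -> float:
        return self.presentation_s + self.inter_stimulus_s

    @property
    def start_times(self) -> tuple[float, ...]:
        return tuple(self.habituation_s + k * self.cycle_s for k in range(self.n_presentations))

    @property
    def total_duration_s(self) -> float:
        return self.habituation_s + self.n_presentations * self.cycle_s

    def period_at(self, t_s: float) -> tuple[str, int]:
        """('habituation'|'during'|'between'|'after', presentation index or -1)."""
        if t_s < 0:
            raise ValueError("negative time")
        if t_s < self.habituation_s:
            return "habituation", -1
        q = t_s - self.habituation_s
        k = int(q // self.cycle_s)
        if k >= self.n_presentations:
            return "after", -1
        return ("during", k) if q - k * self.cycle_s < self.presentation_s else ("between", k)

    def sides_at(self, k: int) -> tuple[str, str | None]:
        """(side of the more-biological stimulus, side of the other) at presentation k."""
        a = self.side_pattern[k]
        pair = CONDITION_PAIRS[self.condition]
        b = None if pair[1] is None else ("R" if a == "L" else "L")
        return a, b

    def swapped_sides(self) -> "TrialSchedule":
        flipped = "".join("R" if c == "L" else "L" for c in self.side_pattern)
        return TrialSchedule(
            condition=self.condition,
            side_pattern=flipped,
            habituation_s=self.habituation_s,
            n_presentations=self.n_presentations,
            inter_stimulus_s=self.inter_stimulus_s,
            presentation_s=self.presentation_s,
            variant_indices=dict(self.variant_indices),
            pattern_id=self.pattern_id,
        )


def schedule_trial(
    condition: str,
    spec: TimelineSpec | None = None,
    schedule_params: ScheduleParams | None = None,
    pattern_id: int | None = None,
    variants: dict[str, int] | None = None,
    seed: int | None = None,
    subject_id: str = "s0",
    assigner: VariantAssigner | None = None,
) -> TrialSchedule:
    """Build a :class:`TrialSchedule` for one trial of ``condition``.

    ``pattern_id`` selects one of the two printed semi-random side
    sequences (drawn at random when None).  Variant indices for stochastic
    stimulus kinds come from ``variants``, the ``assigner`` (enforcing
    cross-trial non-repetition), or a seeded draw, and are constant within
    the trial (one randomization per trial).
    """
    spec = spec or TimelineSpec()
    sp = schedule_params or ScheduleParams()
    rng = np.random.default_rng(seed)
    if pattern_id is None:
        pattern_id = int(rng.integers(2))
    if pattern_id not in (0, 1):
        raise ValueError("pattern_id must be 0 or 1")
    base = SIDE_PATTERNS[pattern_id]
    reps = -(-sp.n_presentations // len(base)) if sp.n_presentations else 1
    pattern = (base * reps)[: sp.n_presentations]

    kinds = [k for k in CONDITION_PAIRS[condition] if k in ("scrambled", "random")]
    variant_indices: dict[str, tuple[int, ...]] = {}
    for kind in kinds:
        if variants and kind in variants:
            v = int(variants[kind])
        elif assigner is not None:
            v = assigner.draw(subject_id, kind)
        else:
            v = int(rng.integers(N_VARIANTS))
        if not 0 <= v < N_VARIANTS:
            raise ValueError(f"variant index {v} out of range for {kind!r}")
        variant_indices[kind] = tuple([v] * sp.n_presentations)

    return TrialSchedule(
        condition=condition,
        side_pattern=pattern,
        habituation_s=sp.habituation_s,
        n_presentations=sp.n_presentations,
        inter_stimulus_s=sp.inter_stimulus_s,
        presentation_s=spec.presentation_seconds,
        variant_indices=variant_indices,
        pattern_id=pattern_id,
    )


def stimulus_angle_at(
    schedule: TrialSchedule,
    spec: TimelineSpec,
    t_s: float,
    side: str | None = None,
    profile: np.ndarray | None = None,
) -> float:
    """Angular position (degrees from screen center) of a stimulus at time t.

    Unsigned by default; with ``side`` given, signed positive on the left
    (matching the positive-is-leftward rotation convention).  ``profile``
    overrides the default uniform-travel center trajectory (pass the
    ``center_x`` magnitude profile of a composed presentation to use the
    digitized walking speed).  NaN outside presentation windows.
    """
    period, k = schedule.period_at(t_s)
    if period != "during":
        return float("nan")
    if profile is None:
        profile = center_x_profile(spec)
    rel = t_s - schedule.start_times[k]
    f = min(int(rel * spec.display_fps), spec.total_frames - 1)
    angle = float(px_to_deg(abs(profile[f]), spec))
    if side is None:
        return angle
    if side not in ("L", "R"):
        raise ValueError("side must be 'L', 'R' or None")
    return angle if side == "L" else -angle
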