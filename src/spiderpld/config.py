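"""Study configuration: timeline, analysis and virtual-agent parameters.

All defaults reproduce the apparatus and presentation geometry of the
treadmill experiment this package models: a 1080p screen with 0.248 mm
pixels viewed from 140 mm, stimuli rescaled to a 170 x 60 px box and shown
at 30 fps, sphere rotations recorded at 120 fps.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: The two semi-random left/right entry sequences used across trials.  The
#: sequence gives, per presentation, the entry side of the "more biological"
#: member of the stimulus pair; the other stimulus enters opposite.
SIDE_PATTERNS = ("LRLRLLRRLR", "RLRLRRLLRL")

#: Experimental conditions mapped to (more-biological, less-biological)
#: stimulus kinds.  ``ellipse_vs_nothing`` is the single-stimulus baseline.
CONDITION_PAIRS = {
    "bio_vs_random": ("biological", "random"),
    "scrambled_vs_random": ("scrambled", "random"),
    "bio_vs_scrambled": ("biological", "scrambled"),
    "silhouette_vs_ellipse": ("silhouette", "ellipse"),
    "ellipse_vs_nothing": ("ellipse", None),
}

CONDITIONS = tuple(CONDITION_PAIRS)

#: The four conditions of the main experiment (each subject sees each once).
MAIN_CONDITIONS = tuple(c for c in CONDITIONS if c != "ellipse_vs_nothing")

#: Number of pre-generated randomizations per stochastic stimulus kind.
N_VARIANTS = 4


class ConfigError(ValueError):
    """A configuration value violates an invariant."""


@dataclass(frozen=True)
class TimelineSpec:
    """Geometry and timing of one stimulus presentation.

    A presentation is ``n_move_blocks`` movement blocks of
    ``move_block_frames`` display frames separated by static pauses of
    ``pause_frames``.  The first ``entry_offscreen_frames`` frames the
    stimulus is still fully outside the screen.
    """

    display_fps: int = 30
    n_move_blocks: int = 3
    move_block_frames: int = 60
    pause_frames: int = 45
    entry_offscreen_frames: int = 30
    total_frames: int = 270
    screen_width_px: int = 1920
    screen_height_px: int = 1080
    pixel_mm: float = 0.248
    view_distance_mm: float = 140.0
    occluder_halfwidth_px: float = 100.0
    stim_width_px: float = 170.0
    stim_height_px: float = 60.0

    def __post_init__(self) -> None:
        expected = (
            self.n_move_blocks * self.move_block_frames
            + (self.n_move_blocks - 1) * self.pause_frames
        )
        if expected != self.total_frames:
            raise ConfigError(
                f"total_frames={self.total_frames} inconsistent with "
                f"{self.n_move_blocks} blocks of {self.move_block_frames} frames "
                f"and {self.n_move_blocks - 1} pauses of {self.pause_frames} "
                f"(expected {expected})"
            )
        if self.display_fps <= 0:
            raise ConfigError("display_fps must be positive")
        if self.entry_offscreen_frames < 0 or self.entry_offscreen_frames >= self.total_frames:
            raise ConfigError("entry_offscreen_frames out of range")

    @property
    def visible_frames(self) -> int:
        return self.total_frames - self.entry_offscreen_frames

    @property
    def visible_seconds(self) -> float:
        return self.visible_frames / self.display_fps

    @property
    def presentation_seconds(self) -> float:
        return self.total_frames / self.display_fps


@dataclass(frozen=True)
class ScheduleParams:
    """Timing of a full trial: habituation then presentation/pause cycles."""

    habituation_s: float = 300.0
    n_presentations: int = 10
    inter_stimulus_s: float = 30.0

    def __post_init__(self) -> None:
        if self.habituation_s < 0 or self.inter_stimulus_s < 0:
            raise ConfigError("durations must be nonnegative")
        if self.n_presentations < 0:
            raise ConfigError("n_presentations must be nonnegative")


@dataclass(frozen=True)
class AnalysisParams:
    """Saccade-extraction parameters for the rotation traces.

    ``peak_threshold`` applies to the cross-axis-suppressed signal in the
    trace's native radians-per-frame units by default
    (``threshold_units='per_frame'``); set ``'per_second'`` to interpret it
    against frame values multiplied by ``camera_fps``.
    """

    camera_fps: float = 120.0
    butter_order: int = 3
    butter_critical: float = 0.5
    peak_threshold: float = 0.001
    threshold_units: str = "per_frame"
    filter_mode: str = "zero_phase"

    def __post_init__(self) -> None:
        if not 0 < self.butter_critical < 1:
            raise ConfigError("butter_critical must lie in (0, 1) (normalized)")
        if self.peak_threshold <= 0:
            raise ConfigError("peak_threshold must be positive")
        if self.camera_fps <= 0:
            raise ConfigError("camera_fps must be positive")
        if self.threshold_units not in ("per_frame", "per_second"):
            raise ConfigError("threshold_units must be 'per_frame' or 'per_second'")
        if self.filter_mode not in ("zero_phase", "causal"):
            raise ConfigError("filter_mode must be 'zero_phase' or 'causal'")


@dataclass(frozen=True)
class AgentParams:
    """Virtual-spider policy parameters.

    The agent walks forward continuously and fires saccades from an
    angle-dependent hazard while stimuli are on screen: the hazard steps up
    when the stimulus sits in the wide-angle secondary-eye band
    (``|angle| >= band_deg``).  Each saccade targets the more-biological
    stimulus with probability ``preference`` and rotates by the target's
    current angular position over ``saccade_duration_s`` with a half-cosine
    angular-velocity profile.  Spontaneous saccades (random direction and
    amplitude) fire throughout the trial at ``spont_hazard_per_s``.
    """

    preference: float = 0.5
    hazard_low_per_s: float = 0.1
    hazard_high_per_s: float = 1.2
    band_deg: float = 50.0
    contrast_multiplier: float = 1.5
    saccade_duration_s: float = 0.15
    forward_speed: float = 0.005  # rad/frame on x (continuous walking)
    wander_sd: float = 3e-4  # rad/frame on y and z
    noise_sd: float = 2e-4  # sensor noise, rad/frame, each axis
    spont_hazard_per_s: float = 0.05
    spont_amplitude_deg: tuple[float, float] = (10.0, 60.0)
    camera_fps: float = 120.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.preference <= 1.0:
            raise ConfigError("preference must lie in [0, 1]")
        if min(self.wander_sd, self.noise_sd) < 0:
            raise ConfigError("noise standard deviations must be nonnegative")
        if self.saccade_duration_s <= 0:
            raise ConfigError("saccade_duration_s must be positive")
        if min(self.hazard_low_per_s, self.hazard_high_per_s, self.spont_hazard_per_s) < 0:
            raise ConfigError("hazards must be nonnegative")


@dataclass(frozen=True)
class StudyConfig:
    """Bundle of all tunable constants, loadable from a flat YAML file."""

    timeline: TimelineSpec = field(default_factory=TimelineSpec)
    schedule: ScheduleParams = field(default_factory=ScheduleParams)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    agent: AgentParams = field(default_factory=AgentParams)
    sphere_diameter_mm: float = 38.0
    seed: int = 0

    def flat(self) -> dict:
        out: dict = {"sphere_diameter_mm": self.sphere_diameter_mm, "seed": self.seed}
        for group in (self.timeline, self.schedule, self.analysis, self.agent):
            for f in dataclasses.fields(group):
                out[f.name] = getattr(group, f.name)
        return out


def _group_fields() -> dict[str, tuple[str, type]]:
    """Map flat key -> (group attribute, group dataclass)."""
    mapping: dict[str, tuple[str, type]] = {}
    for attr, cls in (
        ("timeline", TimelineSpec),
        ("schedule", ScheduleParams),
        ("analysis", AnalysisParams),
        ("agent", AgentParams),
    ):
        for f in dataclasses.fields(cls):
            # camera_fps appears in two groups; keep both in sync on load
            mapping.setdefault(f.name, (attr, cls))
    return mapping


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> StudyConfig:
    """Load a :class:`StudyConfig` from a flat YAML file plus overrides.

    An empty or missing-keys file yields the full defaults; every invariant
    is re-validated, and unknown keys are rejected by name.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        raw.update(loaded)
    if overrides:
        raw.update(overrides)

    mapping = _group_fields()
    groups: dict[str, dict] = {"timeline": {}, "schedule": {}, "analysis": {}, "agent": {}}
    top: dict = {}
    for key, value in raw.items():
        if key in ("sphere_diameter_mm", "seed"):
            top[key] = value
        elif key in mapping:
            attr, _ = mapping[key]
            groups[attr][key] = value
            if key == "camera_fps":  # shared between analysis and agent
                groups["agent"][key] = value
        else:
            raise ConfigError(f"unknown configuration key: {key!r}")

    try:
        return StudyConfig(
            timeline=TimelineSpec(**groups["timeline"]),
            schedule=ScheduleParams(**groups["schedule"]),
            analysis=AnalysisParams(**groups["analysis"]),
            agent=AgentParams(**groups["agent"]),
            **top,
        )
    except TypeError as exc:  # bad field name surfaced by dataclass ctor
        raise ConfigError(str(exc)) from exc
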