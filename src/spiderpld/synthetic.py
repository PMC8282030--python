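"""Synthetic inputs with known ground truth: toy walks and virtual spiders.

``make_toy_walk`` emulates the digitized side view of a walking spider —
3 body points plus 8 legs of 3 joints each on semirigid (fixed-length)
segments, a periodic gait, global translation and occasional occlusion
gaps.  ``simulate_spider`` produces treadmill rotation traces for a whole
trial from a simple saccade policy whose preference and timing are known
exactly, so the entire extraction/inference chain can be validated
end-to-end without any recorded animal data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import (
    AgentParams,
    MAIN_CONDITIONS,
    ScheduleParams,
    TimelineSpec,
)
from .presentation import (
    TrialSchedule,
    VariantAssigner,
    center_x_profile,
    px_to_deg,
    schedule_trial,
)
from .tracks import BODY_POINT_LABELS, JointTrackSet, LEG_POINT_ROLES
from .kinematics import RotationTrace


def make_toy_walk(
    n_frames: int = 72,
    n_legs: int = 8,
    seed: int | None = None,
    n_steps: int = 8,
    gait_amplitude: float = 0.35,
    translation_per_frame: float = -2.0,
    occlusion_rate: float = 0.04,
) -> JointTrackSet:
    """Generate a side-view walking track with semirigid limb chains.

    Each leg is a three-segment chain of fixed lengths hanging from a hip
    on the body axis; joint angles oscillate sinusoidally with per-leg
    phase offsets (``n_steps`` full gait cycles over the clip) while the
    whole body translates at ``translation_per_frame`` px/frame (negative =
    right-to-left, as in a side view of leftward walking).  With
    ``seed``-driven probability ``occlusion_rate``, short runs of far-side
    leg points are marked invisible, mimicking occlusion by the body.
    Setting ``gait_amplitude=0`` yields pure translation.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames)
    phase = 2 * np.pi * n_steps * t / n_frames

    body_len = 80.0
    labels: list[str] = list(BODY_POINT_LABELS)
    leg_ids: list[int | None] = [None] * len(BODY_POINT_LABELS)
    pos = np.zeros((n_frames, 0, 2))

    # rigid body points along the axis (eyes forward at -x: walking leftward)
    body_offsets = {
        "eyes": (-body_len / 2, 6.0),
        "pedicel": (0.0, 2.0),
        "spinneret": (body_len / 2, 0.0),
    }
    cols = []
    for name in BODY_POINT_LABELS:
        ox, oy = body_offsets[name]
        cols.append(np.column_stack([ox + translation_per_frame * t, np.full(n_frames, oy)]))
    pos = np.stack(cols, axis=1)

    seg_lengths = (14.0, 12.0, 10.0)  # femur-patella..tarsus chain, px
    hips_x = np.linspace(-body_len / 2 + 6, body_len / 2 - 10, n_legs)
    for leg in range(n_legs):
        leg_phase = 2 * np.pi * leg / n_legs
        swing = gait_amplitude * np.sin(phase + leg_phase)
        # base angle pointing down-outward; distal segments progressively steeper
        base = -np.pi / 2 + 0.5 * np.sign(hips_x[leg] if hips_x[leg] != 0 else 1.0) * 0.6
        hip = np.column_stack(
            [hips_x[leg] + translation_per_frame * t, np.full(n_frames, -4.0)]
        )
        prev = hip
        for j, (role, L) in enumerate(zip(LEG_POINT_ROLES, seg_lengths)):
            ang = base + swing * (1.0 + 0.4 * j) + 0.25 * j
            joint = prev + L * np.column_stack([np.cos(ang), np.sin(ang)])
            labels.append(f"leg{leg}_{role}")
            leg_ids.append(leg)
            pos = np.concatenate([pos, joint[:, None, :]], axis=1)
            prev = joint

    visible = np.ones(pos.shape[:2], dtype=bool)
    if occlusion_rate > 0:
        far_side = [i for i, l in enumerate(labels) if l.startswith("leg") and int(l[3]) % 2 == 1]
        for p in far_side:
            starts = np.flatnonzero(rng.random(n_frames) < occlusion_rate)
            for s in starts:
                visible[s : s + int(rng.integers(2, 5)), p] = False
        # keep decompose well-posed: every point visible somewhere, frame 0 intact
        visible[0, :] = True
    return JointTrackSet(labels=labels, leg_ids=leg_ids, positions=pos, visible=visible)


# ---------------------------------------------------------------------------
# virtual spider on the treadmill


@dataclass
class GroundTruth:
    """Record of every simulated saccade: time, target, commanded rotation."""

    events: pd.DataFrame  # time_s, kind, chosen_side, commanded_deg, presentation_index
    preference: float
    seed: int | None


def _saccade_waveform(amplitude_rad: float, n_samples: int) -> np.ndarray:
    """Cosine-bell angular-velocity profile integrating to ``amplitude_rad``."""
    w = np.sin(np.pi * (np.arange(n_samples) + 0.5) / n_samples)
    return amplitude_rad * w / w.sum()


def simulate_spider(
    schedule: TrialSchedule,
    spec: TimelineSpec | None = None,
    params: AgentParams | None = None,
    seed: int | None = None,
) -> tuple[RotationTrace, GroundTruth]:
    """Simulate a full-trial rotation trace from the saccade policy.

    The agent walks forward continuously (x) with Gaussian wander on y and
    z.  While a stimulus pair is on screen, stimulus-driven saccade events
    fire from an angle-dependent hazard (stepping up when the stimulus is
    in the wide-angle secondary-eye band); each targets the
    more-biological stimulus with probability ``params.preference`` and
    rotates by the target's current angle over the saccade duration.
    Spontaneous saccades with random direction and amplitude occur at a low
    rate throughout.  Overlapping events are queued with a short refractory
    gap, never superposed.
    """
    spec = spec or TimelineSpec()
    params = params or AgentParams()
    rng = np.random.default_rng(seed)
    fps = params.camera_fps
    n = int(round(schedule.total_duration_s * fps))
    frames_t = np.arange(n) / fps

    # per-frame stimulus angle (NaN when nothing on screen) and hazard
    profile = center_x_profile(spec)
    angle = np.full(n, np.nan)
    pres_idx = np.full(n, -1, dtype=int)
    for k, t0 in enumerate(schedule.start_times):
        f0 = int(round(t0 * fps))
        f1 = min(int(round((t0 + schedule.presentation_s) * fps)), n)
        rel = frames_t[f0:f1] - t0
        disp = np.minimum((rel * spec.display_fps).astype(int), spec.total_frames - 1)
        on = disp >= spec.entry_offscreen_frames
        a = np.asarray(px_to_deg(np.abs(profile[disp]), spec))
        a[~on] = np.nan
        angle[f0:f1] = a
        pres_idx[f0:f1] = k

    hazard = np.zeros(n)
    vis = ~np.isnan(angle)
    hazard[vis] = np.where(
        np.abs(angle[vis]) >= params.band_deg,
        params.hazard_high_per_s,
        params.hazard_low_per_s,
    )
    if schedule.condition in ("silhouette_vs_ellipse", "ellipse_vs_nothing"):
        hazard *= params.contrast_multiplier  # higher-contrast shapes detected earlier

    stim_events = np.flatnonzero(rng.random(n) < hazard / fps)
    spont_events = np.flatnonzero(rng.random(n) < params.spont_hazard_per_s / fps)
    events = sorted(
        [(int(f), "stimulus") for f in stim_events] + [(int(f), "spontaneous") for f in spont_events]
    )

    dur = max(2, int(round(params.saccade_duration_s * fps)))
    refractory = max(1, int(round(0.05 * fps)))
    z = np.zeros(n)
    records = []
    next_free = 0
    for f0, kind in events:
        start = max(f0, next_free)
        if start + dur > n:
            continue
        if kind == "stimulus":
            k = pres_idx[f0]
            side_a, side_b = schedule.sides_at(k)
            toward_a = rng.random() < params.preference
            side = side_a if toward_a else side_b
            if side is None:  # single-stimulus condition, empty side chosen
                continue
            amp_deg = float(np.abs(angle[f0]))
        else:
            side = "L" if rng.random() < 0.5 else "R"
            amp_deg = float(rng.uniform(*params.spont_amplitude_deg))
            k = int(pres_idx[f0])
        sign = 1.0 if side == "L" else -1.0
        z[start : start + dur] += sign * _saccade_waveform(np.radians(amp_deg), dur)
        next_free = start + dur + refractory
        records.append(
            {
                "time_s": start / fps,
                "kind": kind,
                "chosen_side": side,
                "commanded_deg": sign * amp_deg,
                "presentation_index": k if kind == "stimulus" else -1,
            }
        )

    rot = np.empty((n, 3))
    rot[:, 0] = params.forward_speed + rng.normal(0.0, params.noise_sd, n)
    rot[:, 1] = rng.normal(0.0, params.wander_sd, n) + rng.normal(0.0, params.noise_sd, n)
    rot[:, 2] = z + rng.normal(0.0, params.wander_sd, n) + rng.normal(0.0, params.noise_sd, n)
    trace = RotationTrace(rot=rot, fps=fps)
    gt = GroundTruth(
        events=pd.DataFrame(
            records,
            columns=["time_s", "kind", "chosen_side", "commanded_deg", "presentation_index"],
        ),
        preference=params.preference,
        seed=seed,
    )
    return trace, gt


def synthetic_peak_table(
    n_subjects: int = 8,
    n_per_cell: int = 30,
    delta: float | dict = 0.0,
    between_mean: float = 0.0,
    subject_sd: float = 5.0,
    noise_sd: float = 20.0,
    angle_intercept: float = 50.0,
    angle_slope: float = 2.0,
    conditions: tuple[str, ...] = MAIN_CONDITIONS,
    seed: int | None = None,
) -> pd.DataFrame:
    """Directly generate a coded peak table with known model parameters.

    A model-level fixture: signed heights are ``delta`` (per condition, for
    during-stimulus rows) or ``between_mean`` plus a subject offset
    (s.d. ``subject_sd``) plus Gaussian noise; absolute heights follow
    ``angle_intercept + angle_slope * angle`` with the same error structure,
    against angles drawn uniformly on (5, 60) degrees.  Bypasses trace
    simulation so inference can be exercised cheaply at scale.
    """
    rng = np.random.default_rng(seed)
    deltas = delta if isinstance(delta, dict) else {c: float(delta) for c in conditions}
    rows = []
    for s in range(n_subjects):
        subject = f"s{s:03d}"
        off = rng.normal(0.0, subject_sd)
        off_abs = rng.normal(0.0, subject_sd)
        for c in conditions:
            trial = f"{subject}_{c}"
            for period in ("during", "between"):
                mu = deltas[c] if period == "during" else between_mean
                for _ in range(n_per_cell):
                    h = mu + off + rng.normal(0.0, noise_sd)
                    if period == "during":
                        angle = rng.uniform(5.0, 60.0)
                        abs_h = max(
                            0.0,
                            angle_intercept + angle_slope * angle + off_abs + rng.normal(0.0, noise_sd),
                        )
                    else:
                        angle, abs_h = float("nan"), abs(h)
                    rows.append(
                        {
                            "subject_id": subject,
                            "trial_id": trial,
                            "condition": c,
                            "time_s": float("nan"),
                            "presentation_index": -1,
                            "period": period,
                            "raw_sign": "L" if h > 0 else "R",
                            "coded_sign": 1 if h > 0 else -1,
                            "height_deg_s": h,
                            "abs_height_deg_s": abs_h,
                            "stimulus_angle_deg": angle,
                        }
                    )
    return pd.DataFrame(rows)


def make_dataset(
    n_subjects: int,
    conditions: tuple[str, ...] = MAIN_CONDITIONS,
    seed: int | None = None,
    spec: TimelineSpec | None = None,
    schedule_params: ScheduleParams | None = None,
) -> pd.DataFrame:
    """Design table of a full study: each subject sees each condition once.

    Condition order is randomized per subject; the side pattern alternates
    between the two printed sequences; stochastic-stimulus variants are
    assigned without replacement per subject and kind.  Returns one row per
    trial with the trial's own simulation seed, plus the schedule object.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    spec = spec or TimelineSpec()
    sp = schedule_params or ScheduleParams()
    rng = np.random.default_rng(seed)
    assigner = VariantAssigner(seed=None if seed is None else seed + 1)
    rows = []
    for s in range(n_subjects):
        subject = f"s{s:03d}"
        order = rng.permutation(len(conditions))
        for trial_no, ci in enumerate(order):
            condition = conditions[int(ci)]
            pattern_id = int(rng.integers(2))
            sched = schedule_trial(
                condition,
                spec=spec,
                schedule_params=sp,
                pattern_id=pattern_id,
                subject_id=subject,
                assigner=assigner,
                seed=int(rng.integers(2**31 - 1)),
            )
            rows.append(
                {
                    "subject_id": subject,
                    "trial_id": f"{subject}_t{trial_no}",
                    "trial_index": trial_no,
                    "condition": condition,
                    "pattern_id": pattern_id,
                    "sim_seed": int(rng.integers(2**31 - 1)),
                    "schedule": sched,
                }
            )
    return pd.DataFrame(rows)
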