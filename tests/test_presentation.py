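"""Presentation timeline, mirroring, trial schedules and stimulus angle."""

import numpy as np
import pytest

from spiderpld.config import ConfigError, ScheduleParams, TimelineSpec
from spiderpld.displays import make_biological
from spiderpld.presentation import (
    TrialSchedule,
    VariantAssigner,
    VariantPoolError,
    compose_presentation,
    center_x_profile,
    frame_plan,
    px_to_deg,
    schedule_trial,
    stimulus_angle_at,
)
from spiderpld.shapes import make_silhouette


class TestTimelineSpec:
    def test_default_arithmetic(self, spec):
        assert spec.total_frames == 270
        assert spec.presentation_seconds == 9.0
        assert spec.visible_frames == 240
        assert spec.visible_seconds == 8.0
        assert spec.pause_frames / spec.display_fps == 1.5

    def test_inconsistent_totals_rejected(self):
        with pytest.raises(ConfigError, match="total_frames"):
            TimelineSpec(move_block_frames=72)  # 3*72 + 2*45 = 306 != 270

    def test_frame_plan_covers_all_frames(self, spec):
        src, moving = frame_plan(spec, 72)
        assert len(src) == 270
        assert moving.sum() == 180
        assert src.min() == 0 and src.max() == 71


class TestComposePresentation:
    def test_emits_total_frames_and_entry(self, toy_tracks, spec):
        pres = compose_presentation(make_biological(toy_tracks), spec, "L")
        assert pres.n_frames == 270
        assert int(np.argmax(pres.onscreen)) == spec.entry_offscreen_frames
        assert pres.onscreen.sum() / spec.display_fps == 8.0

    def test_mirror_property(self, toy_tracks, spec):
        bio = make_biological(toy_tracks)
        left = compose_presentation(bio, spec, "L")
        right = compose_presentation(bio, spec, "R")
        np.testing.assert_allclose(left.center_x, -right.center_x)
        flipped = right.positions.copy()
        flipped[..., 0] *= -1
        np.testing.assert_allclose(left.positions, flipped)
        np.testing.assert_array_equal(left.dot_visible, right.dot_visible)

    def test_mirror_is_involution(self, toy_tracks, spec):
        pres = compose_presentation(make_biological(toy_tracks), spec, "L")
        back = pres.mirrored().mirrored()
        np.testing.assert_allclose(back.positions, pres.positions)

    def test_ends_hidden_behind_occluder(self, toy_tracks, spec):
        pres = compose_presentation(make_biological(toy_tracks), spec, "L")
        assert abs(pres.center_x[-1]) < 1e-9
        assert not pres.dot_visible[-1].any()

    def test_static_during_pauses(self, toy_tracks, spec):
        pres = compose_presentation(make_biological(toy_tracks), spec, "L")
        _, moving = frame_plan(spec, toy_tracks.n_frames)
        pause = ~moving
        pause_positions = pres.positions[pause]
        # each pause holds one fixed frame
        diffs = np.diff(pres.center_x)[np.flatnonzero(pause[1:] & pause[:-1])]
        np.testing.assert_allclose(diffs, 0.0, atol=1e-12)
        assert pause_positions.shape[0] == 2 * spec.pause_frames

    def test_shape_display_composes(self, toy_tracks, spec):
        sil = make_silhouette(toy_tracks)
        pres = compose_presentation(sil, spec, "R")
        assert len(pres.shape_frames) == spec.total_frames
        assert pres.side == "R"

    def test_bad_side_rejected(self, toy_tracks, spec):
        with pytest.raises(ValueError, match="side"):
            compose_presentation(make_biological(toy_tracks), spec, "C")


class TestTrialSchedule:
    def test_default_trial_duration(self):
        sched = schedule_trial("bio_vs_random", pattern_id=0, seed=0)
        assert sched.total_duration_s == 690.0  # 11 min 30 s
        assert sched.n_presentations == 10
        assert sched.start_times[0] == 300.0

    def test_zero_presentations_is_habituation_only(self):
        sched = schedule_trial(
            "bio_vs_random", schedule_params=ScheduleParams(n_presentations=0), pattern_id=0
        )
        assert sched.total_duration_s == 300.0

    def test_side_pattern_is_a_printed_sequence(self):
        for pid, expected in ((0, "LRLRLLRRLR"), (1, "RLRLRRLLRL")):
            sched = schedule_trial("bio_vs_scrambled", pattern_id=pid)
            assert sched.side_pattern == expected

    def test_period_labeling(self):
        sched = schedule_trial("bio_vs_random", pattern_id=0)
        assert sched.period_at(100.0) == ("habituation", -1)
        assert sched.period_at(300.0) == ("during", 0)
        assert sched.period_at(300.0 + 9.0) == ("between", 0)
        assert sched.period_at(300.0 + 39.0) == ("during", 1)
        assert sched.period_at(690.0) == ("after", -1)

    def test_swapped_sides_flips_every_entry(self):
        sched = schedule_trial("bio_vs_random", pattern_id=0)
        swapped = sched.swapped_sides()
        assert all(a != b for a, b in zip(sched.side_pattern, swapped.side_pattern))

    def test_single_stimulus_condition_has_no_second_side(self):
        sched = schedule_trial("ellipse_vs_nothing", pattern_id=0)
        a, b = sched.sides_at(0)
        assert a in "LR" and b is None

    def test_variant_constant_within_trial(self):
        sched = schedule_trial("scrambled_vs_random", pattern_id=0, seed=3)
        for kind in ("scrambled", "random"):
            assert len(set(sched.variant_indices[kind])) == 1


class TestVariantAssigner:
    def test_no_repetition_across_trials(self):
        assigner = VariantAssigner(seed=0)
        draws = [assigner.draw("s0", "scrambled") for _ in range(4)]
        assert sorted(draws) == [0, 1, 2, 3]

    def test_pool_exhaustion_raises(self):
        assigner = VariantAssigner(seed=0)
        for _ in range(4):
            assigner.draw("s0", "random")
        with pytest.raises(VariantPoolError, match="s0"):
            assigner.draw("s0", "random")

    def test_pools_are_per_subject_and_kind(self):
        assigner = VariantAssigner(seed=0)
        for _ in range(4):
            assigner.draw("s0", "random")
        assert 0 <= assigner.draw("s1", "random") < 4
        assert 0 <= assigner.draw("s0", "scrambled") < 4


class TestStimulusAngle:
    def test_center_is_zero_degrees(self, spec):
        assert px_to_deg(0.0, spec) == 0.0

    def test_closed_form_at_960_px(self, spec):
        # arctan(960 * 0.248 mm / 140 mm) = 59.5 degrees
        assert px_to_deg(960.0, spec) == pytest.approx(59.55, abs=0.05)

    def test_angle_undefined_between_stimuli(self, spec):
        sched = schedule_trial("bio_vs_random", pattern_id=0)
        assert np.isnan(stimulus_angle_at(sched, spec, sched.start_times[0] + 10.0))
        assert np.isnan(stimulus_angle_at(sched, spec, 100.0))

    def test_monotone_nonincreasing_within_presentation(self, spec):
        sched = schedule_trial("bio_vs_random", pattern_id=0)
        t0 = sched.start_times[0]
        ts = t0 + np.linspace(1.01, 8.99, 120)
        angles = [stimulus_angle_at(sched, spec, t) for t in ts]
        assert all(b <= a + 1e-9 for a, b in zip(angles, angles[1:]))

    def test_signed_by_side(self, spec):
        sched = schedule_trial("bio_vs_random", pattern_id=0)
        t = sched.start_times[0] + 2.0
        left = stimulus_angle_at(sched, spec, t, side="L")
        right = stimulus_angle_at(sched, spec, t, side="R")
        assert left > 0 and right == -left

    def test_profile_reaches_screen_edge_at_entry(self, spec):
        profile = center_x_profile(spec)
        e = spec.entry_offscreen_frames
        assert profile[e] - spec.stim_width_px / 2 == pytest.approx(spec.screen_width_px / 2)
        assert profile[e - 1] > profile[e]
        assert profile[-1] == pytest.approx(0.0, abs=1e-9)
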