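"""Scrambled/random display construction invariants and oracles."""

import numpy as np
import pytest

from spiderpld.displays import (
    local_steps_of,
    make_biological,
    make_random,
    make_scrambled,
)
from spiderpld.tracks import decompose

from conftest import track_from_positions


@pytest.fixture(scope="module")
def field(toy_tracks):
    return decompose(toy_tracks)


class TestBiological:
    def test_one_dot_per_point_identity(self, toy_tracks):
        bio = make_biological(toy_tracks)
        assert bio.n_dots == 27
        np.testing.assert_array_equal(bio.positions, toy_tracks.positions)
        np.testing.assert_array_equal(bio.visible, toy_tracks.visible)

    def test_single_pair_track_identity(self):
        pos = [[[0.0, 0.0], [4.0, 2.0]], [[1.0, 0.0], [5.0, 2.0]]]
        ts = track_from_positions(pos)
        bio = make_biological(ts)
        np.testing.assert_allclose(bio.positions, pos)


class TestScrambled:
    def test_path_identity_frame_by_frame(self, toy_tracks, field):
        sc = make_scrambled(toy_tracks, seed=11)
        np.testing.assert_allclose(local_steps_of(sc), field.local_steps, atol=1e-9)

    def test_center_path_matches_biological(self, toy_tracks):
        bio = make_biological(toy_tracks)
        sc = make_scrambled(toy_tracks, seed=11)
        np.testing.assert_allclose(sc.center_path, bio.center_path)

    def test_biological_starts_reproduce_biological(self, toy_tracks, field):
        sc = make_scrambled(toy_tracks, starts=field.start_local)
        rebuilt = field.integrate()
        np.testing.assert_allclose(sc.positions, rebuilt, atol=1e-9)

    def test_hand_integration_oracle(self):
        # 2 dots, 3 frames; integrate the local steps from the same random
        # starts by hand
        pos = [
            [[0.0, 0.0], [2.0, 0.0]],
            [[0.0, 1.0], [2.0, -1.0]],
            [[1.0, 1.0], [3.0, 0.0]],
        ]
        ts = track_from_positions(pos)
        field = decompose(ts)
        starts = np.array([[0.3, -0.2], [-0.5, 0.1]])
        sc = make_scrambled(ts, starts=starts)
        local = starts[None] + np.concatenate(
            [np.zeros((1, 2, 2)), np.cumsum(field.local_steps, axis=0)]
        )
        np.testing.assert_allclose(sc.positions, local + field.center_path[:, None, :], atol=1e-12)

    def test_determinism(self, toy_tracks):
        a = make_scrambled(toy_tracks, seed=7)
        b = make_scrambled(toy_tracks, seed=7)
        np.testing.assert_array_equal(a.positions, b.positions)


class TestRandom:
    def test_step_magnitude_identity(self, toy_tracks, field):
        rd = make_random(toy_tracks, seed=5)
        np.testing.assert_allclose(
            np.linalg.norm(local_steps_of(rd), axis=2),
            np.linalg.norm(field.local_steps, axis=2),
            atol=1e-9,
        )

    def test_box_containment(self, toy_tracks):
        rd = make_random(toy_tracks, seed=5)
        local = rd.positions - rd.center_path[:, None, :]
        assert np.abs(local[..., 0]).max() <= 85.0 + 1e-9
        assert np.abs(local[..., 1]).max() <= 30.0 + 1e-9

    def test_starts_at_biological_first_frame(self, toy_tracks):
        bio = make_biological(toy_tracks)
        rd = make_random(toy_tracks, seed=5)
        np.testing.assert_allclose(rd.positions[0], bio.positions[0], atol=1e-9)

    def test_zero_steps_reproduce_biological(self):
        # pure translation: local steps vanish, so randomized directions
        # change nothing
        base = np.array([[-10.0, -3.0], [10.0, 3.0]])
        pos = [base + [2.0 * f, 0.0] for f in range(5)]
        ts = track_from_positions(pos)
        rd = make_random(ts, seed=9)
        np.testing.assert_allclose(rd.positions, pos, atol=1e-12)

    def test_rejection_loop_resimulation_oracle(self):
        # replay the constructor's draw sequence with the same generator to
        # verify accepted directions near the box edge
        pos = [
            [[-84.0, 0.0], [84.0, 0.0]],
            [[-84.0, 20.0], [84.0, -20.0]],
            [[-60.0, 20.0], [60.0, -20.0]],
        ]
        ts = track_from_positions(pos)
        field = decompose(ts)
        seed = 42
        rd = make_random(ts, seed=seed)

        rng = np.random.default_rng(seed)
        mags = np.linalg.norm(field.local_steps, axis=2)
        local = [field.start_local.copy()]
        for t in range(mags.shape[0]):
            prev = local[-1]
            pending = np.ones(2, dtype=bool)
            cand = np.empty_like(prev)
            while pending.any():
                theta = rng.uniform(0.0, 2 * np.pi, size=int(pending.sum()))
                step = np.column_stack([np.cos(theta), np.sin(theta)]) * mags[t, pending, None]
                cand[pending] = prev[pending] + step
                inside = (np.abs(cand[:, 0]) <= 85.0 + 1e-9) & (np.abs(cand[:, 1]) <= 30.0 + 1e-9)
                pending = pending & ~inside
            local.append(cand)
        expected = np.asarray(local) + field.center_path[:, None, :]
        np.testing.assert_allclose(rd.positions, expected, atol=1e-12)

    def test_rejection_budget_error_names_dot_and_frame(self):
        # a step longer than the box diagonal can never land inside
        pos = [
            [[-85.0, -30.0], [85.0, 30.0]],
            [[-85.0, -30.0], [85.0, 30.0]],
        ]
        ts = track_from_positions(pos)
        ts.positions[1, 1] = [85.0 + 400.0, 30.0]
        with pytest.raises(RuntimeError, match=r"p[01].*transition 0"):
            make_random(ts, seed=1, max_redraws=50)

    def test_determinism(self, toy_tracks):
        a = make_random(toy_tracks, seed=3)
        b = make_random(toy_tracks, seed=3)
        np.testing.assert_array_equal(a.positions, b.positions)


class TestCenterPathEquality:
    def test_all_dot_displays_share_the_center_trajectory(self, toy_tracks):
        bio = make_biological(toy_tracks)
        sc = make_scrambled(toy_tracks, seed=1)
        rd = make_random(toy_tracks, seed=2)
        np.testing.assert_allclose(sc.center_path, bio.center_path)
        np.testing.assert_allclose(rd.center_path, bio.center_path)

    def test_shape_displays_share_the_center_trajectory(self, toy_tracks):
        from spiderpld.shapes import make_ellipse, make_silhouette

        bio = make_biological(toy_tracks)
        sil = make_silhouette(toy_tracks)
        ell = make_ellipse(sil)
        np.testing.assert_allclose(sil.center_path, bio.center_path)
        np.testing.assert_allclose(ell.center_path, bio.center_path)


class TestMirroring:
    def test_involution(self, toy_tracks):
        bio = make_biological(toy_tracks)
        np.testing.assert_array_equal(bio.mirrored().mirrored().positions, bio.positions)

    def test_commutes_with_biological(self, toy_tracks):
        mirrored_tracks = track_from_positions(
            toy_tracks.positions * np.array([-1.0, 1.0]),
            visible=toy_tracks.visible,
            labels=toy_tracks.labels,
            leg_ids=toy_tracks.leg_ids,
        )
        a = make_biological(mirrored_tracks)
        b = make_biological(toy_tracks).mirrored()
        np.testing.assert_allclose(a.positions, b.positions)

    def test_scrambled_path_identity_survives_mirroring(self, toy_tracks, field):
        sc = make_scrambled(toy_tracks, seed=2).mirrored()
        flipped = field.local_steps * np.array([-1.0, 1.0])
        np.testing.assert_allclose(local_steps_of(sc), flipped, atol=1e-9)
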