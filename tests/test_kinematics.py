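"""Trace reading, filtering, cross-axis suppression, peaks and sign coding."""

import numpy as np
import pandas as pd
import pytest
import scipy.signal
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from spiderpld.config import AnalysisParams, TimelineSpec
from spiderpld.kinematics import (
    RotationTrace,
    SaccadeSignal,
    code_peaks,
    extract_saccades,
    find_peaks,
    read_trace,
    saccade_signal,
    smooth,
)
from spiderpld.presentation import schedule_trial


def brute_force_peaks(values, threshold):
    """Exhaustive strict-local-extrema scan (plateaus at first sample)."""
    out = []
    n = len(values)
    for sign in (1.0, -1.0):
        v = values * sign
        for i in range(1, n - 1):
            if v[i] <= threshold or v[i - 1] >= v[i]:
                continue
            r = i + 1
            while r < n and v[r] == v[i]:
                r += 1
            if r < n and v[r] < v[i]:
                out.append(i)
    return sorted(out)


class TestReadTrace:
    def test_plain_csv(self, tmp_path):
        p = tmp_path / "trace.csv"
        p.write_text("frame,rot_x,rot_y,rot_z\n0,0.1,0.2,0.3\n1,0.0,0.0,-0.1\n2,0.1,0.1,0.0\n")
        tr = read_trace(p)
        assert tr.n_frames == 3
        np.testing.assert_allclose(tr.rot[1], [0.0, 0.0, -0.1])

    def test_fictrac_style_extra_columns(self, tmp_path):
        p = tmp_path / "trace.dat"
        rows = []
        for f in range(3):
            cols = [f, 9, 9, 9, 0.01, 0.1 * f, 0.2 * f, 0.3 * f] + [0] * 17
            rows.append(",".join(str(c) for c in cols))
        p.write_text("\n".join(rows))
        tr = read_trace(p)
        np.testing.assert_allclose(tr.rot[2], [0.2, 0.4, 0.6])

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("")
        with pytest.raises(ValueError, match="empty"):
            read_trace(p)

    def test_non_numeric_row_reports_line(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("rot_x,rot_y,rot_z\n0.1,0.2,0.3\n0.1,oops,0.3\n")
        with pytest.raises(ValueError, match="line 3"):
            read_trace(p)

    def test_z_sign_normalization(self, tmp_path):
        df = pd.DataFrame({"rot_x": [0.0, 0.0], "rot_y": [0.0, 0.0], "rot_z": [0.1, -0.2]})
        tr = read_trace(df)
        tr_flipped = RotationTrace(rot=tr.rot * [1, 1, -1], fps=tr.fps)
        np.testing.assert_allclose(tr.rot[:, 2], -tr_flipped.rot[:, 2])


class TestSmooth:
    def test_constant_signal_passes_through(self):
        tr = RotationTrace(rot=np.full((200, 3), 0.01))
        out = smooth(tr)
        np.testing.assert_allclose(out.rot, 0.01, atol=1e-9)

    def test_causal_mode_matches_difference_equation(self):
        # independent oracle: run the order-3 recursion by hand
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        tr = RotationTrace(rot=np.column_stack([x, x, x]))
        out = smooth(tr, AnalysisParams(filter_mode="causal"))
        b, a = scipy.signal.butter(3, 0.5)
        y = np.zeros_like(x)
        for n in range(len(x)):
            acc = 0.0
            for k in range(len(b)):
                if n - k >= 0:
                    acc += b[k] * x[n - k]
            for k in range(1, len(a)):
                if n - k >= 0:
                    acc -= a[k] * y[n - k]
            y[n] = acc / a[0]
        np.testing.assert_allclose(out.rot[:, 2], y, atol=1e-12)

    def test_noise_variance_reduced(self):
        rng = np.random.default_rng(1)
        tr = RotationTrace(rot=rng.normal(size=(2000, 3)))
        out = smooth(tr)
        assert out.rot.var() < tr.rot.var()

    def test_zero_phase_no_lag_on_symmetric_bump(self):
        n = 201
        bump = np.exp(-0.5 * ((np.arange(n) - 100) / 5.0) ** 2)
        tr = RotationTrace(rot=np.column_stack([bump, bump, bump]))
        out = smooth(tr)
        assert int(np.argmax(out.rot[:, 2])) == 100

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            smooth(RotationTrace(rot=np.zeros((8, 3))))


class TestSaccadeSignal:
    @pytest.mark.parametrize(
        "xyz, expected",
        [
            ((0.0, 0.0, 0.004), 0.004),  # pure saccade passes through
            ((0.003, 0.002, 0.004), 0.0),  # coupled motion suppressed
            ((0.002, 0.001, -0.010), -0.007),  # stated rule, by hand
            ((0.0, 0.0, -0.004), -0.004),
        ],
    )
    def test_rule_examples(self, xyz, expected):
        tr = RotationTrace(rot=np.array([xyz]))
        assert saccade_signal(tr).values[0] == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=200, deadline=None)
    @given(
        rot=hnp.arrays(
            float,
            st.tuples(st.integers(1, 50), st.just(3)),
            elements=st.floats(-0.1, 0.1, allow_nan=False),
        )
    )
    def test_suppression_bound_property(self, rot):
        tr = RotationTrace(rot=rot)
        s = saccade_signal(tr).values
        z = rot[:, 2]
        assert np.all(np.abs(s) <= np.abs(z) + 1e-15)
        coupled = np.abs(z) <= np.abs(rot[:, 0]) + np.abs(rot[:, 1])
        assert np.all(s[coupled] == 0.0)
        nonzero = s != 0
        assert np.all(np.sign(s[nonzero]) == np.sign(z[nonzero]))


class TestFindPeaks:
    def test_frozen_example(self):
        v = np.array([0.0, 0.002, 0.005, 0.003, 0.0, -0.004, -0.001])
        peaks = find_peaks(v, 0.001)
        assert peaks["index"].tolist() == [2, 5]
        np.testing.assert_allclose(peaks["value"], [0.005, -0.004])

    def test_all_zero_and_subthreshold_empty(self):
        assert find_peaks(np.zeros(50), 0.001).empty
        assert find_peaks(np.full(50, 0.0005), 0.001).empty

    def test_plateau_counted_once_at_first_sample(self):
        v = np.array([0.0, 0.004, 0.004, 0.004, 0.0])
        peaks = find_peaks(v, 0.001)
        assert peaks["index"].tolist() == [1]

    def test_strictness_at_threshold(self):
        v = np.array([0.0, 0.001, 0.0])
        assert find_peaks(v, 0.001).empty

    def test_brute_force_oracle_on_random_traces(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            n = int(rng.integers(3, 1000))
            v = rng.normal(0, 0.002, n)
            if rng.random() < 0.3:  # inject plateaus and zeros
                v = np.round(v, 3)
            got = find_peaks(v, 0.001)["index"].tolist()
            assert sorted(got) == brute_force_peaks(v, 0.001)

    def test_sign_antisymmetry(self):
        rng = np.random.default_rng(8)
        v = rng.normal(0, 0.003, 500)
        pos = find_peaks(v, 0.001)
        neg = find_peaks(-v, 0.001)
        assert sorted(pos["index"]) == sorted(neg["index"])
        np.testing.assert_allclose(
            np.sort(pos["value"].to_numpy()), np.sort(-neg["value"].to_numpy())
        )


class TestCodePeaks:
    @pytest.fixture
    def sched(self):
        return schedule_trial("bio_vs_random", pattern_id=0)  # pattern LRLRLLRRLR

    def _peaks_at(self, times, values):
        return pd.DataFrame({"index": range(len(times)), "time_s": times, "value": values})

    def test_left_turn_toward_left_biological_is_positive(self, sched, spec):
        # presentation 0: biological enters left; +value = leftward turn
        t = sched.start_times[0] + 5.0
        coded = code_peaks(self._peaks_at([t], [0.01]), sched, spec)
        assert coded.loc[0, "coded_sign"] == 1
        assert coded.loc[0, "period"] == "during"
        assert coded.loc[0, "height_deg_s"] > 0

    def test_pause_keeps_previous_coding(self, sched, spec):
        t = sched.start_times[0] + 9.0 + 10.0  # in the following pause
        coded = code_peaks(self._peaks_at([t], [0.01]), sched, spec)
        assert coded.loc[0, "coded_sign"] == 1
        assert coded.loc[0, "period"] == "between"
        assert np.isnan(coded.loc[0, "stimulus_angle_deg"])

    def test_swapped_sides_negate_coding(self, sched, spec):
        times = [sched.start_times[k] + 4.0 for k in range(10)]
        values = [0.01 if k % 2 else -0.01 for k in range(10)]
        a = code_peaks(self._peaks_at(times, values), sched, spec)
        b = code_peaks(self._peaks_at(times, values), sched.swapped_sides(), spec)
        np.testing.assert_array_equal(a["coded_sign"], -b["coded_sign"])
        np.testing.assert_allclose(a["height_deg_s"], -b["height_deg_s"])

    def test_habituation_peaks_dropped(self, sched, spec):
        coded = code_peaks(self._peaks_at([100.0, 305.0], [0.01, 0.01]), sched, spec)
        assert len(coded) == 1

    def test_height_unit_conversion(self, sched, spec, analysis):
        t = sched.start_times[0] + 5.0
        coded = code_peaks(self._peaks_at([t], [0.01]), sched, spec, analysis)
        assert coded.loc[0, "abs_height_deg_s"] == pytest.approx(
            0.01 * 120.0 * 180.0 / np.pi
        )

    def test_during_angle_matches_stimulus_position(self, sched, spec):
        t = sched.start_times[0] + 1.5
        coded = code_peaks(self._peaks_at([t], [0.01]), sched, spec)
        from spiderpld.presentation import stimulus_angle_at

        assert coded.loc[0, "stimulus_angle_deg"] == pytest.approx(
            stimulus_angle_at(sched, spec, t)
        )


class TestPipelineDeterminism:
    def test_identical_trace_identical_peaks(self):
        rng = np.random.default_rng(3)
        rot = rng.normal(0, 0.002, (3000, 3))
        tr = RotationTrace(rot=rot)
        a = extract_saccades(tr)
        b = extract_saccades(RotationTrace(rot=rot.copy()))
        pd.testing.assert_frame_equal(a, b)
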