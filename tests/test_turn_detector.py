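"""Turn detection: yaw rate, extrema ordering, window-mean bound search."""

import dataclasses

import numpy as np
import pytest

from tugseg import (AlgorithmConfig, DetectionError, TugScenario,
                    condition_yaw, detect_turns, locate_turn_extrema,
                    simulate, window_search_turn_bounds, yaw_rate)
from tugseg.preprocessing import ConditionedSignal


def _signal(values, fs=100.0, source=None):
    values = np.asarray(values, dtype=float)
    return ConditionedSignal(values=values, t=np.arange(values.size) / fs,
                             fs=fs, scale=180.0, baseline=0.0, source=source)


class TestYawRate:
    def test_linear_ramp_gives_constant_slope(self):
        sig = _signal(0.25 * np.arange(400) / 100.0)
        rate = yaw_rate(sig)
        np.testing.assert_allclose(rate, 0.25, atol=1e-9)

    def test_constant_gives_zero(self):
        rate = yaw_rate(_signal(np.full(300, 0.7)))
        np.testing.assert_allclose(rate, 0.0, atol=1e-12)

    def test_logistic_inflection_located_within_one_sample(self):
        t = np.arange(1000) / 100.0
        sig = _signal(1.0 / (1.0 + np.exp(-3.0 * (t - 5.0))))
        rate = yaw_rate(sig)
        assert abs(t[np.argmax(rate)] - 5.0) <= 0.01 + 1e-12


class TestLocateTurnExtrema:
    def test_rise_then_fall_ordered(self):
        t = np.arange(1200) / 100.0
        x = np.clip((t - 3.5), 0, 1) - np.clip((t - 7.5), 0, 1)
        t_max, t_min = locate_turn_extrema(yaw_rate(_signal(x)), 100.0)
        assert 3.5 <= t_max <= 4.6
        assert 7.5 <= t_min <= 8.6
        assert t_max < t_min

    def test_fall_before_rise_raises(self):
        t = np.arange(1200) / 100.0
        x = 1.0 - np.clip((t - 3.5), 0, 1) + np.clip((t - 7.5), 0, 1)
        with pytest.raises(DetectionError, match="turn order"):
            locate_turn_extrema(yaw_rate(_signal(x)), 100.0)


class TestWindowSearchTurnBounds:
    def _piecewise(self, width=1.5):
        # 0 until t=4, linear ramp to 1 over [4, 4+width], plateau 1 after
        t = np.arange(1000) / 100.0
        x = np.clip((t - 4.0) / width, 0.0, 1.0)
        return _signal(x), t

    def test_ramp_bounds_recovered(self):
        sig, t = self._piecewise()
        lo, hi, flags = window_search_turn_bounds(sig, t_extremum=4.75,
                                                  which="turn1_3m")
        assert lo == pytest.approx(4.0, abs=0.15)
        # the 0.9 window-mean level is reached just before the plateau
        assert hi == pytest.approx(5.5, abs=0.25)
        assert not flags

    def test_turn2_mirrors_turn1_on_reversed_signal(self):
        # ramp width chosen so no window mean sits exactly on a stop level
        # (a float tie there can move a bound by one sample)
        sig, t = self._piecewise(width=1.37)
        rev = _signal(sig.values[::-1].copy())
        lo1, hi1, _ = window_search_turn_bounds(sig, 4.685, "turn1_3m")
        T = sig.t[-1]
        lo2, hi2, _ = window_search_turn_bounds(rev, T - 4.685, "turn2_presit")
        assert lo2 == pytest.approx(T - hi1, abs=1e-9)
        assert hi2 == pytest.approx(T - lo1, abs=1e-9)

    def test_plateau_below_high_level_overruns(self):
        # plateau at 0.85 never satisfies the 0.9 criterion: the rightward
        # search runs on until it clamps at the recording edge
        t = np.arange(1000) / 100.0
        x = 0.85 * np.clip((t - 4.0) / 1.5, 0.0, 1.0)
        lo, hi, flags = window_search_turn_bounds(_signal(x), 4.75, "turn1_3m")
        assert "end-clamped-to-edge" in flags
        assert hi == pytest.approx(t[-1])


class TestDetectTurns:
    def test_simulator_bounds_recovered(self):
        scn = TugScenario(seed=7)
        rec, truth = simulate(scn)
        turn1, turn2 = detect_turns(condition_yaw(rec))
        b = truth.boundaries
        assert abs(turn1.t_start - b["turn1_start"]) <= 0.3
        assert abs(turn1.t_end - b["turn1_end"]) <= 0.4
        assert abs(turn2.t_start - b["turn2_start"]) <= 0.4
        assert abs(turn2.t_end - b["turn2_end"]) <= 0.3
        assert turn1.t_end <= turn2.t_start
        for ev in (turn1, turn2):
            assert 90.0 < ev.rotation_span < 270.0

    def test_window_mean_criteria_hold_at_detected_bounds(self):
        # direct restatement of the stop criteria: the signal averages below
        # the low level before turn1 starts and above the high level after
        # turn1 ends
        rec, _ = simulate(TugScenario(seed=19))
        cond = condition_yaw(rec)
        turn1, _ = detect_turns(cond)
        fs = cond.fs
        i0 = cond.index_at(turn1.t_start)
        i1 = cond.index_at(turn1.t_end)
        before = cond.values[max(0, i0 - int(0.5 * fs)):i0 + 1]
        after = cond.values[i1:i1 + int(0.5 * fs)]
        assert np.mean(before) < 0.02 + 0.05
        assert np.mean(after) > 0.9 - 0.05

    def test_same_direction_turns_literal_vs_robust(self):
        scn = TugScenario(seed=3, turn_direction="same")
        rec, truth = simulate(scn)
        cond = condition_yaw(rec)
        with pytest.raises(DetectionError, match="turn order"):
            detect_turns(cond)
        turn1, turn2 = detect_turns(cond, AlgorithmConfig(robust_turns=True))
        b = truth.boundaries
        assert abs(turn1.t_start - b["turn1_start"]) <= 0.4
        assert abs(turn2.t_end - b["turn2_end"]) <= 0.4
        assert turn1.t_end <= turn2.t_start

    def test_mirrored_subject_detected_identically(self):
        # a subject turning clockwise instead of counter-clockwise gives a
        # sign-flipped yaw; orientation repair makes detection identical
        scn = TugScenario(seed=11)
        rec, truth = simulate(scn)
        flipped = dataclasses.replace(rec) if False else rec
        import tugseg.signal_model as sm
        mirrored = sm.ImuRecording(
            t=rec.t, fs=rec.fs, pitch=rec.pitch, yaw=-rec.yaw,
            acc_z=rec.acc_z, gyr_z=rec.gyr_z)
        a1, a2 = detect_turns(condition_yaw(rec))
        m1, m2 = detect_turns(condition_yaw(mirrored))
        assert m1.t_start == pytest.approx(a1.t_start, abs=1e-9)
        assert m2.t_end == pytest.approx(a2.t_end, abs=1e-9)

    def test_noiseless_bounds_near_transition_knots(self, noiseless_recording):
        rec, truth = noiseless_recording
        turn1, turn2 = detect_turns(condition_yaw(rec))
        b = truth.boundaries
        # low-level (0.02) bounds sit within ~0.2 s of the true interval;
        # high-level (0.9) bounds carry the structural smoothstep offset
        assert abs(turn1.t_start - b["turn1_start"]) <= 0.2
        assert abs(turn2.t_end - b["turn2_end"]) <= 0.2
        assert abs(turn1.t_end - b["turn1_end"]) <= 0.5
        assert abs(turn2.t_start - b["turn2_start"]) <= 0.5
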