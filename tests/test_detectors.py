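"""Detector behaviour: threshold-crossing semantics, contact-pattern
rules, fusion logic, and cross-method invariants on simulated gait."""

import numpy as np
import pytest

from gaitevents import (DetectionError, DetectorParams, Kinematics,
                        MarkerTrialData, SyntheticGaitSpec, detect_events,
                        estimate_walking_speed, evaluate_events,
                        simulate_trial)
from gaitevents.detectors import (METHODS, _crossings, detect_fc_velocity3d,
                                  detect_ic_velocity3d,
                                  detect_sagittal_velocity, detect_velocity3d,
                                  detect_m10)

FS = 100.0


# ----------------------------------------------------------------------
# crossing primitive
# ----------------------------------------------------------------------

class TestCrossings:
    def test_downward_crossing_at_first_satisfying_sample(self):
        t = np.arange(300) / FS
        sig = np.where(t < 1.0, 2.0, 0.1)  # drops below 0.5 at t = 1.00
        idx = _crossings(sig, np.ones(300, bool), 0.5, 20, "down")
        assert list(t[idx]) == [1.0]

    def test_no_event_when_never_below(self):
        sig = np.full(300, 1.0)
        assert _crossings(sig, np.ones(300, bool), 0.5, 20, "down").size == 0

    def test_debounce_rejects_chatter(self):
        sig = np.full(300, 2.0)
        sig[100:103] = 0.1   # genuine crossing
        sig[110:113] = 0.1   # re-crossing 0.07 s later: not re-armed
        idx = _crossings(sig, np.ones(300, bool), 0.5, 20, "down")
        assert list(idx) == [100]

    def test_segment_start_counts_as_armed(self):
        sig = np.full(300, 2.0)
        sig[10:] = 0.1  # crossing only 0.1 s after the segment start
        idx = _crossings(sig, np.ones(300, bool), 0.5, 20, "down")
        assert list(idx) == [10]


# ----------------------------------------------------------------------
# event-set structure
# ----------------------------------------------------------------------

@pytest.mark.parametrize("method", METHODS)
def test_event_times_strictly_increasing_and_separated(sw_walk, method):
    trial, _, kin = sw_walk
    events = detect_events(trial, method, kin=kin)
    events.validate(min_separation=0.0)
    for side in ("L", "R"):
        for typ in ("IC", "FC"):
            t = events.times(side, typ)
            if t.size > 1:
                assert np.diff(t).min() >= 0.2 - 1e-9


def test_time_shift_equivariance(sw_walk):
    """Shifting the whole recording in time shifts every event exactly."""
    trial, _, kin = sw_walk
    shifted = MarkerTrialData("shift", trial.sampling_rate, trial.time + 5.0,
                              trial.trajectories, trial.valid_mask)
    base = detect_events(trial, "M5", kin=kin)
    moved = detect_events(shifted, "M5")
    np.testing.assert_allclose(moved.times(), base.times() + 5.0, atol=1e-9)


def test_rigid_translation_invariance_m1(sw_walk):
    trial, _, kin = sw_walk
    moved = trial.copy()
    for m in moved.trajectories:
        moved.trajectories[m] = moved.trajectories[m] + np.array([10., -4., 2.])
    base = detect_events(trial, "M1", kin=kin)
    shifted = detect_events(moved, "M1")
    np.testing.assert_allclose(shifted.times(), base.times(), atol=1e-9)


# ----------------------------------------------------------------------
# walking speed
# ----------------------------------------------------------------------

class TestWalkingSpeed:
    def test_recovers_simulated_speed(self, sw_walk):
        trial, truth, kin = sw_walk
        ws = estimate_walking_speed(trial, kin)
        assert ws == pytest.approx(truth.walking_speed, abs=0.05)

    def test_scales_with_playback_speed(self):
        slow = SyntheticGaitSpec(n_strides=8, stride_duration=1.2,
                                 stride_length=1.2, seed=2)
        fast = SyntheticGaitSpec(n_strides=8, stride_duration=0.6,
                                 stride_length=1.2, seed=2)
        ws_slow = estimate_walking_speed(simulate_trial(slow)[0])
        ws_fast = estimate_walking_speed(simulate_trial(fast)[0])
        assert ws_fast == pytest.approx(2 * ws_slow, rel=0.05)

    def test_single_ic_raises(self):
        trial, _ = simulate_trial(SyntheticGaitSpec(n_strides=1, seed=0))
        # keep only the first second: at most one IC per side
        keep = trial.time <= 2.3
        short = MarkerTrialData(
            "short", trial.sampling_rate, trial.time[keep],
            {m: v[keep] for m, v in trial.trajectories.items()},
            {m: v[keep] for m, v in trial.valid_mask.items()})
        with pytest.raises(DetectionError):
            estimate_walking_speed(short)


# ----------------------------------------------------------------------
# contact-pattern rules (M5/M7)
# ----------------------------------------------------------------------

class TestVelocity3DRules:
    def test_rearfoot_walk_all_rearfoot(self, sw_walk):
        trial, _, kin = sw_walk
        ics = detect_ic_velocity3d(trial, DetectorParams(), "M5", kin)
        strikes = {e.foot_strike for e in ics}
        assert strikes == {"rearfoot"}

    def test_forefoot_walk_toe_first(self, forefoot_walk):
        trial, truth, kin = forefoot_walk
        ics = detect_ic_velocity3d(trial, DetectorParams(), "M5", kin)
        frac = np.mean([e.foot_strike == "forefoot" for e in ics])
        assert frac >= 0.9
        # and the chosen instants are the toe (not heel) stop instants
        rep = evaluate_events(ics, truth.events, trial.sampling_rate)[0]
        assert rep.mae_s <= 0.02

    def test_stationary_trial_no_events(self):
        n = 600
        t = np.arange(n) / FS
        traj = {m: np.tile([i * 0.1, 0.0, 0.03], (n, 1))
                for i, m in enumerate(("LHEEL", "RHEEL", "LTOE", "RTOE"))}
        trial = MarkerTrialData("still", FS, t, traj)
        assert len(detect_velocity3d(trial, DetectorParams(), "M5")) == 0

    def test_fc_refinement_peak_and_fallback_branches(self):
        """Constructed profiles: a heel-speed peak just before the toe
        crossing moves the contact to the frame after the peak; a second
        crossing with a quiet heel uses the crossing itself."""
        n = 1000
        t = np.arange(n) / FS
        # toe: two acceleration episodes from rest; 1 m/s reached 40 ms in
        toe_v = np.zeros(n)
        for t0 in (1.96, 5.96):
            seg = (t >= t0) & (t < t0 + 0.12)
            toe_v[seg] = 25.0 * (t[seg] - t0)
            tail = (t >= t0 + 0.12) & (t < t0 + 1.0)
            toe_v[tail] = 3.0 * np.exp(-(t[tail] - t0 - 0.12) / 0.2)
        toe_x = np.cumsum(toe_v) / FS
        # heel: a single strong speed peak at 1.98 s (none near 6 s)
        heel_v = 2.0 * np.exp(-((t - 1.98) / 0.03) ** 2)
        heel_x = np.cumsum(heel_v) / FS
        traj = {}
        for side in ("L", "R"):
            traj[f"{side}TOE"] = np.column_stack([toe_x, np.zeros(n), np.full(n, .02)])
            traj[f"{side}HEEL"] = np.column_stack([heel_x, np.zeros(n), np.full(n, .03)])
        trial = MarkerTrialData("fc", FS, t, traj)
        fcs = detect_fc_velocity3d(trial, DetectorParams(), "M5")
        t_fc = fcs.times("R", "FC")
        assert t_fc.size == 2
        # branch 1: instant after the ~1.98 s heel peak, i.e. before the
        # toe crossing (~2.00 s)
        assert 1.97 <= t_fc[0] <= 2.00
        # branch 2: no heel peak in the window -> the crossing itself
        assert t_fc[1] == pytest.approx(6.00, abs=0.015)


# ----------------------------------------------------------------------
# threshold forcing and fusion
# ----------------------------------------------------------------------

class TestEquivalences:
    def test_m7_equals_m5_with_forced_thresholds(self, sw_walk):
        trial, _, kin = sw_walk
        ic5 = detect_ic_velocity3d(trial, DetectorParams(), "M5", kin)
        ic7 = detect_ic_velocity3d(
            trial, DetectorParams(walking_speed=1.0, th_toe_ic=0.5), "M7", kin)
        assert [(e.time, e.side, e.foot_strike) for e in ic5] == \
               [(e.time, e.side, e.foot_strike) for e in ic7]
        fc5 = detect_fc_velocity3d(trial, DetectorParams(), "M5", kin)
        fc7 = detect_fc_velocity3d(
            trial, DetectorParams(walking_speed=1.25), "M7", kin)
        assert [(e.time, e.side) for e in fc5] == [(e.time, e.side) for e in fc7]

    def test_m6_ic_equals_m4_ic_with_forced_speed(self, sw_walk):
        trial, _, kin = sw_walk
        m4 = detect_sagittal_velocity(trial, params=DetectorParams(),
                                      method="M4", kin=kin)
        m6 = detect_sagittal_velocity(
            trial, params=DetectorParams(walking_speed=0.5 / 0.78),
            method="M6", kin=kin)
        assert list(m4.times(type="IC")) == list(m6.times(type="IC"))

    def test_m6_without_walking_speed_is_fatal(self, sw_walk):
        trial, _, kin = sw_walk
        with pytest.raises(DetectionError):
            detect_sagittal_velocity(trial, params=DetectorParams(),
                                     method="M6", kin=kin)


class TestM10:
    def test_uses_m7_timing_where_anchored(self, sw_walk):
        trial, _, kin = sw_walk
        ws = estimate_walking_speed(trial, kin)
        m7 = detect_velocity3d(trial, DetectorParams(walking_speed=ws), "M7", kin)
        m10 = detect_m10(trial, kin=kin)
        t7 = set(np.round(m7.times(), 6))
        assert all(round(e.time, 6) in t7 for e in m10)

    def test_pelvis_occlusion_falls_back_to_m7(self, corpus):
        trial, _ = corpus["pelvis_occluded"]
        kin = Kinematics(trial)
        ws = estimate_walking_speed(trial, kin)
        m7 = detect_velocity3d(trial, DetectorParams(walking_speed=ws),
                               "M7", kin).with_method("M10")
        assert detect_m10(trial, kin=kin) == m7

    def test_unanchored_m7_events_are_discarded(self, sw_walk):
        """With the match window shrunk to (near) zero, only M1 events — or
        M7 events exactly coincident with them — survive the fusion, so
        spurious M7 crossings away from an M1 anchor never reach the output."""
        trial, _, kin = sw_walk
        m1 = detect_events(trial, "M1", kin=kin)
        m10 = detect_m10(trial, params=DetectorParams(m10_match_window=1e-6),
                         kin=kin)
        np.testing.assert_allclose(m10.times(), m1.times(), atol=1e-6)
        # default window: every fused event stays anchored to an M1 event
        m10_def = detect_m10(trial, kin=kin)
        for e in m10_def:
            anchors = m1.times(e.side, e.type)
            assert np.min(np.abs(anchors - e.time)) <= 0.25 + 1e-9


# ----------------------------------------------------------------------
# performance sanity of the literature methods on clean gait
# ----------------------------------------------------------------------

@pytest.mark.parametrize("method,min_s", [
    ("M1", 1.0), ("M2", 0.95), ("M3", 0.95), ("M8", 0.95), ("M9", 0.95)])
def test_literature_methods_find_each_cycle(sw_walk, method, min_s):
    trial, truth, kin = sw_walk
    events = detect_events(trial, method, kin=kin)
    for rep in evaluate_events(events, truth.events, trial.sampling_rate,
                               method=method):
        if rep.condition == "SW":
            assert rep.sensitivity is not None and rep.sensitivity >= min_s
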