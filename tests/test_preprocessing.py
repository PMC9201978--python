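"""Signal-processing contracts: gap filling, zero-lag filtering,
differentiation, pelvis frames and component decomposition."""

import numpy as np
import pytest

from gaitevents import (MarkerTrialData, build_pelvis_frames, decompose,
                        differentiate, estimate_vertical, fill_gaps,
                        lowpass_filter)
from gaitevents.preprocessing import valid_segments

FS = 100.0


def _mk_trial(n=400, pelvis=True, fs=FS):
    t = np.arange(n) / fs
    traj = {}
    for i, name in enumerate(("LHEEL", "RHEEL", "LTOE", "RTOE")):
        traj[name] = np.column_stack([t * 1.2, np.full(n, 0.1 * i), np.full(n, 0.03)])
    if pelvis:
        traj["P0"] = np.column_stack([np.zeros(n), t * 1.2, np.full(n, 1.0)])
        traj["P1"] = np.column_stack([np.full(n, 0.2), t * 1.2, np.full(n, 1.0)])
        traj["P3"] = np.column_stack([np.full(n, 0.1), t * 1.2, np.full(n, 0.8)])
    return MarkerTrialData("t", fs, t, traj)


class TestFillGaps:
    def test_short_interior_gap_is_spline_filled(self):
        trial = _mk_trial()
        # quadratic track so the cubic spline reconstructs it exactly
        trial.trajectories["LHEEL"][:, 0] = (np.arange(400) / FS) ** 2
        truth = trial.trajectories["LHEEL"].copy()
        trial.trajectories["LHEEL"][100:130] = np.nan
        trial.valid_mask["LHEEL"][100:130] = False
        out = fill_gaps(trial, max_gap=0.5)
        assert out.valid_mask["LHEEL"].all()
        np.testing.assert_allclose(out.trajectories["LHEEL"][100:130],
                                   truth[100:130], atol=1e-9)

    def test_long_gap_untouched(self):
        trial = _mk_trial()
        trial.trajectories["LHEEL"][100:160] = np.nan  # 0.6 s >= 0.5 s
        trial.valid_mask["LHEEL"][100:160] = False
        out = fill_gaps(trial, max_gap=0.5)
        assert not out.valid_mask["LHEEL"][100:160].any()

    def test_leading_gap_untouched_and_identity_without_gaps(self):
        trial = _mk_trial()
        trial.trajectories["RTOE"][:20] = np.nan
        trial.valid_mask["RTOE"][:20] = False
        out = fill_gaps(trial)
        assert not out.valid_mask["RTOE"][:20].any()
        np.testing.assert_array_equal(out.trajectories["LHEEL"],
                                      trial.trajectories["LHEEL"])


class TestLowpass:
    def test_dc_gain_is_one(self):
        x = np.full(500, 3.7)
        np.testing.assert_allclose(lowpass_filter(x, FS), x, atol=1e-9)

    def test_half_power_at_cutoff(self):
        # forward-backward 4th-order Butterworth: |H|^2 = 1/2 at 7 Hz
        t = np.arange(3000) / FS
        x = np.sin(2 * np.pi * 7.0 * t)
        y = lowpass_filter(x, FS, cutoff=7.0)
        core = slice(500, 2500)
        ratio = np.max(np.abs(y[core])) / np.max(np.abs(x[core]))
        assert ratio == pytest.approx(0.5, rel=0.05)

    def test_time_reversal_symmetry(self):
        # forward-backward filtering is its own time reverse away from the
        # padded edges
        rng = np.random.default_rng(0)
        x = np.cumsum(rng.normal(size=600))
        rev = lowpass_filter(x[::-1], FS)[::-1]
        fwd = lowpass_filter(x, FS)
        np.testing.assert_allclose(rev[50:-50], fwd[50:-50], atol=1e-5)

    def test_short_segment_left_unfiltered(self):
        x = np.sin(np.arange(20))
        with pytest.warns(UserWarning):
            y = lowpass_filter(x, FS)
        np.testing.assert_array_equal(x, y)


class TestDifferentiate:
    def test_linear_ramp_exact(self):
        t = np.arange(100) / FS
        v, mask = differentiate(1.2 * t, FS)
        assert mask.all()
        np.testing.assert_allclose(v, 1.2, atol=1e-9)

    def test_quadratic_exact_in_interior(self):
        t = np.arange(200) / FS
        v, _ = differentiate(t ** 2, FS)
        np.testing.assert_allclose(v[1:-1], 2 * t[1:-1], atol=1e-9)

    def test_constant_zero_and_short_segment_invalid(self):
        v, mask = differentiate(np.full(50, 2.0), FS)
        np.testing.assert_allclose(v, 0.0, atol=1e-12)
        v2, mask2 = differentiate(np.ones(2), FS)
        assert not mask2.any()

    def test_sinusoid_matches_truncation_bound(self):
        f = 2.0
        t = np.arange(400) / FS
        v, _ = differentiate(np.sin(2 * np.pi * f * t), FS)
        err = np.abs(v[1:-1] - 2 * np.pi * f * np.cos(2 * np.pi * f * t[1:-1]))
        bound = (2 * np.pi * f) ** 3 / (6 * FS ** 2)
        assert err.max() <= bound * 1.01


class TestPelvisFrames:
    def test_axis_aligned_configuration(self):
        trial = _mk_trial()  # advancing +y, P0->P1 along +x
        frames = build_pelvis_frames(trial)
        i = 200
        np.testing.assert_allclose(frames.ml[i], [1, 0, 0], atol=1e-9)
        np.testing.assert_allclose(frames.ap[i], [0, 1, 0], atol=1e-9)
        np.testing.assert_allclose(frames.v[i], [0, 0, 1], atol=1e-9)
        np.testing.assert_allclose(frames.origin[i],
                                   [0.1, trial.time[i] * 1.2, 1.0], atol=1e-6)

    def test_orthonormal_wherever_valid(self, sw_walk):
        _, _, kin = sw_walk
        f = kin.frames
        v = f.valid
        for a in (f.ml[v], f.ap[v], f.v[v]):
            np.testing.assert_allclose(np.linalg.norm(a, axis=1), 1.0, atol=1e-9)
        assert np.abs(np.einsum("ij,ij->i", f.ml[v], f.ap[v])).max() < 1e-9
        assert np.abs(np.einsum("ij,ij->i", f.ap[v], f.v[v])).max() < 1e-9

    def test_occluded_pelvis_invalid_everywhere(self):
        trial = _mk_trial()
        for m in ("P0", "P1", "P3"):
            trial.trajectories[m][:] = np.nan
            trial.valid_mask[m][:] = False
        frames = build_pelvis_frames(trial)
        assert not frames.valid.any()

    def test_rigid_rotation_rotates_axes(self):
        trial = _mk_trial()
        frames = build_pelvis_frames(trial)
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        rot = trial.copy()
        for m in rot.trajectories:
            rot.trajectories[m] = rot.trajectories[m] @ R.T
        frames_rot = build_pelvis_frames(rot)
        i = 150
        for a, b in ((frames.ml, frames_rot.ml), (frames.ap, frames_rot.ap),
                     (frames.v, frames_rot.v)):
            np.testing.assert_allclose(R @ a[i], b[i], atol=1e-6)

    def test_collinear_cluster_invalid(self):
        trial = _mk_trial()
        trial.trajectories["P3"] = 0.5 * (trial.trajectories["P0"]
                                          + trial.trajectories["P1"])
        frames = build_pelvis_frames(trial)
        assert not frames.valid.any()


class TestDecompose:
    def test_marker_ahead_of_origin(self):
        trial = _mk_trial()
        frames = build_pelvis_frames(trial)
        n = trial.n_frames
        pos = frames.origin + np.array([0.0, 0.3, 0.0])
        ap, ml, v = decompose("X", pos, np.ones(n, bool), frames)
        i = 100
        assert ap.values[i] == pytest.approx(0.3, abs=1e-9)
        assert ml.values[i] == pytest.approx(0.0, abs=1e-9)
        assert v.values[i] == pytest.approx(0.0, abs=1e-9)

    def test_translation_invariance(self):
        trial = _mk_trial()
        shifted = trial.copy()
        for m in shifted.trajectories:
            shifted.trajectories[m] = shifted.trajectories[m] + np.array([3., -2., 5.])
        for tr in (trial, shifted):
            frames = build_pelvis_frames(tr)
            ap, _, _ = decompose("LHEEL", tr.trajectories["LHEEL"],
                                 tr.valid_mask["LHEEL"], frames)
            if tr is trial:
                base = ap.values.copy()
        np.testing.assert_allclose(ap.values, base, atol=1e-9)


def test_filter_then_differentiate_recovers_inband_velocity(sw_walk):
    """For a trajectory whose spectrum lies inside the 7 Hz pass band
    (the pelvis marker), filtering then differentiating recovers the raw
    finite-difference velocity within 2% RMS away from the edges.  (Foot
    markers carry contact transients above the band, which the filter is
    *supposed* to attenuate.)"""
    trial, _, kin = sw_walk
    vel, _ = kin.derivative("P0", 1)
    raw = np.gradient(trial.trajectories["P0"], 1 / trial.sampling_rate, axis=0)
    core = slice(50, -50)
    num = np.linalg.norm(vel[core] - raw[core])
    den = np.linalg.norm(raw[core])
    assert num / den < 0.02


def test_estimate_vertical_foot_only_fallback(sw_walk):
    trial, _, _ = sw_walk
    stripped = MarkerTrialData(
        "nopelvis", trial.sampling_rate, trial.time,
        {m: trial.trajectories[m] for m in ("LHEEL", "RHEEL", "LTOE", "RTOE")})
    up = estimate_vertical(stripped)
    assert up @ np.array([0, 0, 1.0]) > 0.99


def test_valid_segments_roundtrip():
    mask = np.array([0, 1, 1, 0, 0, 1, 0, 1, 1, 1], bool)
    assert valid_segments(mask) == [(1, 3), (5, 6), (7, 10)]
    assert valid_segments(np.zeros(4, bool)) == []
    assert valid_segments(np.ones(4, bool)) == [(0, 4)]
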