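"""Synthetic gait-trajectory simulator with exact ground-truth events.

The simulator generates the eight-marker gait set (bilateral HEEL/TOE
plus the P0..P3 pelvis cluster) for walks that may include smooth yaw
turns (e.g. 180-degree U-turns) and step negotiation (a smooth change of
ground level along the path), with optional additive marker noise and
occlusion spans.

Foot model.  Contact is stationarity: while a foot is on the ground its
markers do not move.  For a rearfoot (heel-first) pattern the heel is
fixed from the initial contact until heel-off and the toe from toe-down
until the final contact (heel-then-toe rocker); a forefoot pattern swaps
the landing order (toe lands first and is below the heel at landing).
During swing, markers travel along the chord between footfalls with a
cosine-ramped velocity profile — near-constant speed in mid-swing, a
ballistic ~30 ms acceleration at swing onset (push-off) and a slower
~60 ms controlled deceleration before landing — plus a raised-cosine
vertical clearance hump for the heel and a two-hump clearance profile
for the toe.  Ground-truth events are the exact (frame-aligned)
stationarity boundaries: IC = first stationary frame of the striking
marker, FC = last stationary frame of the toe.  Ground truth is recorded
before noise/occlusions are applied and is never perturbed.

Footfalls are placed by arc length along a centreline whose heading
follows the prescribed turns (raised-cosine yaw-rate profile), so every
stride of a straight walk has exactly the nominal length.  The pelvis
centre is the stride-period moving average of the foot markers (which
starts and stops smoothly by construction) plus small physiological
AP/ML/V oscillations; the rigid cluster yaws with the heading.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .conditions import (CW_DURATION_S, SN_HEIGHT_M, YAW_RATE_MIN_DEG_S,
                         YAW_TOTAL_MIN_DEG, ConditionSegment, label_events)
from .detectors import GaitEvent, GaitEventSet
from .strides import STRIDE_COLUMNS
from .trial import MarkerTrialData


@dataclass(frozen=True)
class TurnSpec:
    angle_deg: float
    start_s: float
    duration_s: float


@dataclass(frozen=True)
class StepSpec:
    height_m: float
    position_m: float       # along-path location of the level change
    transition_m: float = 0.30


@dataclass(frozen=True)
class OcclusionSpec:
    marker: str             # marker name, or "PELVIS" for the whole cluster
    start_s: float
    duration_s: float


@dataclass
class SyntheticGaitSpec:
    """Parameters of one simulated walking trial (per-side stride counts)."""

    sampling_rate: float = 100.0
    n_strides: int = 10
    stride_length: float = 1.32
    stride_duration: float = 1.1
    stance_fraction: float = 0.62
    foot_strike: str = "rearfoot"     # rearfoot | forefoot | mixed
    turns: tuple[TurnSpec, ...] = ()
    steps: tuple[StepSpec, ...] = ()
    noise_sd: float = 0.0             # meters, i.i.d. Gaussian per coordinate
    occlusions: tuple[OcclusionSpec, ...] = ()
    seed: int = 0

    # timing of the foot rocker (fractions of the stride duration)
    heel_off_fraction: float = 0.45   # heel rise in terminal stance
    toe_down_fraction: float = 0.08   # forefoot loading after a heel strike
    heel_down_fraction: float = 0.08  # heel drop after a forefoot strike

    # geometry (meters)
    step_width: float = 0.20
    foot_length: float = 0.15
    heel_marker_height: float = 0.03
    toe_marker_height: float = 0.02
    pelvis_height: float = 0.95

    # swing shape: onset (push-off/lift) is ballistic, landing is a slower
    # controlled deceleration — reproduces the near-zero detection bias of
    # velocity-threshold methods observed on real foot-marker data
    swing_ramp_on_s: float = 0.03     # swing-onset acceleration time
    swing_ramp_off_s: float = 0.06    # terminal-swing deceleration time
    heel_clearance_m: float = 0.12
    toe_clearance_m: tuple[float, float] = (0.05, 0.04)

    # context
    lead_in_s: float = 1.0
    lead_out_s: float = 1.0
    pelvis_osc_m: tuple[float, float, float] = (0.01, 0.025, 0.02)  # AP, ML, V

    def validate(self) -> None:
        if not (0.5 < self.stance_fraction < 0.8):
            raise ValueError("stance_fraction must lie in (0.5, 0.8)")
        for v in (self.sampling_rate, self.stride_length, self.stride_duration,
                  self.lead_in_s, self.lead_out_s):
            if v <= 0:
                raise ValueError("durations, lengths and rates must be positive")
        if self.n_strides < 1:
            raise ValueError("need at least one stride per side")
        if self.foot_strike not in ("rearfoot", "forefoot", "mixed"):
            raise ValueError(f"unknown foot_strike {self.foot_strike!r}")
        walk0, walk1 = self.walk_window()
        for t in self.turns:
            if t.start_s < walk0 - 1e-9 or t.start_s + t.duration_s > walk1 + 1e-9:
                raise ValueError("turn lies outside the walking interval")
        for s in self.steps:
            if not (0.0 < s.position_m < self.total_arc_length()):
                raise ValueError("step lies outside the walked path")

    # -- derived timing -----------------------------------------------
    def walk_window(self) -> tuple[float, float]:
        walk_dur = (self.n_strides + 1.5) * self.stride_duration
        return self.lead_in_s, self.lead_in_s + walk_dur

    def total_arc_length(self) -> float:
        return (self.n_strides + 1.5) * self.stride_length

    def total_duration(self) -> float:
        return self.walk_window()[1] + self.lead_out_s

    @property
    def mean_speed(self) -> float:
        return self.stride_length / self.stride_duration


@dataclass
class GroundTruth:
    """Exact events, condition segments and analytic stride parameters."""

    events: GaitEventSet
    segments: list[ConditionSegment]
    strides: pd.DataFrame
    walking_speed: float
    spec: SyntheticGaitSpec = field(repr=False, default=None)


# ----------------------------------------------------------------------
# shape primitives
# ----------------------------------------------------------------------

def _raised_cosine_step(u: np.ndarray) -> np.ndarray:
    """Smooth 0->1 transition with a raised-cosine rate (zero end slopes)."""
    u = np.clip(u, 0.0, 1.0)
    return u - np.sin(2 * np.pi * u) / (2 * np.pi)


def _scurve(u: np.ndarray, alpha_on: float, alpha_off: float) -> np.ndarray:
    """Normalized displacement of a cosine-ramped velocity profile.

    Velocity ramps up over a fraction ``alpha_on`` of the swing, holds a
    plateau, and ramps down over ``alpha_off``; displacement runs 0 -> 1.
    """
    a = float(np.clip(alpha_on, 0.02, 0.45))
    b = float(np.clip(alpha_off, 0.02, 0.45))
    u = np.clip(u, 0.0, 1.0)
    raw = np.empty_like(u)
    lo = u < a
    hi = u > 1.0 - b
    mid = ~lo & ~hi
    raw[lo] = 0.5 * (u[lo] - (a / np.pi) * np.sin(np.pi * u[lo] / a))
    raw[mid] = 0.5 * a + (u[mid] - a)
    x = u[hi] - (1.0 - b)
    raw[hi] = 0.5 * a + (1.0 - a - b) + 0.5 * (
        x + (b / np.pi) * np.sin(np.pi * x / b))
    return raw / (1.0 - 0.5 * (a + b))


def _bump(u: np.ndarray, center: float, width: float) -> np.ndarray:
    """Compactly supported cos^2 bump of unit height."""
    x = (u - center) / width
    out = np.where(np.abs(x) <= 0.5, np.cos(np.pi * x) ** 2, 0.0)
    return out


# ----------------------------------------------------------------------
# trial synthesis
# ----------------------------------------------------------------------

def _heading(spec: SyntheticGaitSpec, t: np.ndarray) -> np.ndarray:
    """Heading angle (rad) at each time stamp."""
    psi = np.zeros_like(t)
    for turn in spec.turns:
        u = (t - turn.start_s) / turn.duration_s
        psi += np.radians(turn.angle_deg) * _raised_cosine_step(u)
    return psi


def _ground_height(spec: SyntheticGaitSpec, d: np.ndarray) -> np.ndarray:
    """Ground level (m) as a function of arc distance along the path."""
    g = np.zeros_like(d)
    for step in spec.steps:
        u = (d - (step.position_m - step.transition_m / 2)) / step.transition_m
        g += step.height_m * _raised_cosine_step(u)
    return g


def _track(time: np.ndarray, points: np.ndarray, starts: np.ndarray,
           ends: np.ndarray, ramp_on_s: float, ramp_off_s: float,
           clearance: "callable") -> np.ndarray:
    """Piecewise trajectory: stationary at ``points[k]`` on
    [starts[k], ends[k]], cosine-ramped swing along the chord between
    consecutive points with an added vertical clearance profile."""
    eps = 1e-9
    pos = np.empty((time.size, 3))
    pos[time <= starts[0] + eps] = points[0]
    for k in range(len(points)):
        pos[(time >= starts[k] - eps) & (time <= ends[k] + eps)] = points[k]
        if k + 1 == len(points):
            pos[time >= ends[k] - eps] = points[k]
            break
        m = (time > ends[k] + eps) & (time < starts[k + 1] - eps)
        dur = starts[k + 1] - ends[k]
        u = (time[m] - ends[k]) / dur
        s = _scurve(u, ramp_on_s / dur, ramp_off_s / dur)
        pos[m] = points[k] + s[:, None] * (points[k + 1] - points[k])
        pos[m, 2] += clearance(u)
    return pos


def simulate_trial(spec: SyntheticGaitSpec) -> tuple[MarkerTrialData, GroundTruth]:
    """Generate one trial and its exact ground truth.

    Identical specs (including the seed) produce bit-identical output.
    """
    spec.validate()
    fs = spec.sampling_rate
    T = spec.stride_duration
    L = spec.stride_length
    snap = lambda x: round(x * fs) / fs  # noqa: E731

    n_frames = int(round(spec.total_duration() * fs)) + 1
    time = np.arange(n_frames) / fs
    rng = np.random.default_rng(spec.seed)

    # --- path geometry -------------------------------------------------
    psi = _heading(spec, time)
    # inclusive right edge: the final footfall lands exactly at walk end
    v_walk = np.where((time >= spec.lead_in_s - 1e-9)
                      & (time <= spec.walk_window()[1] + 1e-9),
                      spec.mean_speed, 0.0)
    d_arc = np.concatenate(([0.0], np.cumsum(0.5 * (v_walk[1:] + v_walk[:-1]) / fs)))
    heading_xy = np.column_stack([np.cos(psi), np.sin(psi)])
    center_xy = np.concatenate(
        ([[0.0, 0.0]],
         np.cumsum(0.5 * (v_walk[1:, None] * heading_xy[1:]
                          + v_walk[:-1, None] * heading_xy[:-1]) / fs, axis=0)))

    # --- footfalls -------------------------------------------------------
    n_foot = spec.n_strides + 2  # footfall indices 0 .. n_strides+1
    footfalls: dict[str, dict[str, np.ndarray]] = {}
    strikes: dict[str, list[str]] = {}
    for side, offset in (("R", 0.0), ("L", 0.5)):
        t_nom = spec.lead_in_s + (np.arange(n_foot) + offset) * T
        t_snap = np.array([snap(t) for t in t_nom])
        idx = np.array([int(round(t * fs)) for t in t_snap])
        d_heel = d_arc[idx]
        heading_k = psi[idx]
        right = np.column_stack([np.sin(heading_k), -np.cos(heading_k)])
        lateral = (spec.step_width / 2) * (right if side == "R" else -right)
        heel_xy = center_xy[idx] + lateral
        toe_xy = heel_xy + spec.foot_length * heading_xy[idx]
        heel_z = _ground_height(spec, d_heel) + spec.heel_marker_height
        toe_z = _ground_height(spec, d_heel + spec.foot_length) + spec.toe_marker_height
        if spec.foot_strike == "mixed":
            strike = ["rearfoot" if k % 2 == 0 else "forefoot" for k in range(n_foot)]
        else:
            strike = [spec.foot_strike] * n_foot
        footfalls[side] = {
            "t": t_snap,
            "heel": np.column_stack([heel_xy, heel_z]),
            "toe": np.column_stack([toe_xy, toe_z]),
        }
        strikes[side] = strike

    # --- marker trajectories --------------------------------------------
    h1, h2 = spec.toe_clearance_m
    heel_clear = lambda u: spec.heel_clearance_m * np.sin(np.pi * u) ** 2  # noqa: E731
    toe_clear = lambda u: h1 * _bump(u, 0.18, 0.36) + h2 * _bump(u, 0.78, 0.40)  # noqa: E731

    trajectories: dict[str, np.ndarray] = {}
    t_end = time[-1]
    for side in ("R", "L"):
        ff = footfalls[side]
        strike = strikes[side]
        heel_starts, heel_ends, toe_starts, toe_ends = [], [], [], []
        for k in range(n_foot):
            fk = ff["t"][k]
            hs = fk if strike[k] == "rearfoot" else snap(fk + spec.heel_down_fraction * T)
            ts = fk if strike[k] == "forefoot" else snap(fk + spec.toe_down_fraction * T)
            heel_starts.append(0.0 if k == 0 else hs)
            toe_starts.append(0.0 if k == 0 else ts)
            heel_ends.append(t_end if k == n_foot - 1 else snap(fk + spec.heel_off_fraction * T))
            toe_ends.append(t_end if k == n_foot - 1 else snap(fk + spec.stance_fraction * T))
        trajectories[f"{side}HEEL"] = _track(
            time, ff["heel"], np.array(heel_starts), np.array(heel_ends),
            spec.swing_ramp_on_s, spec.swing_ramp_off_s, heel_clear)
        trajectories[f"{side}TOE"] = _track(
            time, ff["toe"], np.array(toe_starts), np.array(toe_ends),
            spec.swing_ramp_on_s, spec.swing_ramp_off_s, toe_clear)

    # --- pelvis cluster ---------------------------------------------------
    centroid = np.mean([trajectories[m] for m in
                        ("LHEEL", "RHEEL", "LTOE", "RTOE")], axis=0)
    win = max(3, int(round(T * fs)) | 1)  # odd, one stride period
    pelvis_center = uniform_filter1d(centroid, size=win, axis=0, mode="nearest")
    pelvis_center = pelvis_center + np.array([0.0, 0.0, spec.pelvis_height
                                              - spec.heel_marker_height])
    a_ap, a_ml, a_v = spec.pelvis_osc_m
    walk0, walk1 = spec.walk_window()
    env = np.clip((time - walk0) / 0.5, 0, 1) * np.clip((walk1 - time) / 0.5, 0, 1)
    phase = 2 * np.pi * (time - walk0) / T
    forward3 = np.column_stack([heading_xy, np.zeros(n_frames)])
    right3 = np.column_stack([np.sin(psi), -np.cos(psi), np.zeros(n_frames)])
    up3 = np.array([0.0, 0.0, 1.0])
    pelvis_center = (pelvis_center
                     + (a_ap * env * np.sin(2 * phase))[:, None] * forward3
                     + (a_ml * env * np.sin(phase))[:, None] * right3
                     + (a_v * env * np.sin(2 * phase))[:, None] * up3)
    cluster_local = {  # (right, forward, up) offsets, meters
        "P0": (-0.10, -0.08, 0.00),
        "P1": (+0.10, -0.08, 0.00),
        "P2": (0.00, -0.08, +0.06),
        "P3": (0.00, -0.08, -0.08),
    }
    for name, (r, f, u) in cluster_local.items():
        trajectories[name] = pelvis_center + r * right3 + f * forward3 + u * up3

    # --- ground truth (before noise/occlusion) ----------------------------
    events: list[GaitEvent] = []
    for side in ("R", "L"):
        ff, strike = footfalls[side], strikes[side]
        for k in range(1, n_foot):
            t_ic = ff["t"][k]
            events.append(GaitEvent(time=float(t_ic), frame=int(round(t_ic * fs)),
                                    side=side, type="IC", foot_strike=strike[k],
                                    method="truth"))
        for k in range(n_foot - 1):
            t_fc = snap(ff["t"][k] + spec.stance_fraction * T)
            events.append(GaitEvent(time=float(t_fc), frame=int(round(t_fc * fs)),
                                    side=side, type="FC", method="truth"))
    gt_events = GaitEventSet(events)

    segments: list[ConditionSegment] = []
    for turn in spec.turns:
        peak_rate = 2.0 * abs(turn.angle_deg) / turn.duration_s
        if (abs(turn.angle_deg) >= YAW_TOTAL_MIN_DEG
                and peak_rate >= YAW_RATE_MIN_DEG_S
                and CW_DURATION_S[0] <= turn.duration_s <= CW_DURATION_S[1]):
            segments.append(ConditionSegment(
                label="CW", start=turn.start_s, end=turn.start_s + turn.duration_s,
                total_yaw_deg=turn.angle_deg, peak_yaw_rate_deg_s=peak_rate))
    for side in ("R", "L"):
        ff = footfalls[side]
        z = ff["heel"][:, 2]
        for k in range(1, n_foot - 1):
            dz = z[k + 1] - z[k]
            if abs(dz) > SN_HEIGHT_M:
                segments.append(ConditionSegment(
                    label="SN", start=float(ff["t"][k]), end=float(ff["t"][k + 1]),
                    height_change_m=float(dz), side=side))
    segments.sort(key=lambda s: s.start)
    gt_events = label_events(gt_events, segments)

    rows = []
    for side in ("R", "L"):
        ff = footfalls[side]
        ic_cond = {e.time: e.condition for e in gt_events.select(side, "IC")}
        for k in range(1, n_foot - 1):
            t0, t1 = float(ff["t"][k]), float(ff["t"][k + 1])
            t_fc = snap(ff["t"][k] + spec.stance_fraction * T)
            length = float(np.linalg.norm(ff["heel"][k + 1, :2] - ff["heel"][k, :2]))
            labels = {ic_cond.get(t0, "SW"), ic_cond.get(t1, "SW")}
            cond = "SN" if "SN" in labels else ("CW" if "CW" in labels else "SW")
            rows.append({
                "trial_id": "", "method": "truth", "side": side,
                "t_ic_start": t0, "t_fc": float(t_fc), "t_ic_end": t1,
                "duration_s": t1 - t0, "stance_s": float(t_fc) - t0,
                "swing_s": t1 - float(t_fc), "length_m": length,
                "speed_mps": length / (t1 - t0), "condition": cond,
            })
    gt_strides = pd.DataFrame(rows, columns=["trial_id", "method", *STRIDE_COLUMNS])

    truth = GroundTruth(events=gt_events, segments=segments, strides=gt_strides,
                        walking_speed=spec.mean_speed, spec=spec)

    # --- degradation -------------------------------------------------------
    valid = {name: np.ones(n_frames, dtype=bool) for name in trajectories}
    if spec.noise_sd > 0:
        for name in sorted(trajectories):
            trajectories[name] = trajectories[name] + rng.normal(
                0.0, spec.noise_sd, size=(n_frames, 3))
    for occ in spec.occlusions:
        names = ("P0", "P1", "P2", "P3") if occ.marker.upper() == "PELVIS" \
            else (occ.marker,)
        for name in names:
            i0 = max(0, int(round(occ.start_s * fs)))
            i1 = min(n_frames, int(round((occ.start_s + occ.duration_s) * fs)) + 1)
            trajectories[name][i0:i1] = np.nan
            valid[name][i0:i1] = False

    trial = MarkerTrialData(
        trial_id=f"synthetic-{spec.foot_strike}-{spec.seed}",
        sampling_rate=fs, time=time,
        trajectories=trajectories, valid_mask=valid)
    return trial, truth


# ----------------------------------------------------------------------
# validation corpus
# ----------------------------------------------------------------------

def make_validation_corpus(seed: int = 0, n_strides: int = 10
                           ) -> dict[str, tuple[MarkerTrialData, GroundTruth]]:
    """Deterministic battery of trial archetypes spanning the three walking
    conditions, both contact patterns, three speeds, marker noise and a
    full-trial pelvis occlusion (exercising the fusion detector's fallback)."""
    speeds = {
        "sw_slow": dict(stride_length=1.00, stride_duration=1.25),        # 0.8 m/s
        "sw_comfortable": dict(stride_length=1.32, stride_duration=1.10),  # 1.2 m/s
        "sw_fast": dict(stride_length=1.60, stride_duration=1.00),         # 1.6 m/s
    }
    corpus: dict[str, tuple[MarkerTrialData, GroundTruth]] = {}
    for name, kw in speeds.items():
        corpus[name] = simulate_trial(SyntheticGaitSpec(
            n_strides=n_strides, seed=seed, **kw))

    corpus["forefoot"] = simulate_trial(SyntheticGaitSpec(
        n_strides=n_strides, foot_strike="forefoot", seed=seed))

    uturn = SyntheticGaitSpec(n_strides=max(n_strides, 8), seed=seed)
    mid = 0.5 * sum(uturn.walk_window())
    uturn.turns = (TurnSpec(angle_deg=180.0, start_s=round(mid - 1.0, 2),
                            duration_s=2.0),)
    corpus["uturn"] = simulate_trial(uturn)

    step = SyntheticGaitSpec(n_strides=max(n_strides, 8), seed=seed)
    step.steps = (StepSpec(height_m=0.20, position_m=round(
        step.total_arc_length() / 2, 2)),)
    corpus["step"] = simulate_trial(step)

    corpus["sw_noisy"] = simulate_trial(SyntheticGaitSpec(
        n_strides=n_strides, noise_sd=0.001, seed=seed))

    occl = SyntheticGaitSpec(n_strides=n_strides, seed=seed)
    occl.occlusions = (OcclusionSpec("PELVIS", 0.0, occl.total_duration()),)
    corpus["pelvis_occluded"] = simulate_trial(occl)
    return corpus
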