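"""Walking-condition classification.

Gait events are assigned to one of three strata: straight-line walking
(SW), curvilinear walking (CW) and step negotiation (SN).

CW is identified from the pelvis heading: a segment qualifies when the
net rotation about the vertical reaches 45 degrees with a peak yaw rate
of at least 15 deg/s and a duration between 0.5 and 10 s.  SN is
identified from the heel-marker vertical displacement: a stride whose
consecutive same-side initial contacts differ in heel height by strictly
more than 0.15 m spans a step.  Events inside no segment are SW; where
CW and SN overlap, SN takes precedence (a step negotiated mid-turn is
the rarer, more specific condition).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .detectors import GaitEventSet
from .preprocessing import (Kinematics, PelvisFrameSeries, estimate_vertical,
                            lowpass_filter, differentiate, valid_segments)
from .trial import SIDE_MARKERS, MarkerTrialData

YAW_TOTAL_MIN_DEG = 45.0
YAW_RATE_MIN_DEG_S = 15.0
YAW_RATE_EXTEND_DEG_S = 5.0
CW_DURATION_S = (0.5, 10.0)
CW_MERGE_GAP_S = 0.2
SN_HEIGHT_M = 0.15


@dataclass(frozen=True)
class ConditionSegment:
    """A time interval classified as curvilinear walking or step negotiation."""

    label: str              # CW | SN
    start: float
    end: float
    total_yaw_deg: float | None = None    # CW: net rotation
    peak_yaw_rate_deg_s: float | None = None
    height_change_m: float | None = None  # SN: signed heel-height change
    side: str | None = None               # SN: which foot crossed the step

    def contains(self, t: float) -> bool:
        return self.start <= t <= self.end


def pelvis_yaw(frames: PelvisFrameSeries, vertical: np.ndarray,
               sampling_rate: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unwrapped pelvis heading (deg) about the world vertical and its
    smoothed rate (deg/s); returns (yaw, yaw_rate, valid)."""
    up = vertical / np.linalg.norm(vertical)
    # horizontal basis orthogonal to the vertical
    seed = np.array([1.0, 0.0, 0.0])
    if abs(seed @ up) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    e1 = seed - (seed @ up) * up
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(up, e1)
    ap = np.where(np.isfinite(frames.ap), frames.ap, 0.0)
    yaw = np.degrees(np.arctan2(ap @ e2, ap @ e1))
    valid = frames.valid.copy()
    out = np.full(yaw.shape, np.nan)
    for start, stop in valid_segments(valid):
        out[start:stop] = np.degrees(np.unwrap(np.radians(yaw[start:stop])))
    rate, rate_mask = differentiate(out, sampling_rate, valid)
    rate = lowpass_filter(rate, sampling_rate, valid_mask=rate_mask)
    return out, np.where(rate_mask, rate, np.nan), valid


def detect_curvilinear(frames: PelvisFrameSeries, sampling_rate: float,
                       time: np.ndarray,
                       vertical: np.ndarray | None = None) -> list[ConditionSegment]:
    """Detect curvilinear-walking segments from the pelvis heading.

    Cores where |yaw rate| >= 15 deg/s are extended outward until the
    rate falls below 5 deg/s (so the segment covers the full manoeuvre),
    merged across gaps shorter than 0.2 s, and accepted when the net
    rotation is at least 45 degrees and the duration lies in [0.5, 10] s.
    """
    if not frames.any_valid():
        return []
    if vertical is None:
        v = frames.v[frames.valid].mean(axis=0)
        vertical = v / np.linalg.norm(v)
    yaw, rate, valid = pelvis_yaw(frames, vertical, sampling_rate)
    absrate = np.where(np.isfinite(rate), np.abs(rate), 0.0)
    core = valid & (absrate >= YAW_RATE_MIN_DEG_S)
    # extend each core until |rate| < extension threshold
    intervals: list[list[int]] = []
    for start, stop in valid_segments(core):
        lo, hi = start, stop - 1
        while lo > 0 and valid[lo - 1] and absrate[lo - 1] >= YAW_RATE_EXTEND_DEG_S:
            lo -= 1
        while hi + 1 < len(yaw) and valid[hi + 1] and absrate[hi + 1] >= YAW_RATE_EXTEND_DEG_S:
            hi += 1
        intervals.append([lo, hi])
    # merge segments separated by less than the merge gap
    merged: list[list[int]] = []
    for iv in sorted(intervals):
        if merged and (time[iv[0]] - time[merged[-1][1]]) < CW_MERGE_GAP_S:
            merged[-1][1] = max(merged[-1][1], iv[1])
        else:
            merged.append(iv)
    out: list[ConditionSegment] = []
    for lo, hi in merged:
        duration = time[hi] - time[lo]
        total = yaw[hi] - yaw[lo]
        peak = np.nanmax(absrate[lo:hi + 1])
        if (abs(total) >= YAW_TOTAL_MIN_DEG
                and CW_DURATION_S[0] <= duration <= CW_DURATION_S[1]
                and peak >= YAW_RATE_MIN_DEG_S):
            out.append(ConditionSegment(
                label="CW", start=float(time[lo]), end=float(time[hi]),
                total_yaw_deg=float(total), peak_yaw_rate_deg_s=float(peak)))
    return out


def detect_step_negotiation(trial: MarkerTrialData, events: GaitEventSet,
                            kin: Kinematics | None = None) -> list[ConditionSegment]:
    """Detect step-negotiation strides from heel height at initial contacts.

    For each pair of consecutive same-side ICs, the heel vertical position
    difference between the two instants must exceed 0.15 m strictly.
    """
    kin = kin or Kinematics(trial)
    up = kin.vertical
    out: list[ConditionSegment] = []
    for side in ("L", "R"):
        t_ic = events.times(side, "IC")
        if t_ic.size < 2:
            continue
        heel, _ = SIDE_MARKERS[side]
        h, hmask = kin.height(heel)
        idx = np.array([min(max(trial.frame_of(t), 0), trial.n_frames - 1) for t in t_ic])
        heights = h[idx]
        for k in range(len(idx) - 1):
            if not (np.isfinite(heights[k]) and np.isfinite(heights[k + 1])):
                continue
            dz = heights[k + 1] - heights[k]
            if abs(dz) > SN_HEIGHT_M:
                out.append(ConditionSegment(
                    label="SN", start=float(t_ic[k]), end=float(t_ic[k + 1]),
                    height_change_m=float(dz), side=side))
    return sorted(out, key=lambda s: s.start)


def label_events(events: GaitEventSet,
                 segments: list[ConditionSegment]) -> GaitEventSet:
    """Label each event SN, CW or SW.  SN takes precedence over CW; an
    event inside no segment is straight-line walking (SW)."""
    sn = [s for s in segments if s.label == "SN"]
    cw = [s for s in segments if s.label == "CW"]
    labeled = []
    for e in events:
        if any(s.contains(e.time) for s in sn):
            lab = "SN"
        elif any(s.contains(e.time) for s in cw):
            lab = "CW"
        else:
            lab = "SW"
        labeled.append(replace(e, condition=lab))
    return GaitEventSet(labeled)


def classify_trial(trial: MarkerTrialData, events: GaitEventSet,
                   kin: Kinematics | None = None
                   ) -> tuple[GaitEventSet, list[ConditionSegment]]:
    """Full condition pipeline: CW from the pelvis, SN from heel heights
    at the detected ICs, then event labeling."""
    kin = kin or Kinematics(trial)
    segments: list[ConditionSegment] = []
    if trial.has_pelvis and kin.frames.any_valid():
        vertical = estimate_vertical(trial, kin.frames)
        segments += detect_curvilinear(kin.frames, trial.sampling_rate,
                                       trial.time, vertical)
    segments += detect_step_negotiation(trial, events, kin)
    return label_events(events, segments), segments
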