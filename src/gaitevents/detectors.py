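"""Marker-based gait-event detectors.

Ten detectors identify initial contacts (IC, foot touch-down) and final
contacts (FC, toe-off) from bilateral heel/toe marker kinematics:

====== ==============================================================
M1     peaks of heel/toe AP position relative to the pelvis origin
M2     first maximum / last minimum of high-pass-filtered AP positions
M3     extrema of mid-foot vertical velocity with a height gate
M4     sagittal-plane speed thresholds (fixed, 0.5 m/s)
M5     3D speed thresholds (fixed) with rearfoot/forefoot IC rules and
       heel-peak FC refinement
M6     sagittal-plane speed thresholds adaptive to walking speed
M7     3D speed thresholds adaptive to walking speed (as M5 otherwise)
M8     peaks of heel vertical acceleration gated on null jerk
M9     extrema of heel/toe AP acceleration
M10    M1 events refined by the nearest M7 event; falls back to plain
       M7 wherever the pelvis cluster is occluded
====== ==============================================================

All detectors share threshold-crossing semantics: an event fires at the
first sample satisfying the inequality after the signal has spent at
least ``min_event_separation`` seconds (or since the start of the valid
segment) on the other side of the threshold, which debounces chatter
near the threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .preprocessing import Kinematics, PelvisFrameSeries, valid_segments
from .trial import SIDE_MARKERS, MarkerTrialData

METHODS = tuple(f"M{i}" for i in range(1, 11))

#: fixed thresholds (m/s) and walking-speed multipliers from the method table
FIXED_THRESHOLDS = {
    "M4": {"ic_heel": 0.5, "fc_toe": 0.5},
    "M5": {"ic_heel": 0.5, "ic_toe": 0.5, "fc_toe": 1.0},
}
ADAPTIVE_MULTIPLIERS = {
    "M6": {"ic_heel": 0.78, "fc_toe": 0.66},
    "M7": {"ic_heel": 0.5, "ic_toe": 0.8, "fc_toe": 0.8},
}


class DetectionError(RuntimeError):
    """Raised when a detector's preconditions cannot be met."""


# ----------------------------------------------------------------------
# event containers
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class GaitEvent:
    time: float
    frame: int
    side: str                    # L | R
    type: str                    # IC | FC
    foot_strike: str = "unknown"  # rearfoot | forefoot | unknown
    condition: str = "unlabeled"  # SW | CW | SN | unlabeled
    method: str = ""


class GaitEventSet:
    """Ordered collection of gait events with per-(side, type) monotonicity."""

    COLUMNS = ("side", "type", "time_s", "frame", "condition", "foot_strike", "method")

    def __init__(self, events: list[GaitEvent] | None = None):
        self.events: list[GaitEvent] = sorted(events or [], key=lambda e: (e.time, e.side, e.type))

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def __eq__(self, other) -> bool:
        return isinstance(other, GaitEventSet) and self.events == other.events

    def select(self, side: str | None = None, type: str | None = None) -> "GaitEventSet":
        return GaitEventSet([
            e for e in self.events
            if (side is None or e.side == side) and (type is None or e.type == type)
        ])

    def times(self, side: str | None = None, type: str | None = None) -> np.ndarray:
        return np.array([e.time for e in self.select(side, type)], dtype=float)

    def extend(self, other: "GaitEventSet") -> "GaitEventSet":
        return GaitEventSet(self.events + other.events)

    def with_method(self, method: str) -> "GaitEventSet":
        return GaitEventSet([replace(e, method=method) for e in self.events])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.side, e.type, e.time, e.frame, e.condition, e.foot_strike, e.method)
             for e in self.events],
            columns=list(self.COLUMNS),
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "GaitEventSet":
        events = [
            GaitEvent(time=float(r.time_s), frame=int(r.frame), side=str(r.side),
                      type=str(r.type), foot_strike=str(r.foot_strike),
                      condition=str(r.condition), method=str(r.method))
            for r in df.itertuples()
        ]
        return cls(events)

    def validate(self, min_separation: float = 0.0) -> None:
        for side in ("L", "R"):
            for typ in ("IC", "FC"):
                t = self.times(side, typ)
                if np.any(np.diff(t) <= 0):
                    raise ValueError(f"{side}/{typ} event times not strictly increasing")
            t_all = np.sort(self.times(side))
            if min_separation and np.any(np.diff(t_all) < min_separation - 1e-9):
                raise ValueError(f"same-side events closer than {min_separation} s")


@dataclass
class VelocityCandidates:
    """Threshold-crossing candidates for the 3D-velocity detectors."""
    tic_h: np.ndarray  # heel-speed downward crossings (s)
    tic_t: np.ndarray  # toe-speed downward crossings (s)
    tfc_t: np.ndarray  # toe-speed upward crossings (s)


@dataclass
class DetectorParams:
    """Tunable parameters shared by the detectors.

    Explicit ``th_heel`` / ``th_toe_ic`` / ``th_toe_fc`` values (m/s)
    override the method's fixed thresholds or walking-speed multipliers.
    """

    method: str = "M10"
    th_heel: float | None = None
    th_toe_ic: float | None = None
    th_toe_fc: float | None = None
    walking_speed: float | None = None
    fc_window: float = 0.1
    min_event_separation: float = 0.2
    m10_match_window: float = 0.25
    m2_highpass_hz: float = 0.5
    m1_prominence_frac: float = 0.01
    m3_height_factor: float = 1.3
    m3_amplitude_frac: float = 0.25
    fc_peak_prominence_frac: float = 0.05
    accel_prominence_frac: float = 0.1
    jerk_tol_frac: float = 0.05
    cutoff_hz: float = 7.0

    def resolved_thresholds(self, method: str) -> dict[str, float]:
        """Resolve IC/FC speed thresholds (m/s) for an M4-M7 method."""
        if method in FIXED_THRESHOLDS:
            th = dict(FIXED_THRESHOLDS[method])
        elif method in ADAPTIVE_MULTIPLIERS:
            if self.walking_speed is None:
                raise DetectionError(
                    f"{method} uses adaptive thresholds: walking_speed must be set")
            th = {k: m * self.walking_speed
                  for k, m in ADAPTIVE_MULTIPLIERS[method].items()}
        else:
            raise ValueError(f"no velocity thresholds defined for {method}")
        if self.th_heel is not None:
            th["ic_heel"] = self.th_heel
        if self.th_toe_ic is not None and "ic_toe" in th:
            th["ic_toe"] = self.th_toe_ic
        if self.th_toe_fc is not None:
            th["fc_toe"] = self.th_toe_fc
        return th


# ----------------------------------------------------------------------
# crossing / peak primitives
# ----------------------------------------------------------------------

def _crossings(sig: np.ndarray, mask: np.ndarray, threshold: float,
               min_sep_frames: int, direction: str) -> np.ndarray:
    """First-sample threshold crossings with debouncing.

    ``direction='down'`` fires where ``sig < threshold`` after at least
    ``min_sep_frames`` of ``sig >= threshold`` (a run touching the start
    of a valid segment counts as armed); ``'up'`` is symmetric.
    """
    hits: list[int] = []
    for start, stop in valid_segments(mask & np.isfinite(sig)):
        seg = sig[start:stop]
        sat = seg < threshold if direction == "down" else seg > threshold
        run = min_sep_frames  # a run touching the segment start counts as armed
        for i, s in enumerate(sat):
            if s:
                if i > 0 and not sat[i - 1] and run >= min_sep_frames:
                    hits.append(start + i)
                run = 0
            else:
                run += 1
    return np.array(sorted(hits), dtype=int)


def _peaks(sig: np.ndarray, mask: np.ndarray, fs: float,
           min_sep: float, prominence: float | None = None,
           minima: bool = False) -> np.ndarray:
    """Debounced local extrema indices over valid segments."""
    out: list[int] = []
    distance = max(1, int(round(min_sep * fs)))
    for start, stop in valid_segments(mask & np.isfinite(sig)):
        if stop - start < 3:
            continue
        seg = -sig[start:stop] if minima else sig[start:stop]
        idx, _ = find_peaks(seg, distance=distance, prominence=prominence)
        out.extend(start + idx)
    return np.array(sorted(out), dtype=int)


def _enforce_separation(events: list[GaitEvent], min_sep: float) -> list[GaitEvent]:
    """Drop the later of any same-side event pair closer than min_sep."""
    kept: list[GaitEvent] = []
    last: dict[str, float] = {}
    for e in sorted(events, key=lambda e: e.time):
        if e.side in last and e.time - last[e.side] < min_sep - 1e-9:
            continue
        kept.append(e)
        last[e.side] = e.time
    return kept


def _mk_events(trial: MarkerTrialData, idx: np.ndarray, side: str, typ: str,
               method: str, strikes: list[str] | None = None) -> list[GaitEvent]:
    strikes = strikes or ["unknown"] * len(idx)
    return [
        GaitEvent(time=float(trial.time[i]), frame=int(i), side=side, type=typ,
                  foot_strike=fs_, method=method)
        for i, fs_ in zip(idx, strikes)
    ]


# ----------------------------------------------------------------------
# walking-speed estimate (M5-based)
# ----------------------------------------------------------------------

def estimate_walking_speed(trial: MarkerTrialData, kin: Kinematics | None = None,
                           params: DetectorParams | None = None) -> float:
    """Average stride speed over both sides, strides delimited by M5 ICs.

    Stride speed = horizontal heel displacement between consecutive
    same-side ICs divided by the elapsed time.
    """
    kin = kin or Kinematics(trial)
    params = params or DetectorParams()
    ics = detect_ic_velocity3d(trial, params, method="M5", kin=kin)
    speeds: list[float] = []
    up = kin.vertical
    for side in ("L", "R"):
        t = ics.times(side, "IC")
        if t.size < 2:
            continue
        heel = kin.position(SIDE_MARKERS[side][0])
        idx = np.array([trial.frame_of(x) for x in t])
        pos = heel[idx]
        horiz = pos - np.outer(pos @ up, up)
        disp = np.linalg.norm(np.diff(horiz, axis=0), axis=1)
        speeds.extend(disp / np.diff(t))
    if not speeds:
        raise DetectionError(
            "walking speed undefined: fewer than 2 M5 initial contacts per side")
    return float(np.mean(speeds))


# ----------------------------------------------------------------------
# M1 / M2 / M3
# ----------------------------------------------------------------------

def detect_m1(trial: MarkerTrialData, frames: PelvisFrameSeries | None = None,
              params: DetectorParams | None = None,
              kin: Kinematics | None = None) -> GaitEventSet:
    """IC at maxima, FC at minima of foot AP position relative to the pelvis."""
    params = params or DetectorParams()
    kin = kin or Kinematics(trial, cutoff=params.cutoff_hz, frames=frames)
    if not kin.frames.any_valid():
        warnings.warn("M1: no valid pelvis frames; returning empty event set")
        return GaitEventSet()
    events: list[GaitEvent] = []
    for side, (heel, toe) in SIDE_MARKERS.items():
        for marker, typ, minima in ((heel, "IC", False), (toe, "FC", True)):
            vals, mask = kin.relative_ap(marker)
            finite = vals[np.isfinite(vals)]
            if finite.size < 3 or np.ptp(finite) < 1e-9:
                continue
            prom = params.m1_prominence_frac * np.ptp(finite)
            idx = _peaks(vals, mask, kin.fs,
                         params.min_event_separation, prom, minima=minima)
            events += _mk_events(trial, idx, side, typ, "M1")
    return GaitEventSet(_enforce_separation_by_type(events, params.min_event_separation))


def _enforce_separation_by_type(events: list[GaitEvent], min_sep: float) -> list[GaitEvent]:
    kept: list[GaitEvent] = []
    for side in ("L", "R"):
        for typ in ("IC", "FC"):
            sub = [e for e in events if e.side == side and e.type == typ]
            kept += _enforce_separation(sub, min_sep)
    return kept


def detect_m2(trial: MarkerTrialData, params: DetectorParams | None = None,
              kin: Kinematics | None = None) -> GaitEventSet:
    """IC = earlier of the per-cycle maxima of high-pass-filtered heel/toe AP
    positions; FC = later of the corresponding minima."""
    from .preprocessing import highpass_filter

    params = params or DetectorParams()
    kin = kin or Kinematics(trial, cutoff=params.cutoff_hz)
    if not kin.frames.any_valid():
        warnings.warn("M2: no valid pelvis frames; returning empty event set")
        return GaitEventSet()
    events: list[GaitEvent] = []
    pair_window = 0.3  # s, pairing window between heel and toe extrema
    for side, (heel, toe) in SIDE_MARKERS.items():
        sigs = {}
        for marker in (heel, toe):
            vals, mask = kin.relative_ap(marker)
            sigs[marker] = (
                highpass_filter(np.nan_to_num(vals), kin.fs,
                                params.m2_highpass_hz, valid_mask=mask),
                mask,
            )
        for typ, minima, pick in (("IC", False, min), ("FC", True, max)):
            chosen: list[int] = []
            anchor_sig, anchor_mask = sigs[heel] if typ == "IC" else sigs[toe]
            other_sig, other_mask = sigs[toe] if typ == "IC" else sigs[heel]
            prom_a = 0.05 * (np.ptp(anchor_sig[anchor_mask]) or 1.0)
            prom_o = 0.05 * (np.ptp(other_sig[other_mask]) or 1.0)
            pa = _peaks(anchor_sig, anchor_mask, kin.fs,
                        params.min_event_separation, prom_a, minima=minima)
            po = _peaks(other_sig, other_mask, kin.fs,
                        params.min_event_separation, prom_o, minima=minima)
            for i in pa:
                near = po[np.abs(po - i) <= pair_window * kin.fs] if po.size else po
                chosen.append(pick([i, *near]) if near.size else i)
            events += _mk_events(trial, np.array(sorted(set(chosen)), dtype=int),
                                 side, typ, "M2")
    return GaitEventSet(_enforce_separation_by_type(events, params.min_event_separation))


def detect_m3(trial: MarkerTrialData, params: DetectorParams | None = None,
              kin: Kinematics | None = None) -> GaitEventSet:
    """IC/FC at minima/maxima of the mid-foot vertical velocity, with
    candidates rejected when the mid-foot point is too high above its
    stance-phase baseline (mid-swing artefacts)."""
    params = params or DetectorParams()
    kin = kin or Kinematics(trial, cutoff=params.cutoff_hz)
    events: list[GaitEvent] = []
    up = kin.vertical
    for side, (heel, toe) in SIDE_MARKERS.items():
        mask = kin.mask(heel) & kin.mask(toe)
        mid = 0.5 * (kin.position(heel) + kin.position(toe))
        from .preprocessing import differentiate
        vel, vmask = differentiate(mid, kin.fs, mask)
        vz = np.where(vmask, np.where(np.isfinite(vel), vel, 0.0) @ up, np.nan)
        h = np.where(mask, mid @ up, np.nan)
        finite_h = h[np.isfinite(h)]
        if finite_h.size < 3:
            continue
        ground = np.percentile(finite_h, 2)
        clearance = h - ground
        baseline = np.percentile(clearance[np.isfinite(clearance)], 10)
        # floor at one marker height so a zero baseline cannot reject stance
        height_limit = params.m3_height_factor * max(baseline, 0.025)
        vals = vz[vmask & np.isfinite(vz)]
        if vals.size < 3 or np.ptp(vals) < 1e-9:
            continue
        prom = 0.1 * np.ptp(vals)
        # timing/amplitude constraint: contact-phase extrema are large
        amp_floor = params.m3_amplitude_frac * np.percentile(np.abs(vals), 95)
        for typ, minima in (("IC", True), ("FC", False)):
            idx = _peaks(vz, vmask, kin.fs, params.min_event_separation,
                         prom, minima=minima)
            idx = idx[np.abs(vz[idx]) >= amp_floor] if idx.size else idx
            if typ == "IC":  # the height gate rejects mid-swing minima
                idx = idx[clearance[idx] <= height_limit]
            events += _mk_events(trial, idx, side, typ, "M3")
    return GaitEventSet(_enforce_separation_by_type(events, params.min_event_separation))


# ----------------------------------------------------------------------
# M4 / M6 (sagittal-plane speed thresholds)
# ----------------------------------------------------------------------

def detect_sagittal_velocity(trial: MarkerTrialData,
                             frames: PelvisFrameSeries | None = None,
                             params: DetectorParams | None = None,
                             method: str = "M4",
                             kin: Kinematics | None = None) -> GaitEventSet:
    """M4/M6: IC when heel sagittal speed drops below its threshold, FC
    when toe sagittal speed rises above its threshold."""
    if method not in ("M4", "M6"):
        raise ValueError("method must be M4 or M6")
    params = params or DetectorParams()
    kin = kin or Kinematics(trial, cutoff=params.cutoff_hz, frames=frames)
    if not kin.frames.any_valid():
        warnings.warn(f"{method}: no valid pelvis frames; returning empty event set")
        return GaitEventSet()
    th = params.resolved_thresholds(method)
    min_sep_frames = int(round(params.min_event_separation * kin.fs))
    events: list[GaitEvent] = []
    for side, (heel, toe) in SIDE_MARKERS.items():
        s_heel, m_heel = kin.sagittal_speed(heel)
        s_toe, m_toe = kin.sagittal_speed(toe)
        ic = _crossings(s_heel, m_heel, th["ic_heel"], min_sep_frames, "down")
        fc = _crossings(s_toe, m_toe, th["fc_toe"], min_sep_frames, "up")
        events += _mk_events(trial, ic, side, "IC", method)
        events += _mk_events(trial, fc, side, "FC", method)
    return GaitEventSet(_enforce_separation_by_type(events, params.min_event_separation))


# ----------------------------------------------------------------------
# M5 / M7 (3D speed thresholds with contact-pattern rules)
# ----------------------------------------------------------------------

def velocity_candidates(trial: MarkerTrialData, params: DetectorParams,
                        method: str, side: str,
                        kin: Kinematics | None = None) -> VelocityCandidates:
    """Raw threshold-crossing candidates for one side."""
    kin = kin or Kinematics(trial, cutoff=params.cutoff_hz)
    th = params.resolved_thresholds(method)
    heel, toe = SIDE_MARKERS[side]
    s_heel, m_heel = kin.speed3d(heel)
    s_toe, m_toe = kin.speed3d(toe)
    min_sep_frames = int(round(params.min_event_separation * kin.fs))
    tic_h = trial.time[_crossings(s_heel, m_heel, th["ic_heel"], min_sep_frames, "down")]
    tic_t = trial.time[_crossings(s_toe, m_toe, th["ic_toe"], min_sep_frames, "down")]
    tfc_t = trial.time[_crossings(s_toe, m_toe, th["fc_toe"], min_sep_frames, "up")]
    return VelocityCandidates(tic_h=tic_h, tic_t=tic_t, tfc_t=tfc_t)


def detect_ic_velocity3d(trial: MarkerTrialData, params: DetectorParams | None = None,
                         method: str = "M5",
                         kin: Kinematics | None = None) -> GaitEventSet:
    """M5/M7 initial contacts with rearfoot/forefoot disambiguation.

    Candidates are grouped by the swing interval they terminate (delimited
    by consecutive toe-speed upward crossings).  Within each interval:
    if the heel candidate is not later than the toe candidate the contact
    is rearfoot at the heel instant; otherwise, if the toe marker is below
    the heel marker at the toe instant, the contact is forefoot at the toe
    instant; otherwise rearfoot at the heel instant.
    """
    if method not in ("M5", "M7"):
        raise ValueError("method must be M5 or M7")
    params = params or DetectorParams()
    kin = kin or Kinematics(trial, cutoff=params.cutoff_hz)
    events: list[GaitEvent] = []
    for side, (heel, toe) in SIDE_MARKERS.items():
        cand = velocity_candidates(trial, params, method, side, kin)
        h_heel, _ = kin.height(heel)
        h_toe, _ = kin.height(toe)
        bounds = np.concatenate(([trial.time[0] - 1e-9], cand.tfc_t,
                                 [trial.time[-1] + 1e-9]))
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            th_in = cand.tic_h[(cand.tic_h > lo) & (cand.tic_h <= hi)]
            tt_in = cand.tic_t[(cand.tic_t > lo) & (cand.tic_t <= hi)]
            tic_h = th_in[0] if th_in.size else None
            tic_t = tt_in[0] if tt_in.size else None
            if tic_h is None and tic_t is None:
                continue
            if tic_h is not None and (tic_t is None or tic_h <= tic_t):
                t_ev, strike = tic_h, "rearfoot"
            elif tic_t is not None:
                i = trial.frame_of(tic_t)
                toe_below = (np.isfinite(h_toe[i]) and np.isfinite(h_heel[i])
                             and h_toe[i] < h_heel[i])
                if toe_below:
                    t_ev, strike = tic_t, "forefoot"
                elif tic_h is not None:
                    t_ev, strike = tic_h, "rearfoot"
                else:
                    continue
            else:
                continue
            i = trial.frame_of(t_ev)
            events.append(GaitEvent(time=float(t_ev), frame=i, side=side,
                                    type="IC", foot_strike=strike, method=method))
    return GaitEventSet(_enforce_separation_by_type(events, params.min_event_separation))


def detect_fc_velocity3d(trial: MarkerTrialData, params: DetectorParams | None = None,
                         method: str = "M5",
                         kin: Kinematics | None = None) -> GaitEventSet:
    """M5/M7 final contacts.

    Each toe-speed upward crossing seeds a search for a local peak of the
    3D heel speed within a centred ``fc_window``; if found (the heel
    starting to rotate about the forefoot), the contact is placed at the
    instant following the peak (the discrete zero-acceleration sample),
    otherwise at the crossing itself.
    """
    if method not in ("M5", "M7"):
        raise ValueError("method must be M5 or M7")
    params = params or DetectorParams()
    kin = kin or Kinematics(trial, cutoff=params.cutoff_hz)
    half = params.fc_window / 2.0
    events: list[GaitEvent] = []
    for side, (heel, toe) in SIDE_MARKERS.items():
        cand = velocity_candidates(trial, params, method, side, kin)
        s_heel, m_heel = kin.speed3d(heel)
        finite = s_heel[m_heel & np.isfinite(s_heel)]
        prom = params.fc_peak_prominence_frac * (
            np.percentile(finite, 95) - np.percentile(finite, 5)) if finite.size else None
        peak_idx = _peaks(s_heel, m_heel, kin.fs, min_sep=0.0, prominence=prom)
        peak_t = trial.time[peak_idx] if peak_idx.size else np.array([])
        for t_cross in cand.tfc_t:
            in_win = peak_idx[(peak_t >= t_cross - half) & (peak_t <= t_cross + half)] \
                if peak_idx.size else np.array([], dtype=int)
            if in_win.size:
                best = in_win[np.argmax(s_heel[in_win])]
                i = min(best + 1, trial.n_frames - 1)  # instant after the peak
                t_ev = trial.time[i]
            else:
                t_ev = t_cross
                i = trial.frame_of(t_cross)
            events.append(GaitEvent(time=float(t_ev), frame=int(i), side=side,
                                    type="FC", method=method))
    return GaitEventSet(_enforce_separation_by_type(events, params.min_event_separation))


def detect_velocity3d(trial: MarkerTrialData, params: DetectorParams | None = None,
                      method: str = "M5",
                      kin: Kinematics | None = None) -> GaitEventSet:
    """Full M5/M7 event set (ICs and FCs)."""
    ic = detect_ic_velocity3d(trial, params, method, kin)
    fc = detect_fc_velocity3d(trial, params, method, kin)
    return ic.extend(fc)


# ----------------------------------------------------------------------
# M8 / M9 (acceleration extrema)
# ----------------------------------------------------------------------

def detect_accel(trial: MarkerTrialData, frames: PelvisFrameSeries | None = None,
                 params: DetectorParams | None = None, method: str = "M8",
                 kin: Kinematics | None = None) -> GaitEventSet:
    """M8: IC at heel vertical-acceleration maxima with null jerk, FC at
    toe AP-acceleration maxima under the same gate.  M9: IC at heel AP
    acceleration minima, FC at toe AP acceleration maxima."""
    if method not in ("M8", "M9"):
        raise ValueError("method must be M8 or M9")
    params = params or DetectorParams()
    kin = kin or Kinematics(trial, cutoff=params.cutoff_hz, frames=frames)
    if not kin.frames.any_valid():
        warnings.warn(f"{method}: no valid pelvis frames; returning empty event set")
        return GaitEventSet()
    events: list[GaitEvent] = []
    for side, (heel, toe) in SIDE_MARKERS.items():
        if method == "M8":
            _, _, a_heel_v = kin.component(heel, "acceleration")
            a_toe_ap, _, _ = kin.component(toe, "acceleration")
            _, _, j_heel_v = kin.component(heel, "jerk")
            j_toe_ap, _, _ = kin.component(toe, "jerk")
            specs = (("IC", a_heel_v, False, j_heel_v), ("FC", a_toe_ap, False, j_toe_ap))
        else:
            a_heel_ap, _, _ = kin.component(heel, "acceleration")
            a_toe_ap, _, _ = kin.component(toe, "acceleration")
            specs = (("IC", a_heel_ap, True, None), ("FC", a_toe_ap, False, None))
        for typ, comp, minima, jerk in specs:
            vals = comp.values[comp.valid_mask & np.isfinite(comp.values)]
            if vals.size < 3 or np.ptp(vals) < 1e-12:
                continue
            prom = params.accel_prominence_frac * (
                np.percentile(vals, 95) - np.percentile(vals, 5))
            idx = _peaks(comp.values, comp.valid_mask, kin.fs,
                         params.min_event_separation, prom or None, minima=minima)
            if jerk is not None and idx.size:
                # "null jerk": the jerk crosses zero at the acceleration
                # extremum (sign change across the peak, or |jerk| tiny)
                jv = jerk.values
                rms = np.sqrt(np.nanmean(jv[jerk.valid_mask] ** 2))
                eps = params.jerk_tol_frac * rms

                def _null_jerk(i: int) -> bool:
                    if not np.isfinite(jv[i]):
                        return False
                    if abs(jv[i]) <= eps:
                        return True
                    lo, hi = max(i - 1, 0), min(i + 1, len(jv) - 1)
                    return bool(np.isfinite(jv[lo]) and np.isfinite(jv[hi])
                                and jv[lo] * jv[hi] < 0)

                idx = idx[np.array([_null_jerk(i) for i in idx])]
            events += _mk_events(trial, idx, side, typ, method)
    return GaitEventSet(_enforce_separation_by_type(events, params.min_event_separation))


# ----------------------------------------------------------------------
# M10 (fusion)
# ----------------------------------------------------------------------

def detect_m10(trial: MarkerTrialData, frames: PelvisFrameSeries | None = None,
               params: DetectorParams | None = None,
               kin: Kinematics | None = None) -> GaitEventSet:
    """Fuse M1 (pelvis-anchored, false-positive resistant) with M7
    (3D-velocity, precise timing).

    Every M1 event is refined to the nearest same-side, same-type M7
    event within ``m10_match_window``; unmatched M1 events are kept with
    an unknown foot-strike, unmatched M7 events are discarded.  Wherever
    the pelvis cluster is occluded (and on trials without pelvis markers)
    the M7 events are used directly.
    """
    params = params or DetectorParams()
    kin = kin or Kinematics(trial, cutoff=params.cutoff_hz, frames=frames)

    refine_method = "M7"
    p7 = params
    if p7.walking_speed is None:
        try:
            ws = estimate_walking_speed(trial, kin, params)
            p7 = replace(params, walking_speed=ws)
        except DetectionError:
            warnings.warn("M10: walking speed unavailable; refining with M5 thresholds")
            refine_method = "M5"
    m7 = detect_velocity3d(trial, p7, method=refine_method, kin=kin)

    pelvis_valid = kin.frames.valid
    if not pelvis_valid.any():
        return m7.with_method("M10")

    m1 = detect_m1(trial, params=params, kin=kin)
    fused: list[GaitEvent] = []
    window = params.m10_match_window
    for side in ("L", "R"):
        for typ in ("IC", "FC"):
            anchors = list(m1.select(side, typ))
            refs = list(m7.select(side, typ))
            used = [False] * len(refs)
            for a in anchors:
                best, best_d = None, window + 1e-12
                for j, r in enumerate(refs):
                    d = abs(r.time - a.time)
                    if not used[j] and d <= best_d:
                        best, best_d = j, d
                if best is not None:
                    used[best] = True
                    r = refs[best]
                    fused.append(replace(r, method="M10"))
                else:
                    fused.append(replace(a, method="M10", foot_strike="unknown"))
            # during pelvis occlusion M1 cannot anchor: take M7 directly
            for j, r in enumerate(refs):
                if used[j]:
                    continue
                i = min(max(trial.frame_of(r.time), 0), trial.n_frames - 1)
                if not pelvis_valid[i]:
                    fused.append(replace(r, method="M10"))
    return GaitEventSet(_enforce_separation_by_type(fused, params.min_event_separation))


# ----------------------------------------------------------------------
# dispatch
# ----------------------------------------------------------------------

def detect_events(trial: MarkerTrialData, method: str = "M10",
                  params: DetectorParams | None = None,
                  kin: Kinematics | None = None) -> GaitEventSet:
    """Run one of the ten detectors on a trial."""
    params = params or DetectorParams(method=method)
    kin = kin or Kinematics(trial, cutoff=params.cutoff_hz)
    if method in ("M6", "M7") and params.walking_speed is None:
        params = replace(params, walking_speed=estimate_walking_speed(trial, kin, params))
    if method == "M1":
        return detect_m1(trial, params=params, kin=kin)
    if method == "M2":
        return detect_m2(trial, params=params, kin=kin)
    if method == "M3":
        return detect_m3(trial, params=params, kin=kin)
    if method in ("M4", "M6"):
        return detect_sagittal_velocity(trial, params=params, method=method, kin=kin)
    if method in ("M5", "M7"):
        return detect_velocity3d(trial, params=params, method=method, kin=kin)
    if method in ("M8", "M9"):
        return detect_accel(trial, params=params, method=method, kin=kin)
    if method == "M10":
        return detect_m10(trial, params=params, kin=kin)
    raise ValueError(f"unknown method {method!r}")
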