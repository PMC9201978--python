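"""Stride assembly and spatio-temporal parameters.

A stride is the interval between consecutive initial contacts of the
same foot; the intervening same-side final contact splits it into stance
(IC to FC) and swing (FC to next IC).  Stride length is the
horizontal-plane displacement of the heel marker between the bounding
ICs (the vertical component is excluded so that step negotiation does
not inflate the length); speed is length over duration.

Walking bouts — the unit of analysis for validation — are maximal
episodes of continuous stepping (no inter-IC gap of 3 s or more)
containing at least two left and two right strides.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .detectors import GaitEventSet
from .preprocessing import Kinematics
from .trial import SIDE_MARKERS, MarkerTrialData

BOUT_MAX_IC_GAP_S = 3.0
BOUT_MIN_STRIDES_PER_SIDE = 2


@dataclass
class Stride:
    side: str
    t_ic_start: float
    t_ic_end: float
    t_fc: float | None = None
    length: float | None = None
    speed: float | None = None
    condition: str = "unlabeled"
    matched: bool = False
    flag: str = ""  # degenerate-FC diagnostics

    @property
    def duration(self) -> float:
        return self.t_ic_end - self.t_ic_start

    @property
    def stance_duration(self) -> float | None:
        return None if self.t_fc is None else self.t_fc - self.t_ic_start

    @property
    def swing_duration(self) -> float | None:
        return None if self.t_fc is None else self.t_ic_end - self.t_fc


STRIDE_COLUMNS = ("side", "t_ic_start", "t_fc", "t_ic_end", "duration_s",
                  "stance_s", "swing_s", "length_m", "speed_mps", "condition")


def assemble_strides(events: GaitEventSet) -> list[Stride]:
    """One stride per consecutive same-side IC pair; the FC is the unique
    same-side FC strictly inside the interval (absent/multiple leaves the
    stance/swing split undefined and raises a flag)."""
    strides: list[Stride] = []
    for side in ("L", "R"):
        t_ic = events.times(side, "IC")
        t_fc = events.times(side, "FC")
        for a, b in zip(t_ic[:-1], t_ic[1:]):
            inside = t_fc[(t_fc > a) & (t_fc < b)]
            if inside.size == 1:
                strides.append(Stride(side=side, t_ic_start=float(a),
                                      t_ic_end=float(b), t_fc=float(inside[0])))
            else:
                flag = "no_fc" if inside.size == 0 else "multiple_fc"
                strides.append(Stride(side=side, t_ic_start=float(a),
                                      t_ic_end=float(b), t_fc=None, flag=flag))
    return sorted(strides, key=lambda s: (s.t_ic_start, s.side))


def compute_stride_params(strides: list[Stride], trial: MarkerTrialData,
                          kin: Kinematics | None = None,
                          horizontal_only: bool = True) -> list[Stride]:
    """Fill in stride length (heel displacement between bounding ICs) and
    speed.  Strides whose heel marker is occluded at an endpoint are
    dropped (counted missing by the caller)."""
    kin = kin or Kinematics(trial)
    up = kin.vertical
    out: list[Stride] = []
    for s in strides:
        heel = SIDE_MARKERS[s.side][0]
        pos = kin.position(heel)
        mask = kin.mask(heel)
        i0 = min(max(trial.frame_of(s.t_ic_start), 0), trial.n_frames - 1)
        i1 = min(max(trial.frame_of(s.t_ic_end), 0), trial.n_frames - 1)
        if not (mask[i0] and mask[i1]):
            continue
        d = pos[i1] - pos[i0]
        if horizontal_only:
            d = d - (d @ up) * up
        length = float(np.linalg.norm(d))
        out.append(replace(s, length=length, speed=length / s.duration))
    return out


def identify_bouts(strides: list[Stride]) -> list[tuple[float, float]]:
    """Maximal continuous-stepping intervals with >= 2 strides per side.

    Continuity breaks where consecutive ICs (either side, time-ordered)
    are 3 s or more apart."""
    ics = sorted({(s.t_ic_start) for s in strides} | {s.t_ic_end for s in strides})
    if not ics:
        return []
    groups: list[list[float]] = [[ics[0]]]
    for t in ics[1:]:
        if t - groups[-1][-1] >= BOUT_MAX_IC_GAP_S:
            groups.append([t])
        else:
            groups[-1].append(t)
    bouts = []
    for g in groups:
        lo, hi = g[0], g[-1]
        n = {"L": 0, "R": 0}
        for s in strides:
            if s.t_ic_start >= lo - 1e-9 and s.t_ic_end <= hi + 1e-9:
                n[s.side] += 1
        if all(v >= BOUT_MIN_STRIDES_PER_SIDE for v in n.values()):
            bouts.append((float(lo), float(hi)))
    return bouts


def strides_in_bouts(strides: list[Stride],
                     bouts: list[tuple[float, float]]) -> list[Stride]:
    return [s for s in strides
            if any(s.t_ic_start >= lo - 1e-9 and s.t_ic_end <= hi + 1e-9
                   for lo, hi in bouts)]


def label_strides(strides: list[Stride], labeled_events: GaitEventSet) -> list[Stride]:
    """Stride condition from its bounding ICs: SN if either IC is SN,
    else CW if either is CW, else SW."""
    out = []
    for s in strides:
        labels = set()
        for e in labeled_events.select(s.side, "IC"):
            if abs(e.time - s.t_ic_start) < 1e-6 or abs(e.time - s.t_ic_end) < 1e-6:
                labels.add(e.condition)
        if "SN" in labels:
            cond = "SN"
        elif "CW" in labels:
            cond = "CW"
        else:
            cond = "SW"
        out.append(replace(s, condition=cond))
    return out


def stride_table(strides: list[Stride], trial_id: str = "",
                 method: str = "") -> pd.DataFrame:
    """Tidy per-stride parameter table."""
    rows = []
    for s in strides:
        rows.append({
            "trial_id": trial_id, "method": method, "side": s.side,
            "t_ic_start": s.t_ic_start, "t_fc": s.t_fc, "t_ic_end": s.t_ic_end,
            "duration_s": s.duration, "stance_s": s.stance_duration,
            "swing_s": s.swing_duration, "length_m": s.length,
            "speed_mps": s.speed, "condition": s.condition,
        })
    return pd.DataFrame(rows, columns=["trial_id", "method", *STRIDE_COLUMNS])


def build_stride_table(trial: MarkerTrialData, labeled_events: GaitEventSet,
                       kin: Kinematics | None = None, method: str = "",
                       restrict_to_bouts: bool = False) -> pd.DataFrame:
    """Events-to-table convenience pipeline: assemble, measure, label."""
    kin = kin or Kinematics(trial)
    strides = assemble_strides(labeled_events)
    strides = compute_stride_params(strides, trial, kin)
    if restrict_to_bouts:
        strides = strides_in_bouts(strides, identify_bouts(strides))
    strides = label_strides(strides, labeled_events)
    return stride_table(strides, trial.trial_id, method)
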