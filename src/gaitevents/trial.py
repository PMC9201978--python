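"""Core container for marker trajectories.

A trial holds time-stamped 3D trajectories for the eight-marker gait set
(bilateral HEEL/TOE markers plus an optional four-marker pelvis cluster
P0..P3) together with per-frame validity masks.  Positions are always in
meters and time in seconds; readers are responsible for unit conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

FOOT_MARKERS = ("LHEEL", "RHEEL", "LTOE", "RTOE")
PELVIS_MARKERS = ("P0", "P1", "P2", "P3")
ALL_MARKERS = FOOT_MARKERS + PELVIS_MARKERS

#: Markers used per body side.
SIDE_MARKERS = {"L": ("LHEEL", "LTOE"), "R": ("RHEEL", "RTOE")}


class TrialValidationError(ValueError):
    """Raised when a trial violates its structural invariants."""


@dataclass
class MarkerTrialData:
    """Time-stamped 3D marker trajectories with occlusion masks.

    Parameters
    ----------
    trial_id : str
        Free-form identifier.
    sampling_rate : float
        Sampling frequency in Hz (positive).
    time : ndarray, shape (N,)
        Uniformly spaced time stamps in seconds, strictly increasing.
    trajectories : dict of str -> ndarray, shape (N, 3)
        Positions in meters keyed by marker name.  The four foot markers
        are mandatory; pelvis markers P0..P3 are optional.
    valid_mask : dict of str -> ndarray, shape (N,), bool
        False where the marker is occluded/missing.  Built from NaNs in
        the trajectories when not given.
    """

    trial_id: str
    sampling_rate: float
    time: np.ndarray
    trajectories: dict[str, np.ndarray]
    valid_mask: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.trajectories = {k: np.asarray(v, dtype=float) for k, v in self.trajectories.items()}
        if not self.valid_mask:
            self.valid_mask = {
                k: np.all(np.isfinite(v), axis=1) for k, v in self.trajectories.items()
            }
        else:
            self.valid_mask = {k: np.asarray(v, dtype=bool) for k, v in self.valid_mask.items()}
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if self.sampling_rate <= 0:
            raise TrialValidationError("sampling_rate must be positive")
        n = self.time.shape[0]
        if n < 2:
            raise TrialValidationError("trial must contain at least two frames")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise TrialValidationError("time must be strictly increasing")
        if np.max(np.abs(dt - 1.0 / self.sampling_rate)) > 1e-6:
            raise TrialValidationError(
                "time must be uniformly spaced at 1/sampling_rate (tol 1e-6 s)"
            )
        for name in FOOT_MARKERS:
            if name not in self.trajectories:
                raise TrialValidationError(f"required foot marker {name!r} missing")
        for name, xyz in self.trajectories.items():
            if xyz.shape != (n, 3):
                raise TrialValidationError(f"trajectory {name!r} must have shape ({n}, 3)")
            mask = self.valid_mask.get(name)
            if mask is None or mask.shape != (n,):
                raise TrialValidationError(f"valid_mask for {name!r} missing or wrong shape")
            if not np.all(np.isfinite(xyz[mask])):
                raise TrialValidationError(f"non-finite positions flagged valid for {name!r}")

    # ------------------------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.time.shape[0]

    @property
    def has_pelvis(self) -> bool:
        """True when the full pelvis cluster needed for the anatomical
        frame (P0, P1, P3) is present in the marker set."""
        return all(m in self.trajectories for m in ("P0", "P1", "P3"))

    def pelvis_any_valid(self) -> bool:
        """True when the pelvis frame can be built on at least one frame."""
        if not self.has_pelvis:
            return False
        m = self.valid_mask
        return bool(np.any(m["P0"] & m["P1"] & m["P3"]))

    def frame_of(self, t: float) -> int:
        """Frame index of a time stamp (0-based, ``round(t * fs)`` relative
        to the first sample)."""
        return int(round((t - self.time[0]) * self.sampling_rate))

    def copy(self) -> "MarkerTrialData":
        return MarkerTrialData(
            trial_id=self.trial_id,
            sampling_rate=self.sampling_rate,
            time=self.time.copy(),
            trajectories={k: v.copy() for k, v in self.trajectories.items()},
            valid_mask={k: v.copy() for k, v in self.valid_mask.items()},
        )
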