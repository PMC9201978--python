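"""Kinematic preprocessing for marker trajectories.

Pipeline order (fixed): gap-filling of short occlusions, zero-lag
low-pass Butterworth filtering (4th order, 7 Hz default), numerical
differentiation, pelvis anatomical-frame construction and decomposition
of foot kinematics into anterior-posterior (AP), medio-lateral (ML) and
vertical (V) components.

The pelvis frame follows the rigid-cluster convention: ML is the unit
vector from P0 to P1 (pointing right), AP is the unit normal of the
plane through P0, P1 and P3 pointing forward, and V = ML x AP points
cranially.  "Forward" is disambiguated by projecting the candidate
normal on the smoothed pelvis-origin velocity (with a small hysteresis
so the sign cannot flutter when the subject is nearly stationary); if
the subject never moves, a cranial-V heuristic based on the estimated
world vertical is used instead.

Derivative components are taken as the dot product of the *global*
derivative with the instantaneous frame axis, not as derivatives of the
decomposed scalar: differentiating in the rotating frame would add
spurious terms during turns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline

from .trial import MarkerTrialData

DEFAULT_CUTOFF_HZ = 7.0
DEFAULT_FILTER_ORDER = 4
#: minimum contiguous valid samples for stable zero-lag filtering
MIN_FILTER_SAMPLES = 30


def valid_segments(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs of a boolean mask as half-open (start, stop)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
    starts = list(edges[mask[edges + 1]] + 1)
    stops = list(edges[~mask[edges + 1]] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))


# ----------------------------------------------------------------------
# gap filling
# ----------------------------------------------------------------------

def fill_gaps(trial: MarkerTrialData, max_gap: float = 0.5) -> MarkerTrialData:
    """Interpolate interior occlusion gaps strictly shorter than ``max_gap``.

    Each coordinate is cubic-spline interpolated across the gap using the
    marker's valid samples.  Gaps of duration >= ``max_gap`` seconds, and
    leading/trailing invalid runs, are left untouched.
    """
    out = trial.copy()
    max_frames = max_gap * trial.sampling_rate
    idx = np.arange(trial.n_frames)
    for name, mask in trial.valid_mask.items():
        if mask.all() or not mask.any():
            continue
        invalid = valid_segments(~mask)
        fill = np.zeros(trial.n_frames, dtype=bool)
        for start, stop in invalid:
            if start == 0 or stop == trial.n_frames:
                continue  # leading/trailing runs are not interior
            if (stop - start) < max_frames:
                fill[start:stop] = True
        if not fill.any():
            continue
        xyz = out.trajectories[name]
        spline = CubicSpline(idx[mask], xyz[mask], axis=0)
        xyz[fill] = spline(idx[fill])
        out.valid_mask[name] = mask | fill
    return out


# ----------------------------------------------------------------------
# filtering and differentiation
# ----------------------------------------------------------------------

def lowpass_filter(
    series: np.ndarray,
    sampling_rate: float,
    cutoff: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_FILTER_ORDER,
    valid_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Zero-lag (forward-backward) Butterworth low-pass filter.

    Applied independently to every contiguous valid segment of every
    coordinate.  Segments too short to edge-pad are returned unfiltered
    with a warning.  The effective magnitude response is the squared
    single-pass response, i.e. gain 1/2 at the cutoff frequency.
    """
    series = np.asarray(series, dtype=float)
    if valid_mask is None:
        valid_mask = np.all(np.isfinite(series), axis=-1) if series.ndim > 1 \
            else np.isfinite(series)
    sos = signal.butter(order, cutoff, btype="low", fs=sampling_rate, output="sos")
    # padlen for the equivalent transfer function of a 4th-order section pair
    padlen = 3 * (2 * order + 1)
    out = series.copy()
    for start, stop in valid_segments(valid_mask):
        if stop - start <= max(padlen, MIN_FILTER_SAMPLES):
            if stop - start < MIN_FILTER_SAMPLES:
                warnings.warn(
                    f"segment of {stop - start} samples too short to filter; left as-is",
                    stacklevel=2,
                )
                continue
        seg = series[start:stop]
        out[start:stop] = signal.sosfiltfilt(sos, seg, axis=0, padlen=min(padlen, stop - start - 1))
    return out


def highpass_filter(
    series: np.ndarray,
    sampling_rate: float,
    cutoff: float,
    order: int = DEFAULT_FILTER_ORDER,
    valid_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Zero-lag Butterworth high-pass; same segment handling as the low-pass."""
    series = np.asarray(series, dtype=float)
    if valid_mask is None:
        valid_mask = np.all(np.isfinite(series), axis=-1) if series.ndim > 1 \
            else np.isfinite(series)
    sos = signal.butter(order, cutoff, btype="high", fs=sampling_rate, output="sos")
    padlen = 3 * (2 * order + 1)
    out = series.copy()
    for start, stop in valid_segments(valid_mask):
        if stop - start < MIN_FILTER_SAMPLES:
            continue
        out[start:stop] = signal.sosfiltfilt(
            sos, series[start:stop], axis=0, padlen=min(padlen, stop - start - 1)
        )
    return out


def differentiate(
    series: np.ndarray,
    sampling_rate: float,
    valid_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Differentiate per valid segment: central differences in the interior,
    one-sided at segment edges.  Returns (derivative, mask); segments with
    fewer than 3 samples become invalid."""
    series = np.asarray(series, dtype=float)
    if valid_mask is None:
        valid_mask = np.all(np.isfinite(series), axis=-1) if series.ndim > 1 \
            else np.isfinite(series)
    out = np.full_like(series, np.nan)
    out_mask = np.zeros(series.shape[0], dtype=bool)
    dt = 1.0 / sampling_rate
    for start, stop in valid_segments(valid_mask):
        if stop - start < 3:
            continue
        out[start:stop] = np.gradient(series[start:stop], dt, axis=0)
        out_mask[start:stop] = True
    return out, out_mask


# ----------------------------------------------------------------------
# pelvis anatomical frame
# ----------------------------------------------------------------------

@dataclass
class PelvisFrameSeries:
    """Per-frame pelvis anatomical frame.

    origin : (N, 3) midpoint of P0 and P1, meters
    ml, ap, v : (N, 3) unit axes (right / forward / cranial)
    valid : (N,) False where any required pelvis marker is occluded or
        the cluster is degenerate (collinear markers)
    """

    origin: np.ndarray
    ml: np.ndarray
    ap: np.ndarray
    v: np.ndarray
    valid: np.ndarray

    def any_valid(self) -> bool:
        return bool(np.any(self.valid))


def _unit(v: np.ndarray, axis: int = -1) -> tuple[np.ndarray, np.ndarray]:
    norm = np.linalg.norm(v, axis=axis, keepdims=True)
    ok = norm[..., 0] > 1e-12
    return np.divide(v, np.where(norm > 1e-12, norm, 1.0)), ok


def estimate_vertical(trial: MarkerTrialData,
                      frames: "PelvisFrameSeries | None" = None) -> np.ndarray:
    """Estimate the world-vertical unit vector (pointing up).

    Uses the mean pelvis V axis when a pelvis frame is available.  The
    foot-only fallback takes the direction of least variance of the heel
    trajectories (walking spans a horizontal plane) with the sign chosen
    so that the distribution is bottom-heavy (feet rest on the ground and
    make excursions upward, so the mean exceeds the median along "up").
    """
    if frames is not None and frames.any_valid():
        v = frames.v[frames.valid].mean(axis=0)
        return v / np.linalg.norm(v)
    pts = []
    for m in ("LHEEL", "RHEEL"):
        pts.append(trial.trajectories[m][trial.valid_mask[m]])
    pts = np.concatenate(pts, axis=0)
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    up = vt[-1]
    proj = pts @ up
    if np.mean(proj) < np.median(proj):
        up = -up
    return up


def build_pelvis_frames(
    trial: MarkerTrialData,
    cutoff: float = DEFAULT_CUTOFF_HZ,
    speed_hysteresis: float = 0.05,
) -> PelvisFrameSeries:
    """Construct the pelvis anatomical frame from the P0/P1/P3 cluster.

    Frames where any required marker is occluded, or where the cluster is
    collinear, are marked invalid.  ``speed_hysteresis`` (m/s) is the
    origin-speed below which the forward-sign decision is carried over
    from neighbouring moving frames instead of being re-evaluated.
    """
    n = trial.n_frames
    nanframe = np.full((n, 3), np.nan)
    if not trial.has_pelvis:
        return PelvisFrameSeries(nanframe.copy(), nanframe.copy(), nanframe.copy(),
                                 nanframe.copy(), np.zeros(n, dtype=bool))
    mask = trial.valid_mask["P0"] & trial.valid_mask["P1"] & trial.valid_mask["P3"]
    p0 = lowpass_filter(trial.trajectories["P0"], trial.sampling_rate, cutoff, valid_mask=mask)
    p1 = lowpass_filter(trial.trajectories["P1"], trial.sampling_rate, cutoff, valid_mask=mask)
    p3 = lowpass_filter(trial.trajectories["P3"], trial.sampling_rate, cutoff, valid_mask=mask)

    ml_raw = p1 - p0
    ml, ok_ml = _unit(ml_raw)
    normal = np.cross(ml_raw, p3 - p0)
    ap, ok_ap = _unit(normal)
    valid = mask & ok_ml & ok_ap

    origin = 0.5 * (p0 + p1)
    vel, vel_mask = differentiate(origin, trial.sampling_rate, mask)
    speed = np.linalg.norm(np.where(np.isfinite(vel), vel, 0.0), axis=1)

    proj = np.einsum("ij,ij->i", ap, np.where(np.isfinite(vel), vel, 0.0))
    decided = valid & vel_mask & (np.abs(proj) > speed_hysteresis)
    sign = np.zeros(n)
    sign[decided] = np.sign(proj[decided])
    if decided.any():
        # carry nearest decided sign into slow/stationary stretches
        idx = np.arange(n)
        dec_idx = idx[decided]
        # choose between the decided neighbours on each side
        pos = np.searchsorted(dec_idx, idx)
        left = dec_idx[np.clip(pos - 1, 0, dec_idx.size - 1)]
        right = dec_idx[np.clip(pos, 0, dec_idx.size - 1)]
        nearest = np.where(np.abs(idx - left) <= np.abs(right - idx), left, right)
        sign = sign[nearest]
    else:
        # stationary trial: pick the sign making V = ML x AP point up
        up = estimate_vertical(trial)
        v_cand = np.cross(ml, ap)
        score = np.nanmedian(np.einsum("ij,j->i", v_cand[valid], up)) if valid.any() else 1.0
        sign[:] = 1.0 if score >= 0 else -1.0
    ap = ap * sign[:, None]
    v = np.cross(ml, ap)

    origin = np.where(valid[:, None], origin, np.nan)
    ml = np.where(valid[:, None], ml, np.nan)
    ap = np.where(valid[:, None], ap, np.nan)
    v = np.where(valid[:, None], v, np.nan)
    return PelvisFrameSeries(origin=origin, ml=ml, ap=ap, v=v, valid=valid)


# ----------------------------------------------------------------------
# component decomposition
# ----------------------------------------------------------------------

@dataclass
class ComponentSeries:
    """A scalar kinematic series for one marker along one pelvis axis
    (or the 3D magnitude)."""

    marker: str
    component: str   # AP | ML | V | 3D
    quantity: str    # position | velocity | acceleration | jerk
    values: np.ndarray
    valid_mask: np.ndarray


def decompose(
    marker: str,
    values: np.ndarray,
    valid_mask: np.ndarray,
    frames: PelvisFrameSeries,
    quantity: str = "position",
) -> tuple[ComponentSeries, ComponentSeries, ComponentSeries]:
    """Decompose a 3D series into pelvis-frame (AP, ML, V) components.

    Positions are expressed relative to the pelvis origin; derivatives
    (velocity/acceleration/jerk) are projected directly onto the frame
    axes at each instant.
    """
    values = np.asarray(values, dtype=float)
    rel = values - frames.origin if quantity == "position" else values
    mask = valid_mask & frames.valid
    comps = {}
    for name, axis in (("AP", frames.ap), ("ML", frames.ml), ("V", frames.v)):
        c = np.einsum("ij,ij->i", np.where(np.isfinite(rel), rel, 0.0),
                      np.where(np.isfinite(axis), axis, 0.0))
        c = np.where(mask, c, np.nan)
        comps[name] = ComponentSeries(marker, name, quantity, c, mask.copy())
    return comps["AP"], comps["ML"], comps["V"]


# ----------------------------------------------------------------------
# cached per-trial kinematics
# ----------------------------------------------------------------------

class Kinematics:
    """Lazy per-trial cache of filtered positions, derivatives and
    pelvis-frame components, shared by the event detectors."""

    def __init__(self, trial: MarkerTrialData,
                 cutoff: float = DEFAULT_CUTOFF_HZ,
                 frames: PelvisFrameSeries | None = None):
        self.trial = fill_gaps(trial)
        self.fs = trial.sampling_rate
        self.cutoff = cutoff
        self._pos: dict[str, np.ndarray] = {}
        self._deriv: dict[tuple[str, int], tuple[np.ndarray, np.ndarray]] = {}
        self._frames = frames
        self._vertical: np.ndarray | None = None

    # -- geometry ------------------------------------------------------
    @property
    def frames(self) -> PelvisFrameSeries:
        if self._frames is None:
            self._frames = build_pelvis_frames(self.trial, self.cutoff)
        return self._frames

    @property
    def vertical(self) -> np.ndarray:
        if self._vertical is None:
            frames = self.frames if self.trial.has_pelvis else None
            self._vertical = estimate_vertical(self.trial, frames)
        return self._vertical

    # -- scalar/vector series -------------------------------------------
    def mask(self, marker: str) -> np.ndarray:
        return self.trial.valid_mask[marker]

    def position(self, marker: str) -> np.ndarray:
        """Gap-filled, low-pass filtered position (N, 3)."""
        if marker not in self._pos:
            self._pos[marker] = lowpass_filter(
                self.trial.trajectories[marker], self.fs, self.cutoff,
                valid_mask=self.mask(marker))
        return self._pos[marker]

    def derivative(self, marker: str, n: int) -> tuple[np.ndarray, np.ndarray]:
        """n-th derivative of the filtered position (1=velocity, ...)."""
        key = (marker, n)
        if key not in self._deriv:
            if n == 0:
                self._deriv[key] = (self.position(marker), self.mask(marker).copy())
            else:
                prev, pmask = self.derivative(marker, n - 1)
                self._deriv[key] = differentiate(prev, self.fs, pmask)
        return self._deriv[key]

    def speed3d(self, marker: str) -> tuple[np.ndarray, np.ndarray]:
        """Magnitude of the 3D marker velocity."""
        vel, mask = self.derivative(marker, 1)
        s = np.linalg.norm(np.where(np.isfinite(vel), vel, 0.0), axis=1)
        return np.where(mask, s, np.nan), mask

    def component(self, marker: str, quantity: str = "position"
                  ) -> tuple[ComponentSeries, ComponentSeries, ComponentSeries]:
        order = {"position": 0, "velocity": 1, "acceleration": 2, "jerk": 3}[quantity]
        values, mask = self.derivative(marker, order)
        return decompose(marker, values, mask, self.frames, quantity)

    def sagittal_speed(self, marker: str) -> tuple[np.ndarray, np.ndarray]:
        """Speed in the pelvis sagittal (AP-V) plane."""
        ap, _, v = self.component(marker, "velocity")
        s = np.hypot(ap.values, v.values)
        return s, ap.valid_mask

    def relative_ap(self, marker: str) -> tuple[np.ndarray, np.ndarray]:
        """AP component of the marker position relative to the pelvis
        origin, evaluated in the horizontal plane.

        The progression (AP) direction is horizontal by definition, so the
        relative position is first projected on the horizontal plane; this
        prevents cluster-axis wobble (marker noise tilting the AP axis)
        from coupling the large vertical heel-pelvis offset into the AP
        component.  Identical to the plain AP component when the pelvis
        axes are noise-free and level.
        """
        up = self.vertical
        rel = self.position(marker) - self.frames.origin
        rel_h = rel - np.outer(rel @ up, up)
        ap_h = self.frames.ap - np.outer(
            np.where(np.isfinite(self.frames.ap @ up), self.frames.ap @ up, 0.0), up)
        norm = np.linalg.norm(ap_h, axis=1, keepdims=True)
        ap_h = np.divide(ap_h, np.where(norm > 1e-12, norm, 1.0))
        mask = self.mask(marker) & self.frames.valid
        vals = np.einsum("ij,ij->i", np.nan_to_num(rel_h), np.nan_to_num(ap_h))
        return np.where(mask, vals, np.nan), mask

    def height(self, marker: str) -> tuple[np.ndarray, np.ndarray]:
        """Position along the estimated world vertical."""
        pos = self.position(marker)
        h = np.where(np.isfinite(pos).all(axis=1), pos @ self.vertical, np.nan)
        return h, self.mask(marker)
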