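"""Cross-subject standardization of 6-DOF patellar trajectories.

Raw trajectories differ in laterality, frame count and cycle timing.  This
module makes them comparable: left knees are mirrored into right-knee
semantics, the peak-flexion frame is located from the proximal-distal
excursion Tz, the cycle is split there and each phase resampled onto a
uniform 25-point grid (biphasic resampling, preserving flexion/extension
hysteresis that a single-phase resample would average away), and a
Savitzky-Golay filter suppresses frame-quantization noise.  The clustering
feature vector is the standardized, smoothed lateral translation Tx — 50
values per subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .anatomy import DOF_NAMES, mirror_dof
from .exceptions import AlreadyMirroredError, InvalidArgumentError, MalformedCycleError


@dataclass
class DOFTrajectory:
    """Per-frame anatomical 6-vectors [Tx,Ty,Tz,Rx,Ry,Rz] (mm / degrees)."""

    subject_id: str
    laterality: str
    samples: np.ndarray
    mirrored: bool = False

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 6:
            raise InvalidArgumentError("samples must be an (N, 6) array")
        if arr.shape[0] < 5:
            raise InvalidArgumentError("need at least 5 frames")
        if not np.all(np.isfinite(arr)):
            raise InvalidArgumentError("samples must be finite")
        if self.laterality not in ("left", "right"):
            raise InvalidArgumentError("laterality must be 'left' or 'right'")
        self.samples = arr

    @property
    def n_frames(self) -> int:
        return self.samples.shape[0]


@dataclass
class StandardizedTrajectory:
    """Biphasic 2x25-point standardized series for all six DOFs."""

    subject_id: str
    series: np.ndarray  # (2 * points_per_phase, 6)
    kpeak: int
    points_per_phase: int = 25
    smoothed: bool = False

    def __post_init__(self) -> None:
        arr = np.asarray(self.series, dtype=float)
        if arr.shape != (2 * self.points_per_phase, 6):
            raise InvalidArgumentError(
                f"series must have shape ({2 * self.points_per_phase}, 6)"
            )
        if not np.all(np.isfinite(arr)):
            raise InvalidArgumentError("standardized series must be finite")
        self.series = arr

    def dof(self, name: str) -> np.ndarray:
        return self.series[:, DOF_NAMES.index(name)]


@dataclass
class KinematicSummary:
    """Per-subject peak (max) and total range (max - min) for each DOF."""

    subject_id: str
    peaks: dict = field(default_factory=dict)
    ranges: dict = field(default_factory=dict)

    @property
    def max_lateral_displacement(self) -> float:
        return self.peaks["Tx"]

    @property
    def lateral_range_of_motion(self) -> float:
        return self.ranges["Tx"]

    @property
    def max_longitudinal_displacement(self) -> float:
        return self.peaks["Tz"]


def mirror_if_left(traj: DOFTrajectory) -> DOFTrajectory:
    """Map left-knee trajectories into right-knee semantics.

    Negates Tx, Ry and Rz for left knees; right knees pass through.  Either
    way the returned trajectory carries ``mirrored=True`` and feeding it back
    in raises :class:`AlreadyMirroredError` — the raw map is an involution,
    so a second application would silently undo the first.
    """
    if traj.mirrored:
        raise AlreadyMirroredError(f"{traj.subject_id}: trajectory already mirrored")
    samples = mirror_dof(traj.samples) if traj.laterality == "left" else traj.samples.copy()
    return DOFTrajectory(traj.subject_id, traj.laterality, samples, mirrored=True)


def find_peak_frame(traj: DOFTrajectory | np.ndarray) -> int:
    """Index of peak flexion: the (first) maximum of proximal-distal Tz.

    The peak must be interior (not frame 0 or N-1), otherwise the cycle does
    not contain both a flexion and an extension phase and the subject is
    rejected as malformed.
    """
    samples = traj.samples if isinstance(traj, DOFTrajectory) else np.asarray(traj, dtype=float)
    if samples.shape[0] < 5:
        raise InvalidArgumentError("need at least 5 frames")
    tz = samples[:, 2]
    kpeak = int(np.argmax(tz))  # first index among ties
    if kpeak < 1 or kpeak > samples.shape[0] - 2:
        raise MalformedCycleError(
            f"peak flexion at boundary frame {kpeak}; cycle lacks an interior maximum"
        )
    return kpeak


def biphasic_resample(
    traj: DOFTrajectory, kpeak: int, points_per_phase: int = 25
) -> StandardizedTrajectory:
    """Resample flexion (0..kpeak) and extension (kpeak..N-1) phases separately.

    Each phase is linearly interpolated onto ``points_per_phase`` uniformly
    spaced frame-index values including both endpoints, so the value at the
    phase boundary equals the raw sample at ``kpeak`` exactly and the Tz
    cycle maximum is preserved.
    """
    n = traj.n_frames
    if not 1 <= kpeak <= n - 2:
        raise InvalidArgumentError(f"kpeak={kpeak} outside the interior range [1, {n - 2}]")
    if points_per_phase < 2:
        raise InvalidArgumentError("need at least 2 grid points per phase")
    flex_grid = np.linspace(0.0, kpeak, points_per_phase)
    ext_grid = np.linspace(kpeak, n - 1.0, points_per_phase)
    idx = np.arange(n, dtype=float)
    out = np.empty((2 * points_per_phase, 6))
    for d in range(6):
        out[:points_per_phase, d] = np.interp(flex_grid, idx, traj.samples[:, d])
        out[points_per_phase:, d] = np.interp(ext_grid, idx, traj.samples[:, d])
    # endpoints of the two grids are the raw kpeak sample; pin them exactly
    out[points_per_phase - 1] = traj.samples[kpeak]
    out[points_per_phase] = traj.samples[kpeak]
    return StandardizedTrajectory(traj.subject_id, out, kpeak, points_per_phase)


def sg_filter(series: np.ndarray, window: int = 7, order: int = 2) -> np.ndarray:
    """Savitzky-Golay smoothing with polynomial edge fitting.

    Interior samples are the closed-form local least-squares polynomial fit
    (for window 7, order 2 the kernel is (-2,3,6,7,6,3,-2)/21); edge samples
    come from the polynomial fitted to the terminal window, so polynomials up
    to ``order`` pass through the filter unchanged everywhere.
    """
    x = np.asarray(series, dtype=float)
    if window % 2 == 0:
        raise InvalidArgumentError("window must be odd")
    if order >= window:
        raise InvalidArgumentError("order must be smaller than window")
    if x.shape[0] < window:
        raise InvalidArgumentError("series shorter than the filter window")
    return savgol_filter(x, window, order, mode="interp", axis=0)


def smooth_standardized(
    std: StandardizedTrajectory, window: int = 7, order: int = 2
) -> StandardizedTrajectory:
    """Apply the SG filter per DOF *within each phase segment*, extrema kept.

    Smoothing across the flexion/extension junction would blur the hysteresis
    corner, so each 25-point phase is filtered independently and the junction
    samples are restored afterwards.  Within each phase the pre-filter
    extremum samples of every DOF are also restored: a quadratic kernel
    attenuates sharp features such as the terminal-extension J-sign hook by
    millimetres, and peak amplitudes are the clinical readout downstream.
    """
    p = std.points_per_phase
    out = np.empty_like(std.series)
    for seg in (slice(0, p), slice(p, 2 * p)):
        raw = std.series[seg]
        sm = sg_filter(raw, window, order)
        for d in range(6):
            hi = int(np.argmax(raw[:, d]))
            lo = int(np.argmin(raw[:, d]))
            sm[hi, d] = raw[hi, d]
            sm[lo, d] = raw[lo, d]
        out[seg] = sm
    out[p - 1] = std.series[p - 1]
    out[p] = std.series[p]
    return StandardizedTrajectory(std.subject_id, out, std.kpeak, p, smoothed=True)


def summarize_dof(traj: StandardizedTrajectory | DOFTrajectory | np.ndarray,
                  subject_id: str | None = None) -> KinematicSummary:
    """Peak and total range for each DOF of a (standardized) trajectory."""
    if isinstance(traj, StandardizedTrajectory):
        samples, sid = traj.series, traj.subject_id
    elif isinstance(traj, DOFTrajectory):
        samples, sid = traj.samples, traj.subject_id
    else:
        samples, sid = np.asarray(traj, dtype=float), subject_id or "unknown"
    if samples.size == 0:
        raise InvalidArgumentError("empty series")
    peaks = {name: float(samples[:, d].max()) for d, name in enumerate(DOF_NAMES)}
    ranges = {
        name: float(samples[:, d].max() - samples[:, d].min())
        for d, name in enumerate(DOF_NAMES)
    }
    return KinematicSummary(sid, peaks, ranges)


def build_feature_matrix(cohort: list[StandardizedTrajectory]) -> pd.DataFrame:
    """Stack the standardized, smoothed Tx series into an S x 50 matrix."""
    if not cohort:
        raise InvalidArgumentError("empty cohort")
    lengths = {std.series.shape[0] for std in cohort}
    if len(lengths) != 1:
        raise InvalidArgumentError(f"inconsistent standardized lengths: {sorted(lengths)}")
    n = lengths.pop()
    rows = np.vstack([std.dof("Tx") for std in cohort])
    return pd.DataFrame(
        rows,
        index=[std.subject_id for std in cohort],
        columns=[f"tx_{i:02d}" for i in range(n)],
    )
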