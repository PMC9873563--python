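"""Walk-cycle (stride) detection and cycle-wise time normalization.

The 8-m walk features that operate per cycle (lower-body variability, the
cycle-binned autocorrelation PCs, delay lags, per-stride spectral energy)
all rely on a stride segmentation.  With angle-only data, stride starts are
taken at successive maxima of the reference leg's hip-flexion angle — a
robust event once per gait cycle — rather than at foot-contact events, which
would need ground-reaction information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .skeleton_io import KinematicsBundle

__all__ = ["StrideSegmentation", "CycleMatrix", "NoGaitError",
           "detect_strides", "time_normalize_cycles"]


class NoGaitError(ValueError):
    """Fewer than two stride events could be found in the recording."""


@dataclass(frozen=True)
class StrideSegmentation:
    """Stride-start frame indices (per reference leg) and cycle statistics."""

    boundaries: np.ndarray
    frame_rate: float

    def __post_init__(self):
        b = np.asarray(self.boundaries, dtype=int)
        if len(b) < 2 or np.any(np.diff(b) <= 0):
            raise ValueError("need >= 2 strictly increasing boundaries")

    @property
    def n_cycles(self) -> int:
        return len(self.boundaries) - 1

    @property
    def mean_cycle_s(self) -> float:
        return float(np.mean(np.diff(self.boundaries))) / self.frame_rate

    @property
    def boundaries_s(self) -> np.ndarray:
        return np.asarray(self.boundaries) / self.frame_rate


@dataclass(frozen=True)
class CycleMatrix:
    """A per-frame signal resampled onto a fixed grid per stride (cycles x points)."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("values must be 2-D (cycles x points)")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite entries in cycle matrix")

    @property
    def n_cycles(self) -> int:
        return self.values.shape[0]

    @property
    def n_points(self) -> int:
        return self.values.shape[1]


def detect_strides(kin: KinematicsBundle, reference_leg: str = "dominant",
                   min_spacing_s: float = 0.5,
                   prominence_frac: float = 0.2) -> StrideSegmentation:
    """Detect stride starts at maxima of the reference-leg hip-flexion angle.

    Peaks must be at least ``min_spacing_s`` apart and have a prominence of at
    least ``prominence_frac`` of the channel's range; the first and last
    partial cycles (before the first and after the last peak) are implicitly
    discarded since only complete peak-to-peak cycles are counted.

    Raises :class:`NoGaitError` when fewer than two maxima survive, e.g. for a
    constant pose.
    """
    if kin.channel_map is None:
        raise ValueError("kinematics bundle lacks a channel map")
    if reference_leg not in ("dominant", "nondominant"):
        raise ValueError("reference_leg must be 'dominant' or 'nondominant'")
    cm = kin.channel_map
    side_joint = "RightHip" if (
        (reference_leg == "dominant") == (kin.recording.hand_dominance == "right")
    ) else "LeftHip"
    ch = cm.find(side_joint, "flexion")
    x = kin.recording.angles[:, ch]
    rng = float(np.ptp(x))
    if rng == 0:
        raise NoGaitError("no gait detected: hip flexion channel is constant")
    fr = kin.frame_rate
    peaks, _ = find_peaks(x, distance=max(1, int(round(min_spacing_s * fr))),
                          prominence=prominence_frac * rng)
    if len(peaks) < 2:
        raise NoGaitError(f"no gait detected: {len(peaks)} hip-flexion maxima found")
    return StrideSegmentation(boundaries=peaks.astype(int), frame_rate=fr)


def time_normalize_cycles(signal: np.ndarray, seg: StrideSegmentation,
                          n_points: int = 101) -> CycleMatrix:
    """Linearly resample each stride onto ``n_points`` samples over [0, 100)%.

    Row r covers frames ``boundaries[r]`` to ``boundaries[r+1]`` (end
    exclusive), sampled at fractions k/n_points of the cycle.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    x = np.asarray(signal, dtype=float).ravel()
    b = np.asarray(seg.boundaries)
    if b[-1] >= x.size:
        raise ValueError("stride boundaries exceed the signal length")
    rows = np.empty((seg.n_cycles, n_points), dtype=float)
    frames = np.arange(x.size, dtype=float)
    for r in range(seg.n_cycles):
        grid = b[r] + (b[r + 1] - b[r]) * np.arange(n_points) / n_points
        rows[r] = np.interp(grid, frames, x)
    return CycleMatrix(values=rows)
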