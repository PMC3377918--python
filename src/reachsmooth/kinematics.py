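"""Filtering, numerical differentiation, and principal-axis rotation.

Preprocessing follows standard optical motion-capture practice: positions
are low-pass filtered with a zero-phase Butterworth filter (8 Hz cut-off
by default — hand-movement content above that is dominated by tremor and
marker noise), optionally rotated so the main movement direction lies
along x, then differentiated numerically up to jerk.

Differentiation is two-point by default: ``v[i] = (x[i+1] - x[i]) * rate``,
each order shortening the series by one sample. A central (3-point)
scheme is available via ``scheme="central"``. After the third derivative
all series are truncated to the common length so index ``i`` of velocity,
speed, acceleration and jerk refers to the same leading sample window.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .errors import AlignmentError, LengthError, ParameterError, RankError
from .trajectory_io import Trajectory

DiffScheme = Literal["forward", "central"]


@dataclass(frozen=True)
class KinematicSeries:
    """Velocity, speed, acceleration and jerk on a common time base.

    All arrays share length M. ``offset`` counts leading source samples
    not represented (0 for the forward scheme; 1 per derivative order for
    the central scheme). Units: mm/s, mm/s^2, mm/s^3.
    """

    velocity: np.ndarray
    speed: np.ndarray
    acceleration: np.ndarray
    jerk_vec: np.ndarray
    rate_hz: float
    offset: int = 0

    def __post_init__(self) -> None:
        lens = {
            len(self.velocity),
            len(self.speed),
            len(self.acceleration),
            len(self.jerk_vec),
        }
        if len(lens) != 1:
            raise AlignmentError(f"series lengths differ: {sorted(lens)}")

    @property
    def n_samples(self) -> int:
        return len(self.speed)


def lowpass_filter(
    traj: Trajectory, cutoff_hz: float = 8.0, order: int = 4
) -> Trajectory:
    """Zero-phase Butterworth low-pass filter, applied per axis.

    Forward-backward application squares the magnitude response and
    cancels phase lag, so filtered extrema stay aligned in time with the
    raw movement — important because curvature and the speed gate are
    evaluated sample-by-sample.
    """
    if not 0 < cutoff_hz < traj.rate_hz / 2:
        raise ParameterError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={traj.rate_hz / 2} Hz)"
        )
    if order < 1:
        raise ParameterError(f"filter order must be >= 1, got {order}")
    if traj.n_samples <= 3 * order:
        raise LengthError(
            f"{traj.n_samples} samples too short for order-{order} "
            "zero-phase filtering"
        )
    sos = butter(order, cutoff_hz, btype="low", fs=traj.rate_hz, output="sos")
    filtered = sosfiltfilt(sos, traj.positions, axis=0)
    return traj.with_positions(filtered)


def differentiate(
    series: np.ndarray, rate_hz: float, scheme: DiffScheme = "forward"
) -> np.ndarray:
    """Numerical time derivative of a sampled series.

    forward: ``out[i] = (in[i+1] - in[i]) * rate`` (length M-1).
    central: ``out[i] = (in[i+2] - in[i]) * rate / 2`` (length M-2),
    exact for quadratics.
    """
    series = np.asarray(series, dtype=float)
    if scheme == "forward":
        if series.shape[0] < 2:
            raise LengthError("need >= 2 samples to differentiate")
        return np.diff(series, axis=0) * rate_hz
    if scheme == "central":
        if series.shape[0] < 3:
            raise LengthError("need >= 3 samples for central differences")
        return (series[2:] - series[:-2]) * (rate_hz / 2.0)
    raise ParameterError(f"unknown differentiation scheme {scheme!r}")


def compute_kinematics(
    traj: Trajectory, scheme: DiffScheme = "forward"
) -> KinematicSeries:
    """Derive velocity, speed, acceleration and jerk from positions.

    Three successive differentiations; all series are then truncated to
    the jerk length (N-3 forward, N-6 central) so they share one index
    base. Speed is the Euclidean norm of velocity.
    """
    per_order = 1 if scheme == "forward" else 2
    if traj.n_samples < 3 * per_order + 1:
        raise LengthError(
            f"need >= {3 * per_order + 1} samples for jerk, got {traj.n_samples}"
        )
    vel = differentiate(traj.positions, traj.rate_hz, scheme)
    acc = differentiate(vel, traj.rate_hz, scheme)
    jerk = differentiate(acc, traj.rate_hz, scheme)
    m = len(jerk)
    vel, acc = vel[:m], acc[:m]
    speed = np.linalg.norm(vel, axis=1)
    return KinematicSeries(
        velocity=vel,
        speed=speed,
        acceleration=acc,
        jerk_vec=jerk,
        rate_hz=traj.rate_hz,
        offset=0 if scheme == "forward" else 3,
    )


def principal_axis_rotate(traj: Trajectory) -> Trajectory:
    """Rotate positions so the main movement direction is the x-axis.

    Mean-centres the positions and rotates them onto the eigenvectors of
    the position covariance, ordered by descending eigenvalue (x carries
    the table-to-mouth direction, y the second component, z the
    remainder). Each axis sign is chosen so the coordinate of the sample
    farthest from the first sample is positive, making the rotation
    deterministic. Curvature, jerk and all smoothness metrics are
    invariant to this rigid transform; it only standardises plots and
    per-axis inspection.
    """
    centred = traj.positions - traj.positions.mean(axis=0)
    cov = np.cov(centred.T)
    if not np.isfinite(cov).all() or np.allclose(cov, 0):
        raise RankError("positions are degenerate: zero variance")
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    rot = evecs[:, order]
    projected = centred @ rot
    disp = projected - projected[0]
    far = int(np.argmax(np.linalg.norm(disp, axis=1)))
    signs = np.where(disp[far] >= 0, 1.0, -1.0)
    return traj.with_positions(projected * signs)
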