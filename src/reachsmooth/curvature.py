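"""Instantaneous 3D curvature and the MedianLC smoothness score.

Curvature at a sample is computed from velocity v and acceleration a:

    kappa^2 = (|v|^2 |a|^2 - (v . a)^2) / |v|^6

i.e. the inverse squared radius of the osculating circle. Curvature is a
purely geometric property of the path — it does not change when the same
path is traversed at a different speed — which is what makes it suitable
for comparing movement quality across participants who cannot control
their movement speed.

MedianLC is the median of -ln(kappa) (kappa in 1/mm) over samples where
the hand speed exceeds a gate (50 mm/s by default): higher MedianLC
means flatter, smoother paths. The speed gate removes the near-zero
velocity samples around movement reversals, where curvature diverges for
every mover, healthy or not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateSegmentError, InsufficientDataError
from .kinematics import KinematicSeries
from .segmentation import Segment
from .trajectory_io import Trajectory

#: guard added to |v|^2 in the curvature denominator, (mm/s)^2
SPEED_EPS = 1e-12

#: minimum number of gated finite samples for a valid median statistic
MIN_GATED_SAMPLES = 10

#: default tangential-velocity gate for MedianLC/MedianLJ, mm/s
DEFAULT_SPEED_GATE = 50.0


@dataclass(frozen=True)
class CurvatureSeries:
    """Per-sample curvature (1/mm) with its -ln transform and gate mask."""

    kappa: np.ndarray
    neg_log_kappa: np.ndarray
    gate_mask: np.ndarray


def curvature_series(
    kin: KinematicSeries, speed_gate_mm_s: float = DEFAULT_SPEED_GATE
) -> CurvatureSeries:
    """Instantaneous curvature at every kinematic sample.

    The numerator |v|^2|a|^2 - (v.a)^2 is non-negative by Cauchy-Schwarz
    but can dip below zero in floating point on nearly straight motion;
    it is clamped at 0. A tiny guard on |v|^2 keeps rest samples finite
    (they are excluded by the speed gate anyway).
    """
    v, a = kin.velocity, kin.acceleration
    v2 = np.einsum("ij,ij->i", v, v)
    a2 = np.einsum("ij,ij->i", a, a)
    va = np.einsum("ij,ij->i", v, a)
    num = np.maximum(v2 * a2 - va**2, 0.0)
    kappa = np.sqrt(num / (v2 + SPEED_EPS) ** 3)
    with np.errstate(divide="ignore"):
        nlk = np.where(kappa > 0, -np.log(np.maximum(kappa, 1e-300)), np.inf)
    return CurvatureSeries(
        kappa=kappa,
        neg_log_kappa=nlk,
        gate_mask=kin.speed > speed_gate_mm_s,
    )


def median_lc(
    curv: CurvatureSeries,
    kin: KinematicSeries,
    speed_gate_mm_s: float = DEFAULT_SPEED_GATE,
) -> float:
    """Median of -ln(kappa) over speed-gated samples (MedianLC).

    Non-finite values (kappa exactly zero) are dropped before taking the
    median; at least :data:`MIN_GATED_SAMPLES` finite gated samples are
    required.
    """
    mask = kin.speed > speed_gate_mm_s
    vals = curv.neg_log_kappa[mask]
    vals = vals[np.isfinite(vals)]
    if len(vals) < MIN_GATED_SAMPLES:
        raise InsufficientDataError(
            f"only {len(vals)} usable samples above the {speed_gate_mm_s} mm/s "
            f"gate (need >= {MIN_GATED_SAMPLES})"
        )
    return float(np.median(vals))


def ioc(traj: Trajectory, seg: Segment) -> float:
    """Index of curvature of one segment: path length / chord length.

    The classical whole-segment spatial-irregularity measure; 1.0 for a
    perfectly straight stroke, pi/2 for a semicircle. Unlike MedianLC it
    requires segmentation and cannot distinguish where along the stroke
    the meandering happened.
    """
    pos = traj.positions[seg.start : seg.end]
    if len(pos) < 2:
        raise DegenerateSegmentError(f"segment {seg} has fewer than 2 samples")
    chord = float(np.linalg.norm(pos[-1] - pos[0]))
    if chord <= 0:
        raise DegenerateSegmentError(
            "segment endpoints coincide; IOC undefined"
        )
    path = float(np.sum(np.linalg.norm(np.diff(pos, axis=0), axis=1)))
    return path / chord
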