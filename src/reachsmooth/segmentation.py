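"""Decomposition of continuous repetitive movement into single strokes.

The jerk-ratio normaliser (360 A^2 / d^6) is defined for one
point-to-point movement of amplitude A and duration d, so continuous
lap-mouth-lap data must first be cut into single strokes. Strokes are
maximal runs of samples whose speed stays at or above a threshold set to
a fraction (10% by default) of the maximum speed of the analysis window.
A lap-to-mouth-to-lap cycle whose speed dips at the mouth therefore
yields two strokes.

Runs shorter than ``min_samples`` (threshold-crossing chatter) are
discarded, and segments whose endpoint displacement is below 100 mm are
excluded from metric computation as failed segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import NoMovementError, RangeError
from .trajectory_io import Trajectory

#: default threshold as a fraction of the window's maximum speed
DEFAULT_SEG_FRAC = 0.1

#: default minimum amplitude (mm) for a segment to count as one stroke
DEFAULT_MIN_AMP_MM = 100.0

#: default minimum run length in samples
DEFAULT_MIN_SAMPLES = 5


@dataclass(frozen=True)
class Segment:
    """Half-open sample interval [start, end) holding one stroke."""

    start: int
    end: int
    duration_s: float
    amplitude_mm: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise RangeError(f"invalid segment bounds [{self.start}, {self.end})")
        if self.duration_s <= 0:
            raise RangeError(f"segment duration must be > 0, got {self.duration_s}")


def segment_strokes(
    speed: np.ndarray,
    rate_hz: float,
    frac: float = DEFAULT_SEG_FRAC,
    min_samples: int = DEFAULT_MIN_SAMPLES,
    traj: Trajectory | None = None,
) -> list[Segment]:
    """Cut a speed profile into single-stroke segments.

    Threshold = ``frac * max(speed)`` over the window; segments are
    maximal runs with ``speed >= threshold`` (boundary samples included,
    which makes tie handling deterministic). If ``traj`` is given (its
    positions aligned with ``speed``), amplitudes are filled in via
    :func:`segment_amplitude`.
    """
    speed = np.asarray(speed, dtype=float)
    if speed.size == 0 or np.max(speed) <= 0:
        raise NoMovementError("speed profile contains no movement")
    theta = frac * float(np.max(speed))
    above = speed >= theta
    edges = np.diff(above.astype(np.int8))
    starts = np.nonzero(edges == 1)[0] + 1
    ends = np.nonzero(edges == -1)[0] + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, len(speed)]
    segs = []
    for s, e in zip(starts, ends):
        if e - s < min_samples:
            continue
        seg = Segment(start=int(s), end=int(e), duration_s=(e - s) / rate_hz)
        if traj is not None:
            seg = replace(seg, amplitude_mm=segment_amplitude(traj, seg))
        segs.append(seg)
    return segs


def segment_amplitude(traj: Trajectory, seg: Segment) -> float:
    """Endpoint displacement (mm) of a segment.

    Amplitude is the straight-line distance between the first and last
    sample of the stroke, not the path length: the minimum-jerk
    normaliser is defined for a point-to-point movement of amplitude A.
    """
    if seg.end > traj.n_samples:
        raise RangeError(
            f"segment [{seg.start}, {seg.end}) exceeds trajectory of "
            f"{traj.n_samples} samples"
        )
    return float(
        np.linalg.norm(traj.positions[seg.end - 1] - traj.positions[seg.start])
    )


def filter_segments(
    segs: list[Segment], min_amp_mm: float = DEFAULT_MIN_AMP_MM
) -> list[Segment]:
    """Keep segments with amplitude >= ``min_amp_mm`` (order preserved).

    Small-amplitude runs are treated as failed segmentation and excluded
    from the jerk-ratio and IOC statistics. An empty result is allowed
    and signals that the movement could not be decomposed into strokes.
    """
    return [s for s in segs if s.amplitude_mm >= min_amp_mm]
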