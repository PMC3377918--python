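"""Jerk magnitude, MedianLJ, the mean-squared-jerk ratio, and the
full-session analysis pipeline.

Temporal smoothness is quantified by jerk, the third time-derivative of
position. Raw jerk scales with movement speed, so strokes are normalised
by the minimum possible mean squared jerk of a movement with the same
amplitude A and duration d:

    MSJ ratio = MeanJ^2 / (C * A^2 / d^6),   MeanJ^2 = (1/d) * int J^2 dt

with C = 360 by default. Note the classical minimum-jerk stroke has
MeanJ^2 = 720 * A^2 / d^6 (the integral of its squared jerk polynomial
(60 - 360 tau + 360 tau^2)^2 over [0, 1] is 720), so under C = 360 an
ideal stroke scores a ratio of 2, not 1; ``normalizer_const=720``
selects the convention that scores the ideal stroke at 1. The ratio is
dimensionless — invariant to rescaling amplitude or duration of a fixed
movement shape — which is what makes jerk comparable across movement
speeds at all.

:func:`analyze` composes the whole pipeline (window, filter, rotate,
differentiate, curvature, segmentation, metrics) into a single
:class:`SmoothnessReport` that records every parameter used.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np

from .curvature import (
    DEFAULT_SPEED_GATE,
    MIN_GATED_SAMPLES,
    curvature_series,
    ioc,
    median_lc,
)
from .errors import (
    DegenerateSegmentError,
    InsufficientDataError,
    ReachSmoothError,
    SegmentationFailure,
)
from .kinematics import (
    DiffScheme,
    KinematicSeries,
    compute_kinematics,
    lowpass_filter,
    principal_axis_rotate,
)
from .segmentation import (
    DEFAULT_MIN_AMP_MM,
    DEFAULT_MIN_SAMPLES,
    DEFAULT_SEG_FRAC,
    Segment,
    filter_segments,
    segment_strokes,
)
from .trajectory_io import Trajectory, clip_window

#: normaliser constant C in MeanJ^2_0 = C * A^2 / d^6
DEFAULT_NORMALIZER = 360.0


@dataclass(frozen=True)
class AnalysisParams:
    """Every knob of the analysis pipeline, with the standard defaults.

    ``window_start_s``/``window_duration_s`` select the stable analysis
    window (duration ``None`` analyses the full recording; continuous
    30 s clinical recordings are conventionally windowed to 15 s).
    """

    window_start_s: float = 0.0
    window_duration_s: float | None = None
    cutoff_hz: float = 8.0
    filter_order: int = 4
    diff_scheme: DiffScheme = "forward"
    speed_gate_mm_s: float = DEFAULT_SPEED_GATE
    seg_frac: float = DEFAULT_SEG_FRAC
    min_amp_mm: float = DEFAULT_MIN_AMP_MM
    min_samples: int = DEFAULT_MIN_SAMPLES
    normalizer_const: float = DEFAULT_NORMALIZER
    rotate: bool = True


@dataclass(frozen=True)
class SmoothnessReport:
    """All scalar smoothness metrics of one session plus their provenance.

    ``mean_log_msj_ratio`` and ``ioc_mean`` are ``None`` when no segment
    survived the amplitude filter (continuous movement that could not be
    decomposed into strokes).
    """

    median_lc: float
    median_lj: float
    mean_log_msj_ratio: float | None
    per_segment_log_msj: list[float]
    n_segments_retained: int
    ioc_mean: float | None
    segments: list[Segment]
    params: AnalysisParams
    label: str = ""

    def to_dict(self) -> dict:
        """JSON-serialisable representation (stable field names)."""
        d = asdict(self)
        d["segments"] = [asdict(s) for s in self.segments]
        d["params"] = asdict(self.params)
        return d


def jerk_magnitude(kin: KinematicSeries) -> np.ndarray:
    """Euclidean norm of the jerk vector at every sample, mm/s^3."""
    return np.linalg.norm(kin.jerk_vec, axis=1)


def median_lj(
    kin: KinematicSeries, speed_gate_mm_s: float = DEFAULT_SPEED_GATE
) -> float:
    """Median of ln(J) over speed-gated samples (MedianLJ).

    Uses the same 50 mm/s tangential-velocity gate as MedianLC. Being
    un-normalised, MedianLJ confounds movement irregularity with speed;
    it is reported for comparison with the normalised jerk ratio.
    """
    j = jerk_magnitude(kin)
    mask = kin.speed > speed_gate_mm_s
    with np.errstate(divide="ignore"):
        vals = np.log(j[mask])
    vals = vals[np.isfinite(vals)]
    if len(vals) < MIN_GATED_SAMPLES:
        raise InsufficientDataError(
            f"only {len(vals)} usable samples above the {speed_gate_mm_s} mm/s "
            f"gate (need >= {MIN_GATED_SAMPLES})"
        )
    return float(np.median(vals))


def msj_ratio_segment(
    kin: KinematicSeries,
    seg: Segment,
    normalizer_const: float = DEFAULT_NORMALIZER,
) -> float:
    """Mean-squared-jerk ratio of one stroke.

    MeanJ^2 is the trapezoidal integral of J^2 over the segment samples
    [start, end) divided by the segment duration; the normaliser is
    ``normalizer_const * A^2 / d^6`` with the segment's endpoint
    amplitude A and duration d.
    """
    d, a = seg.duration_s, seg.amplitude_mm
    if d <= 0 or a <= 0:
        raise DegenerateSegmentError(
            f"segment duration {d} s / amplitude {a} mm must be positive"
        )
    j = jerk_magnitude(kin)[seg.start : seg.end]
    if len(j) < 2:
        raise DegenerateSegmentError("segment too short to integrate jerk")
    mean_j2 = float(np.trapezoid(j**2, dx=1.0 / kin.rate_hz)) / d
    return mean_j2 * d**6 / (normalizer_const * a**2)


def mean_log_msj_ratio(
    kin: KinematicSeries,
    segments: Sequence[Segment],
    normalizer_const: float = DEFAULT_NORMALIZER,
) -> tuple[float, list[float]]:
    """Session-level jerk score: mean of ln(MSJ ratio) over strokes.

    Returns the mean and the per-stroke values. Raises
    :class:`SegmentationFailure` when no stroke is available, mirroring
    participants whose continuous movement cannot be segmented.
    """
    if not segments:
        raise SegmentationFailure(
            "no retained movement segments; cannot normalise jerk"
        )
    logs = [
        float(np.log(msj_ratio_segment(kin, s, normalizer_const)))
        for s in segments
    ]
    return float(np.mean(logs)), logs


def _stage(name: str, exc: ReachSmoothError) -> ReachSmoothError:
    exc.args = (f"[{name}] {exc.args[0]}",) + exc.args[1:]
    return exc


def analyze(traj: Trajectory, params: AnalysisParams | None = None) -> SmoothnessReport:
    """Run the full smoothness analysis on one session.

    Pipeline: clip the analysis window -> 8 Hz zero-phase Butterworth
    filter -> principal-axis rotation -> velocity/acceleration/jerk ->
    curvature -> MedianLC & MedianLJ (speed-gated) -> stroke
    segmentation (10% of max speed, 100 mm amplitude floor) -> per-stroke
    MSJ ratios and IOC. Deterministic: the same input and parameters
    produce an identical report.
    """
    p = params or AnalysisParams()
    try:
        if p.window_duration_s is not None:
            traj = clip_window(traj, p.window_start_s, p.window_duration_s)
        elif p.window_start_s > 0:
            traj = clip_window(
                traj, p.window_start_s, traj.duration_s - p.window_start_s
            )
    except ReachSmoothError as exc:
        raise _stage("window", exc)
    try:
        traj = lowpass_filter(traj, p.cutoff_hz, p.filter_order)
    except ReachSmoothError as exc:
        raise _stage("filter", exc)
    if p.rotate:
        try:
            traj = principal_axis_rotate(traj)
        except ReachSmoothError as exc:
            raise _stage("rotate", exc)
    try:
        kin = compute_kinematics(traj, p.diff_scheme)
    except ReachSmoothError as exc:
        raise _stage("kinematics", exc)

    try:
        curv = curvature_series(kin, p.speed_gate_mm_s)
        mlc = median_lc(curv, kin, p.speed_gate_mm_s)
        mlj = median_lj(kin, p.speed_gate_mm_s)
    except ReachSmoothError as exc:
        raise _stage("metrics", exc)

    try:
        segs = segment_strokes(
            kin.speed, kin.rate_hz, p.seg_frac, p.min_samples, traj=traj
        )
        retained = filter_segments(segs, p.min_amp_mm)
    except ReachSmoothError as exc:
        raise _stage("segmentation", exc)

    if retained:
        mean_lmsj, per_seg = mean_log_msj_ratio(kin, retained, p.normalizer_const)
        ioc_mean = float(np.mean([ioc(traj, s) for s in retained]))
    else:
        mean_lmsj, per_seg, ioc_mean = None, [], None

    return SmoothnessReport(
        median_lc=mlc,
        median_lj=mlj,
        mean_log_msj_ratio=mean_lmsj,
        per_segment_log_msj=per_seg,
        n_segments_retained=len(retained),
        ioc_mean=ioc_mean,
        segments=retained,
        params=p,
        label=traj.label,
    )
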