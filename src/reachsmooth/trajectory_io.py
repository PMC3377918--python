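"""Reading, writing, validating, and windowing 3D trajectory files.

The canonical container is :class:`Trajectory`: an N x 3 array of hand
positions in millimetres sampled uniformly at ``rate_hz``. Files are plain
CSV with a mandatory header, either ``t,x,y,z`` (time in seconds) or
``x,y,z`` with the rate supplied by the caller. A ``_m`` suffix on the
coordinate headers (``x_m,y_m,z_m``) declares metres and triggers
conversion to mm on read. Millimetres are the single internal unit:
speed gates are in mm/s, curvature in 1/mm, amplitudes in mm.

Recordings with marker drop-outs must be pre-clipped to gap-free windows;
no interpolation is performed here, because every downstream derivative
assumes a uniform sample interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, RangeError, SamplingError, ValidationError

#: tolerated deviation of successive timestamps, as a fraction of 1/rate
UNIFORMITY_TOL = 0.01


@dataclass(frozen=True)
class Trajectory:
    """Uniformly sampled 3D position series.

    Parameters
    ----------
    positions
        N x 3 float array, coordinates in mm.
    rate_hz
        Sampling frequency in Hz (> 0).
    label
        Free-text identifier (file stem, condition name, ...).
    meta
        Arbitrary key/value annotations (arm side, session, ...).
    """

    positions: np.ndarray
    rate_hz: float
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValidationError(
                f"positions must be N x 3, got shape {pos.shape}"
            )
        if pos.shape[0] < 2:
            raise ValidationError("a trajectory needs at least 2 samples")
        if not np.isfinite(pos).all():
            bad = np.nonzero(~np.isfinite(pos).all(axis=1))[0]
            raise ValidationError(
                f"non-finite coordinates at rows {bad.tolist()[:20]}"
            )
        if not (self.rate_hz > 0 and np.isfinite(self.rate_hz)):
            raise ValidationError(f"rate_hz must be positive, got {self.rate_hz}")
        object.__setattr__(self, "positions", pos)

    @property
    def n_samples(self) -> int:
        return self.positions.shape[0]

    @property
    def duration_s(self) -> float:
        """Recording duration in seconds (N samples span N/rate seconds)."""
        return self.n_samples / self.rate_hz

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.n_samples) / self.rate_hz

    def with_positions(self, positions: np.ndarray) -> "Trajectory":
        """Copy of this trajectory with new positions, same metadata."""
        return replace(self, positions=positions)


def read_trajectory(path: str | Path, rate_hz: float | None = None) -> Trajectory:
    """Read a trajectory CSV.

    Accepts ``t,x,y,z`` (rate inferred from the time column, which must be
    uniform to within 1% of the sample interval) or ``x,y,z`` with
    ``rate_hz`` given. Coordinate columns suffixed ``_m`` are converted
    from metres to millimetres.

    Raises
    ------
    FormatError
        Missing/unrecognised columns, or 3-column file without a rate.
    SamplingError
        Non-uniform timestamps.
    ValidationError
        NaN rows or too few samples.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols

    scale = 1.0
    if {"x", "y", "z"} <= set(cols):
        axes = ["x", "y", "z"]
    elif {"x_m", "y_m", "z_m"} <= set(cols):
        axes = ["x_m", "y_m", "z_m"]
        scale = 1000.0  # metres -> mm
    else:
        raise FormatError(
            f"{path}: expected columns (t,)x,y,z or x_m,y_m,z_m; got {cols}"
        )

    time_col = next((c for c in ("t", "time", "t_s") if c in cols), None)
    pos = df[axes].to_numpy(dtype=float) * scale
    if np.isnan(pos).any():
        bad = np.nonzero(np.isnan(pos).any(axis=1))[0]
        raise ValidationError(
            f"{path}: NaN coordinates at rows {bad.tolist()[:20]}"
        )

    if time_col is not None:
        t = df[time_col].to_numpy(dtype=float)
        if len(t) < 2:
            raise ValidationError(f"{path}: need at least 2 samples")
        dt = np.diff(t)
        dt_med = float(np.median(dt))
        if dt_med <= 0:
            raise SamplingError(f"{path}: non-increasing timestamps")
        if np.any(np.abs(dt - dt_med) > UNIFORMITY_TOL * dt_med):
            worst = int(np.argmax(np.abs(dt - dt_med)))
            raise SamplingError(
                f"{path}: non-uniform timestamps (interval {dt[worst]:.6g} s "
                f"at row {worst} vs median {dt_med:.6g} s)"
            )
        inferred = 1.0 / dt_med
        # snap float jitter from the text round trip (200.00000000000003 -> 200)
        snapped = round(inferred, 6)
        if snapped > 0 and abs(inferred - snapped) <= 1e-9 * snapped:
            inferred = snapped
        if rate_hz is not None and abs(rate_hz - inferred) > UNIFORMITY_TOL * inferred:
            raise SamplingError(
                f"{path}: supplied rate {rate_hz} Hz contradicts time column "
                f"({inferred:.6g} Hz)"
            )
        rate = inferred
    else:
        if rate_hz is None:
            raise FormatError(
                f"{path}: no time column; supply rate_hz (e.g. --rate 200)"
            )
        rate = float(rate_hz)

    return Trajectory(positions=pos, rate_hz=rate, label=path.stem)


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as ``t,x,y,z`` CSV (seconds, mm).

    The round trip ``read_trajectory(write_trajectory(T))`` reproduces
    positions to <= 1e-9 mm and the rate exactly (times are emitted at
    full float precision).
    """
    path = Path(path)
    df = pd.DataFrame(
        {
            "t": traj.times,
            "x": traj.positions[:, 0],
            "y": traj.positions[:, 1],
            "z": traj.positions[:, 2],
        }
    )
    try:
        df.to_csv(path, index=False, float_format="%.17g")
    except OSError as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc


def clip_window(traj: Trajectory, start_s: float, duration_s: float) -> Trajectory:
    """Extract the analysis window ``[start_s, start_s + duration_s)``.

    Recordings are clipped to the stable, gap-free portion before
    analysis (15 s windows for continuous lap-to-mouth sessions in the
    reference protocol). Returns round(duration * rate) samples starting
    at round(start * rate).
    """
    if start_s < 0 or duration_s <= 0:
        raise RangeError(f"invalid window start={start_s}s duration={duration_s}s")
    i0 = round(start_s * traj.rate_hz)
    n = round(duration_s * traj.rate_hz)
    if i0 + n > traj.n_samples:
        raise RangeError(
            f"window [{start_s}, {start_s + duration_s}) s exceeds recording "
            f"of {traj.duration_s:.3f} s"
        )
    return replace(traj, positions=traj.positions[i0 : i0 + n])
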