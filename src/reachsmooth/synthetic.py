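"""Synthetic reach-session generator.

Emulates the repetitive lap -> mouth -> lap drinking movement used to
assess proximal arm function: alternating minimum-jerk strokes along a
bowed 3D path, separated by short rests, repeated for a configurable
number of cycles at comfortable / fast / slow pacing. Two corruption
mechanisms turn a clean healthy session into a paretic-like one:

* **sub-movements** — short corrective minimum-jerk pulses superimposed
  on each stroke at random onsets and directions (the standard
  sub-movement superposition account of jerky post-stroke reaching);
  ``corruption_level`` is the expected number of pulses per stroke;
* **sensor noise** — i.i.d. Gaussian noise per axis, emulating optical
  marker jitter.

The path is bowed out of the movement plane (``arc_height_frac``) so
even a clean session has finite, well-defined curvature, as real
lap-to-mouth arcs do. Rests hold the endpoint exactly still (plus
noise), guaranteeing clean segmentation boundaries. Everything is
deterministic under ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .trajectory_io import Trajectory

#: out-of-plane bow split between the two transverse axes (unit vector)
_BOW_Y, _BOW_Z = 0.33, 0.944


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one simulated session.

    Defaults model a comfortable-pace healthy session: 400 mm
    lap-to-mouth amplitude, 1 s strokes, 0.3 s rests, 8 cycles at
    200 Hz, a bow of 15% of the amplitude, 0.5 mm marker noise, no
    sub-movement corruption.
    """

    amplitude_mm: float = 400.0
    stroke_duration_s: float = 1.0
    rest_s: float = 0.3
    n_cycles: int = 8
    rate_hz: float = 200.0
    arc_height_frac: float = 0.15
    corruption_level: float = 0.0
    submovement_amp_frac: float = 0.25
    submovement_dur_s: float = 0.25
    noise_sd_mm: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.amplitude_mm, self.stroke_duration_s, self.rate_hz) <= 0:
            raise ParameterError("amplitude, stroke duration and rate must be > 0")
        if self.rest_s < 0 or self.noise_sd_mm < 0 or self.corruption_level < 0:
            raise ParameterError("rest, noise sd and corruption level must be >= 0")
        if self.n_cycles < 1:
            raise ParameterError("need at least one movement cycle")

    @property
    def session_duration_s(self) -> float:
        """2 strokes + 2 rests per cycle."""
        return self.n_cycles * (2 * self.stroke_duration_s + 2 * self.rest_s)


def min_jerk_position(tau: np.ndarray) -> np.ndarray:
    """Normalised minimum-jerk position profile 10 tau^3 - 15 tau^4 + 6 tau^5."""
    return tau**3 * (10.0 - 15.0 * tau + 6.0 * tau**2)


def min_jerk_profile(amplitude_mm: float, duration_s: float, rate_hz: float) -> np.ndarray:
    """One-dimensional minimum-jerk stroke, endpoints inclusive.

    The quintic x(tau) = A (10 tau^3 - 15 tau^4 + 6 tau^5) is the unique
    point-to-point movement minimising integrated squared jerk with zero
    endpoint velocity and acceleration; its peak speed is 15/8 * A/d.
    """
    if amplitude_mm <= 0 or duration_s <= 0 or rate_hz <= 0:
        raise ParameterError("amplitude, duration and rate must be positive")
    n = round(duration_s * rate_hz)
    tau = np.arange(n + 1) / n
    return amplitude_mm * min_jerk_position(tau)


def _bowed_path(s: np.ndarray, amplitude_mm: float, arc_height_frac: float) -> np.ndarray:
    """Map arc-length parameter s in [0, 1] to 3D positions on the stroke path.

    The path is a circular arc of chord ``amplitude_mm`` and sagitta
    ``arc_height_frac * amplitude_mm``, bowed out of the movement axis
    along a fixed oblique direction so the session is genuinely 3D. A
    circular arc has constant curvature along the whole stroke, so the
    clean session has a single well-defined -ln(kappa) everywhere --
    the idealisation of a real lap-to-mouth arc.
    """
    a, h = amplitude_mm, arc_height_frac * amplitude_mm
    if h <= 0:
        return np.column_stack([a * s, np.zeros_like(s), np.zeros_like(s)])
    r = (a * a / 4.0 + h * h) / (2.0 * h)  # radius from chord and sagitta
    phi = np.arcsin(a / (2.0 * r))  # half-angle subtended by the chord
    ang = (2.0 * s - 1.0) * phi
    x = a / 2.0 + r * np.sin(ang)
    bow = r * np.cos(ang) - (r - h)
    return np.column_stack([x, _BOW_Y * bow, _BOW_Z * bow])


def _submovement_pulse(t_local: np.ndarray, onset: float, dur: float) -> np.ndarray:
    """There-and-back minimum-jerk bump: 0 -> 1 -> 0 over [onset, onset+dur]."""
    tau = np.clip((t_local - onset) / dur, 0.0, 1.0)
    out_leg = min_jerk_position(np.clip(2 * tau, 0, 1))
    back_leg = min_jerk_position(np.clip(2 * tau - 1, 0, 1))
    return out_leg - back_leg


def generate_session(cfg: SyntheticConfig) -> Trajectory:
    """Simulate one repetitive reach session.

    The session is assembled piecewise on an exact common time grid:
    forward stroke, rest, backward stroke, rest, repeated ``n_cycles``
    times, plus the final endpoint sample — so a 5-cycle session of 1 s
    strokes and 0.3 s rests spans exactly 13 s (2601 samples at 200 Hz).
    """
    rate = cfg.rate_hz
    n_stroke = round(cfg.stroke_duration_s * rate)
    n_rest = round(cfg.rest_s * rate)
    if n_stroke < 2:
        raise ParameterError("stroke too short for the sampling rate")

    pieces: list[np.ndarray] = []
    stroke_idx = 0
    for _ in range(cfg.n_cycles):
        for forward in (True, False):
            tau = np.arange(n_stroke) / n_stroke  # endpoint sample owned by next piece
            s = min_jerk_position(tau)
            if not forward:
                s = 1.0 - s
            pos = _bowed_path(s, cfg.amplitude_mm, cfg.arc_height_frac)
            if cfg.corruption_level > 0:
                t_local = tau * cfg.stroke_duration_s
                pos = pos + _submovements(cfg, stroke_idx, t_local)
            pieces.append(pos)
            stroke_idx += 1
            rest_point = _bowed_path(
                np.array([1.0 if forward else 0.0]), cfg.amplitude_mm,
                cfg.arc_height_frac,
            )
            if n_rest:
                pieces.append(np.repeat(rest_point, n_rest, axis=0))
    pieces.append(_bowed_path(np.array([0.0]), cfg.amplitude_mm, cfg.arc_height_frac))
    positions = np.concatenate(pieces, axis=0)
    if cfg.noise_sd_mm > 0:
        # dedicated stream: the noise realisation of a given seed is the
        # same at every corruption level (common random numbers)
        noise_rng = np.random.default_rng([cfg.seed, _NOISE_STREAM])
        positions = positions + noise_rng.normal(0.0, cfg.noise_sd_mm, positions.shape)
    return Trajectory(
        positions=positions,
        rate_hz=rate,
        label=f"synthetic(seed={cfg.seed})",
        meta={"config": cfg},
    )


#: stream tag separating the noise RNG from the per-stroke pulse RNGs
_NOISE_STREAM = 10**6


def _submovements(
    cfg: SyntheticConfig, stroke_idx: int, t_local: np.ndarray
) -> np.ndarray:
    """Sum of corrective pulses for one stroke (possibly zero pulses).

    Pulses are events of a unit-rate birth process truncated at
    ``corruption_level``, so the pulse count per stroke is
    Poisson(corruption_level) and, for a fixed seed, the pulses at a
    lower level are exactly a subset of those at a higher level. This
    coupling lets corruption-level sweeps compare like with like: raising
    the level adds corrective pulses to the same underlying session
    instead of redrawing everything.
    """
    extra = np.zeros((len(t_local), 3))
    d_stroke = cfg.stroke_duration_s
    rng = np.random.default_rng([cfg.seed, stroke_idx])
    birth = rng.exponential(1.0)
    while birth <= cfg.corruption_level:
        amp = cfg.submovement_amp_frac * cfg.amplitude_mm * rng.uniform(0.3, 1.0)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        dur = min(cfg.submovement_dur_s, d_stroke)
        onset = rng.uniform(0.0, max(d_stroke - dur, 0.0))
        extra += amp * np.outer(_submovement_pulse(t_local, onset, dur), direction)
        birth += rng.exponential(1.0)
    return extra


_PRESETS = {
    "comfortable": {},
    "fast": {"stroke_duration_s": 0.5},
    "slow": {"stroke_duration_s": 2.5},
    "paretic_mild": {"corruption_level": 1.0, "noise_sd_mm": 1.0},
    "paretic_severe": {"corruption_level": 3.0, "noise_sd_mm": 1.0},
}


def condition_preset(name: str, seed: int = 0) -> SyntheticConfig:
    """Named study conditions.

    ``comfortable`` / ``fast`` / ``slow`` vary stroke duration (1.0 /
    0.5 / 2.5 s) at zero corruption, mirroring self-paced, maximum-speed
    and deliberately slow healthy movement; ``paretic_mild`` /
    ``paretic_severe`` add sub-movement corruption (1 / 3 expected
    pulses per stroke) and heavier 1.0 mm noise. The paretic presets are
    calibration points for the metric's ordering behaviour, not fitted
    patient models.
    """
    try:
        kwargs = _PRESETS[name]
    except KeyError:
        raise ParameterError(
            f"unknown preset {name!r}; choose from {sorted(_PRESETS)}"
        ) from None
    return SyntheticConfig(seed=seed, **kwargs)
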