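import numpy as np
import pytest

from reachsmooth import SyntheticConfig, Trajectory, generate_session, min_jerk_profile


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_circle(radius_mm=100.0, period_s=3.0, rate_hz=200.0, turns=2.0):
    """Planar circle traversed at constant angular rate."""
    n = round(turns * period_s * rate_hz)
    t = np.arange(n) / rate_hz
    w = 2 * np.pi / period_s
    pos = np.column_stack(
        [radius_mm * np.cos(w * t), radius_mm * np.sin(w * t), np.zeros(n)]
    )
    return Trajectory(positions=pos, rate_hz=rate_hz, label="circle")


def make_line(speed_mm_s=200.0, duration_s=2.0, rate_hz=200.0, direction=(1.0, 2.0, -0.5)):
    """Straight line at constant velocity.

    Built as integer multiples of an exactly representable per-sample
    step so repeated differencing is exact (zero jerk, not epsilon jerk).
    """
    d = np.asarray(direction, dtype=float)
    # scale the step by a power of two so every coordinate increment is
    # exactly representable; the realised speed is within sqrt(2) of the
    # requested one, which is all the tests need
    target = speed_mm_s / rate_hz / np.linalg.norm(d)
    step = d * 2.0 ** round(np.log2(target))
    n = round(duration_s * rate_hz)
    return Trajectory(
        positions=np.outer(np.arange(n, dtype=float), step),
        rate_hz=rate_hz,
        label="line",
    )


def make_helix(r_mm=50.0, c_mm=50.0, rate_hz=200.0, omega=2.0, duration_s=6.0):
    """Circular helix x=r cos(th), y=r sin(th), z=c th; curvature r/(r^2+c^2)."""
    t = np.arange(round(duration_s * rate_hz)) / rate_hz
    th = omega * t
    pos = np.column_stack([r_mm * np.cos(th), r_mm * np.sin(th), c_mm * th])
    return Trajectory(positions=pos, rate_hz=rate_hz, label="helix")


def make_stroke(amplitude_mm=300.0, duration_s=1.0, rate_hz=200.0):
    """Straight-line minimum-jerk stroke along x."""
    x = min_jerk_profile(amplitude_mm, duration_s, rate_hz)
    pos = np.column_stack([x, np.zeros_like(x), np.zeros_like(x)])
    return Trajectory(positions=pos, rate_hz=rate_hz, label="stroke")


def random_rotation(rng):
    """Haar-ish random proper rotation via QR."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


@pytest.fixture(scope="session")
def clean_session():
    """Noiseless, uncorrupted 5-cycle comfortable session."""
    return generate_session(SyntheticConfig(n_cycles=5, noise_sd_mm=0.0, seed=1))


@pytest.fixture(scope="session")
def default_session():
    """Default comfortable session with sensor noise, seed 1."""
    from reachsmooth import condition_preset

    return generate_session(condition_preset("comfortable", seed=1))
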