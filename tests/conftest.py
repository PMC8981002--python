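import numpy as np
import pytest

from wristfall import AccelTrace, SubjectProfile


def mag_trace(mag, rate=100.0, t0=0.0, axis=(0.0, 0.0, 1.0)) -> AccelTrace:
    """Build a trace whose vector magnitude equals the given scalar series."""
    mag = np.asarray(mag, dtype=float)
    u = np.asarray(axis) / np.linalg.norm(axis)
    return AccelTrace(rate=rate, t0=t0, samples=mag[:, None] * u[None, :])


def piecewise_fall_trace(spike_g: float, rate: float = 100.0,
                         dip_g: float = 0.3, dip_s: float = 0.3,
                         rest_ripple: float = 0.02) -> AccelTrace:
    """The canonical constructed candidate: 5 s at 1 g, a free-fall dip, a
    short spike, then a quiet plateau."""
    n_rest = int(3.0 * rate)
    mag = np.concatenate([
        np.full(int(5.0 * rate), 1.0),
        np.full(int(dip_s * rate), dip_g),
        np.full(int(0.05 * rate), spike_g),
        1.0 + rest_ripple * np.sin(np.linspace(0, 40 * np.pi, n_rest)),
    ])
    return mag_trace(mag, rate=rate)


@pytest.fixture
def profile() -> SubjectProfile:
    return SubjectProfile(height_cm=170.0, weight_kg=70.0, watch_side="left")
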