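import numpy as np
import pytest

from synkin import SimConfig, TimeSeries, generate_ground_truth, synthesize_session


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_series():
    """A 3-channel, 50-sample series at 100 Hz with distinct channels."""
    t = np.arange(50) / 100.0
    values = np.vstack([np.sin(2 * np.pi * 2 * t), np.cos(2 * np.pi * 2 * t), t])
    return TimeSeries(values, 100.0, ("a", "b", "c"))


@pytest.fixture(scope="session")
def tiny_session():
    """A small but complete synthetic session (2 set types x 3 reps)."""
    config = SimConfig(seed=42, n_set_types=2, n_reps=3)
    truth = generate_ground_truth(config)
    return truth, synthesize_session(truth, config), config


def bump_trace(
    onsets,
    durations,
    amplitude=80.0,
    baseline=20.0,
    total_s=None,
    rate_hz=100.0,
):
    """Raised-cosine flexion bumps with known onset/offset times (seconds)."""
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    durations = np.broadcast_to(
        np.asarray(durations, dtype=float), onsets.shape
    )
    if total_s is None:
        total_s = onsets[-1] + durations[-1] + 2.0
    n = int(round(total_s * rate_hz))
    x = np.full(n, baseline)
    for onset, dur in zip(onsets, durations):
        m = int(round(dur * rate_hz))
        i0 = int(round(onset * rate_hz))
        u = np.linspace(0.0, 1.0, m)
        x[i0 : i0 + m] += amplitude * 0.5 * (1.0 - np.cos(2.0 * np.pi * u))
    return x
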