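import numpy as np
import pytest

from phaseconn import (
    ConnectivityMatrix,
    EEGRecording,
    SynthCohortConfig,
    gen_connectivity_matrix,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sine_recording():
    """Builder for multichannel sinusoid recordings."""

    def build(freqs_hz, fs=400.0, duration=10.0, phases=None, labels=None):
        t = np.arange(0.0, duration, 1.0 / fs)
        phases = phases if phases is not None else [0.0] * len(freqs_hz)
        data = np.stack(
            [np.sin(2 * np.pi * f * t + p) for f, p in zip(freqs_hz, phases)]
        )
        labels = labels or [f"ch{i}" for i in range(len(freqs_hz))]
        return EEGRecording(data=data, fs=fs, channel_labels=labels)

    return build


@pytest.fixture
def uniform_matrix():
    """Builder for constant-weight connectivity matrices."""

    def build(n, value, labels=None):
        w = np.full((n, n), float(value))
        np.fill_diagonal(w, 0.0)
        return ConnectivityMatrix(weights=w, channel_labels=labels or [f"ch{i}" for i in range(n)])

    return build


@pytest.fixture
def control_matrix():
    """A 21-node control-like matrix at the reference mean strength."""
    cfg = SynthCohortConfig(
        target_mean_strength=0.5575, edge_value_range=(0.1, 0.95), seed=101
    )
    return gen_connectivity_matrix(cfg)
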