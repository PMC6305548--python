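import numpy as np
import pytest

from febci.recording import CHANNELS, Recording
from febci.signal_model import SyntheticConfig, TrialTiming


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def timing():
    return TrialTiming()


@pytest.fixture
def gen_config():
    return SyntheticConfig()


@pytest.fixture
def sine_recording():
    """Two-tone 4-channel recording at 250 Hz (2 Hz + 20 Hz)."""
    fs = 250.0
    t = np.arange(1000) / fs
    x = np.sin(2 * np.pi * 2 * t) + 0.8 * np.sin(2 * np.pi * 20 * t)
    samples = np.vstack([x, 0.9 * x, 1.1 * x, x + 0.1])
    return Recording(samples, fs, CHANNELS)


def brute_force_sampen(series, m, r):
    """Independent exhaustive template-counting oracle for SampEn.

    Counts pairs of length-m and length-(m+1) templates within Chebyshev
    distance r over the same N-m starting points, self-matches excluded.
    """
    x = list(map(float, series))
    N = len(x)
    B = A = 0
    for i in range(N - m):
        for j in range(i + 1, N - m):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                B += 1
            if max(abs(x[i + k] - x[j + k]) for k in range(m + 1)) <= r:
                A += 1
    if B == 0:
        raise ValueError("oracle: B == 0")
    if A == 0:
        return float("inf")
    import math

    return -math.log(A / B)
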