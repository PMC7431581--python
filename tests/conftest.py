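"""Shared fixtures: small synthetic recordings and independent SE oracles."""

from __future__ import annotations

import numpy as np
import pytest

from cpvi import SimConfig, SimEvent, VentMode, WaveformRecording, simulate_recording


def naive_sample_entropy(x, m: int, r_abs: float) -> float:
    """Independent O(N^2) template-counting SampEn (the reference oracle).

    Direct transcription of the definition: template vectors of length m and
    m+1 starting at i = 1..N-m, Chebyshev distance, self-matches excluded.
    Deliberately separate from the run-length kernel under test.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    from numpy.lib.stride_tricks import sliding_window_view

    w_m = sliding_window_view(x, m)[: n - m]
    w_m1 = sliding_window_view(x, m + 1)[: n - m]
    b = a = 0
    for i in range(n - m):
        d_m = np.max(np.abs(w_m - w_m[i]), axis=1)
        d_m1 = np.max(np.abs(w_m1 - w_m1[i]), axis=1)
        b += int(np.sum(d_m <= r_abs)) - 1  # minus the self-match
        a += int(np.sum(d_m1 <= r_abs)) - 1
    if a <= 0 or b <= 0:
        return float("nan")
    return float(-np.log(a / b))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def short_recording() -> WaveformRecording:
    """30 s of a clean quasi-sinusoidal two-channel signal at 200 Hz."""
    t = np.arange(0, 30.0, 1.0 / 200.0)
    flow = 40.0 * np.sin(2 * np.pi * t / 4.0)
    paw = 10.0 + 5.0 * np.sin(2 * np.pi * t / 4.0 - 0.5)
    return WaveformRecording(flow=flow, paw=paw, rate=200.0, subject_id="sine")


@pytest.fixture(scope="session")
def quiet_recording() -> WaveformRecording:
    """A 30-min event-free PSV recording."""
    cfg = SimConfig(mode=VentMode.PSV, base_rr=16.0, duration_min=30.0, seed=7,
                    subject_id="quiet")
    rec, _, _ = simulate_recording(cfg)
    return rec


@pytest.fixture(scope="session")
def eventful_recording():
    """A 60-min PSV recording with one strong asynchrony cluster (seg 2)."""
    cfg = SimConfig(mode=VentMode.PSV, base_rr=16.0, duration_min=60.0, seed=11,
                    subject_id="eventful",
                    events=[SimEvent("asynchrony_cluster", 33.0, 42.0,
                                     asynchrony_fraction=0.7)])
    return simulate_recording(cfg)
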