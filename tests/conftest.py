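"""Shared fixtures: simulated recordings are expensive, so build them once."""

import numpy as np
import pytest

from noxlux import (
    ActivityGenParams,
    EEGGenParams,
    SDProtocol,
    detect_artifacts,
    epoch_and_fft,
    simulate_activity,
    simulate_recording,
)


@pytest.fixture(scope="session")
def control_trace():
    """15-day entrained control activity trace (pink fractal component)."""
    return simulate_activity(ActivityGenParams(seed=3))


@pytest.fixture(scope="session")
def baseline_recording():
    """One baseline day of EEG/EMG with its ground-truth hypnogram."""
    rec, truth = simulate_recording(EEGGenParams(days=1, seed=5))
    return rec, truth


@pytest.fixture(scope="session")
def baseline_spectra(baseline_recording):
    rec, _ = baseline_recording
    return detect_artifacts(epoch_and_fft(rec), rec)


@pytest.fixture(scope="session")
def sd_recording():
    """Baseline day + sleep-deprivation day (6-h forced wake from ZT0)."""
    rec, truth = simulate_recording(
        EEGGenParams(days=2, seed=11), sd=SDProtocol(0.0, 6.0)
    )
    return rec, truth


@pytest.fixture(scope="session")
def sd_spectra(sd_recording):
    rec, _ = sd_recording
    return detect_artifacts(epoch_and_fft(rec), rec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
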