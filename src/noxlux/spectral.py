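"""Epoch-wise EEG spectral analysis (0.25–25 Hz, 4-s epochs).

One rectangular-window FFT per 4-s epoch, scaled so the sum over all
non-DC bins equals the epoch's variance (discrete Parseval); bins above
25 Hz are dropped after scaling.  Downstream helpers compute band
powers, per-vigilance-state mean spectra and the 2-h slow-wave-activity
(SWA) timecourse in NREM sleep.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    NREM,
    SAMPLES_PER_EPOCH,
    Hypnogram,
    SignalRecording,
    WAKE,
    REM,
)

__all__ = [
    "EpochSpectra",
    "BandDefinition",
    "SWATimecourse",
    "DELTA",
    "THETA",
    "SWA_BROAD",
    "SWA_DELTA",
    "epoch_and_fft",
    "detect_artifacts",
    "band_power",
    "state_spectra",
    "swa_timecourse",
]

FREQ_BINS_HZ = np.arange(1, 101) * 0.25  # 0.25 … 25.0 Hz


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band with inclusive edges on the 0.25-Hz bin grid."""

    name: str
    lo_hz: float
    hi_hz: float

    def __post_init__(self) -> None:
        if not (0.25 <= self.lo_hz < self.hi_hz <= 25.0):
            raise ValueError(f"band {self.name}: require 0.25 <= lo < hi <= 25.0")
        for edge in (self.lo_hz, self.hi_hz):
            if abs(edge / 0.25 - round(edge / 0.25)) > 1e-9:
                raise ValueError(f"band {self.name}: edges must be multiples of 0.25 Hz")

    def mask(self) -> np.ndarray:
        return (FREQ_BINS_HZ >= self.lo_hz - 1e-9) & (FREQ_BINS_HZ <= self.hi_hz + 1e-9)


# Canonical bands.  Two SWA presets ship because study conventions vary
# between a 0.5-Hz and a 0.75-Hz lower edge.
DELTA = BandDefinition("delta", 0.75, 4.0)
THETA = BandDefinition("theta", 6.25, 9.0)
SWA_BROAD = BandDefinition("swa", 0.5, 4.0)
SWA_DELTA = BandDefinition("swa_delta", 0.75, 4.0)


@dataclass
class EpochSpectra:
    """Per-epoch power spectra (µV² per 0.25-Hz bin) plus EMG RMS."""

    power: np.ndarray  # (n_epochs, 100)
    emg_rms: np.ndarray  # (n_epochs,)
    dropped_power: np.ndarray  # per-epoch power above 25 Hz (Parseval remainder)
    artifact: np.ndarray = None  # type: ignore[assignment]
    epoch_seconds: float = 4.0
    start_zt_h: float = 0.0
    freq_bins_hz: np.ndarray = field(default_factory=lambda: FREQ_BINS_HZ.copy())

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        if self.power.ndim != 2 or self.power.shape[1] != 100:
            raise ValueError("power must be (n_epochs, 100)")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")
        if self.artifact is None:
            self.artifact = np.zeros(self.power.shape[0], dtype=bool)

    @property
    def n_epochs(self) -> int:
        return int(self.power.shape[0])

    @property
    def zt_h(self) -> np.ndarray:
        return self.start_zt_h + np.arange(self.n_epochs) * self.epoch_seconds / 3600.0


@dataclass
class SWATimecourse:
    """Mean NREM slow-wave power per ZT-aligned clock bin.

    Bins with no artifact-free NREM epoch are NaN, never zero.
    """

    bin_start_zt_h: np.ndarray
    swa: np.ndarray
    n_epochs: np.ndarray
    bin_hours: float = 2.0
    band: BandDefinition = SWA_BROAD


def epoch_and_fft(recording: SignalRecording) -> EpochSpectra:
    """Compute per-4-s-epoch power spectra and integrated EMG values.

    Power scaling is exact Parseval: for each epoch the sum of all
    non-DC bin powers (retained 0.25–25 Hz plus the dropped remainder
    up to 64 Hz) equals the epoch's mean squared deviation.
    """
    if recording.sample_rate_hz != 128:
        raise ValueError(f"expected 128 samples/s, got {recording.sample_rate_hz}")
    if not np.all(np.isfinite(recording.eeg)) or not np.all(np.isfinite(recording.emg)):
        raise ValueError("non-finite samples in recording")
    n_epochs = recording.n_epochs
    if n_epochs < 1:
        raise ValueError("recording shorter than one epoch")

    eeg = recording.eeg.reshape(n_epochs, SAMPLES_PER_EPOCH)
    spec = np.fft.rfft(eeg, axis=1)
    n = SAMPLES_PER_EPOCH
    # One-sided power per bin; DC excluded, Nyquist not doubled.
    p = (np.abs(spec) ** 2) * (2.0 / n**2)
    p[:, 0] /= 2.0
    p[:, -1] /= 2.0
    power = p[:, 1:101]
    dropped = p[:, 101:].sum(axis=1)

    emg = recording.emg.reshape(n_epochs, SAMPLES_PER_EPOCH)
    emg_rms = np.sqrt((emg**2).mean(axis=1))
    return EpochSpectra(
        power=power,
        emg_rms=emg_rms,
        dropped_power=dropped,
        start_zt_h=recording.start_zt_h,
    )


def detect_artifacts(
    spectra: EpochSpectra,
    recording: SignalRecording,
    k: float = 6.0,
    flat_floor: float = 1e-12,
) -> EpochSpectra:
    """Flag artifact epochs in place (flags annotate, never delete).

    An epoch is flagged when its EEG peak amplitude exceeds ``k`` robust
    standard deviations (1.4826 * MAD) of the whole recording, or when
    it is flatline (variance below ``flat_floor``).
    """
    eeg = recording.eeg.reshape(-1, SAMPLES_PER_EPOCH)
    if eeg.shape[0] != spectra.n_epochs:
        raise ValueError("recording and spectra have different epoch counts")
    med = np.median(recording.eeg)
    robust_sd = 1.4826 * np.median(np.abs(recording.eeg - med))
    peak = np.abs(eeg - med).max(axis=1)
    variance = eeg.var(axis=1)
    if robust_sd <= 0:
        flags = np.ones(spectra.n_epochs, dtype=bool)  # flat recording
    else:
        flags = (peak > k * robust_sd) | (variance < flat_floor)
    spectra.artifact = flags
    return spectra


def band_power(spectra: EpochSpectra, band: BandDefinition) -> np.ndarray:
    """Per-epoch power summed over a band; artifact epochs yield NaN."""
    mask = band.mask()
    out = spectra.power[:, mask].sum(axis=1)
    out = out.astype(float)
    out[spectra.artifact] = np.nan
    return out


def state_spectra(
    spectra: EpochSpectra,
    hyp: Hypnogram,
    normalise: bool = False,
) -> dict[int, np.ndarray]:
    """Mean spectrum (all 100 bins) over artifact-free epochs per state.

    A state with no artifact-free epoch maps to an all-NaN spectrum.
    With ``normalise`` each spectrum is divided by the recording's mean
    total power over artifact-free epochs (an opt-in, since absolute-vs-
    normalised reporting conventions differ between studies).
    """
    if hyp.n_epochs != spectra.n_epochs:
        raise ValueError("hypnogram and spectra have different epoch counts")
    good = ~spectra.artifact
    scale = 1.0
    if normalise:
        total = spectra.power[good].sum(axis=1).mean()
        if total > 0:
            scale = 1.0 / total
    out: dict[int, np.ndarray] = {}
    for state in (WAKE, NREM, REM):
        sel = good & (hyp.states == state)
        if not np.any(sel):
            out[state] = np.full(100, np.nan)
        else:
            out[state] = spectra.power[sel].mean(axis=0) * scale
    return out


def swa_timecourse(
    spectra: EpochSpectra,
    hyp: Hypnogram,
    band: BandDefinition = SWA_BROAD,
    bin_hours: float = 2.0,
) -> SWATimecourse:
    """Mean NREM slow-wave power per ZT-aligned ``bin_hours`` clock bin.

    Epochs are assigned to half-open bins [start, start + bin_hours)
    anchored at the recording's start ZT; bins without artifact-free
    NREM epochs (e.g. during enforced waking) are NaN.
    """
    if hyp.n_epochs != spectra.n_epochs:
        raise ValueError("hypnogram and spectra have different epoch counts")
    bp = band_power(spectra, band)
    zt = spectra.zt_h
    n_bins = int(np.ceil((zt[-1] + spectra.epoch_seconds / 3600.0 - spectra.start_zt_h) / bin_hours - 1e-9))
    idx = np.floor((zt - spectra.start_zt_h) / bin_hours + 1e-12).astype(int)
    starts = spectra.start_zt_h + np.arange(n_bins) * bin_hours
    swa = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    sel = (hyp.states == NREM) & ~spectra.artifact
    for b in range(n_bins):
        use = sel & (idx == b)
        counts[b] = int(use.sum())
        if counts[b]:
            swa[b] = np.nanmean(bp[use])
    return SWATimecourse(
        bin_start_zt_h=starts, swa=swa, n_epochs=counts, bin_hours=bin_hours, band=band
    )
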