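"""Shared data containers for the rest-activity / sleep-EEG pipeline.

All timing is expressed in zeitgeber time (ZT): hours since lights-on,
so ZT0 = light onset and, for a 12:12 schedule, ZT12 = onset of the dark
(or dim-light) phase.  Containers are thin dataclasses around numpy
arrays; they validate their invariants on construction and are otherwise
passive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta

import numpy as np

__all__ = [
    "LightSchedule",
    "ActivityTrace",
    "SignalRecording",
    "Hypnogram",
    "WAKE",
    "NREM",
    "REM",
    "STATE_LABELS",
    "EPOCH_SECONDS",
    "SAMPLE_RATE_HZ",
    "SAMPLES_PER_EPOCH",
]

# Vigilance states are stored as small integers throughout.
WAKE, NREM, REM = 0, 1, 2
STATE_LABELS = ("W", "N", "R")

# Epoching constants: 4-s epochs of 128 Hz signal.
EPOCH_SECONDS = 4
SAMPLE_RATE_HZ = 128
SAMPLES_PER_EPOCH = EPOCH_SECONDS * SAMPLE_RATE_HZ  # 512


@dataclass(frozen=True)
class LightSchedule:
    """A 12:12 light:dark (or light:dim-light) cycle.

    ``night_lux`` = 0 describes a standard light:dark (LD) schedule;
    a small positive value (e.g. 5 lux) describes dim-light-at-night
    (DLAN).  Lux values are labels carried through to reports; nothing
    downstream models phototransduction.
    """

    lights_on_clock: str = "10:00"
    light_lux: float = 75.0
    night_lux: float = 0.0
    cycle_hours: float = 24.0

    def __post_init__(self) -> None:
        if not (0 <= self.night_lux < self.light_lux):
            raise ValueError(
                f"require 0 <= night_lux < light_lux, got {self.night_lux}/{self.light_lux}"
            )
        if self.cycle_hours <= 0:
            raise ValueError("cycle_hours must be positive")

    @property
    def half_hours(self) -> float:
        """Duration of each phase; the cycle splits exactly in half."""
        return self.cycle_hours / 2.0

    def is_dark(self, zt_h: np.ndarray | float) -> np.ndarray | bool:
        """True where a ZT hour falls in the dark/dim half [ZT12, ZT24)."""
        return (np.asarray(zt_h) % self.cycle_hours) >= self.half_hours

    def lights_on_datetime(self, day0: str = "2020-01-01") -> datetime:
        hh, mm = (int(p) for p in self.lights_on_clock.split(":"))
        return datetime.fromisoformat(day0) + timedelta(hours=hh, minutes=mm)


@dataclass
class ActivityTrace:
    """Binned locomotor counts anchored to a light schedule.

    ``counts[i]`` covers ZT hours
    ``[start_zt_h + i*bin_seconds/3600, start_zt_h + (i+1)*bin_seconds/3600)``.
    """

    counts: np.ndarray
    bin_seconds: float = 60.0
    start_zt_h: float = 0.0
    schedule: LightSchedule = field(default_factory=LightSchedule)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1 or self.counts.size == 0:
            raise ValueError("counts must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.counts)):
            raise ValueError("counts contain non-finite values; impute or drop upstream")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.bin_seconds <= 0:
            raise ValueError("bin_seconds must be positive")

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)

    @property
    def duration_h(self) -> float:
        return self.n_bins * self.bin_seconds / 3600.0

    @property
    def zt_h(self) -> np.ndarray:
        """ZT hour of each bin start."""
        return self.start_zt_h + np.arange(self.n_bins) * self.bin_seconds / 3600.0

    def with_counts(self, counts: np.ndarray, bin_seconds: float | None = None) -> "ActivityTrace":
        return replace(
            self,
            counts=counts,
            bin_seconds=self.bin_seconds if bin_seconds is None else bin_seconds,
        )


@dataclass
class SignalRecording:
    """Raw EEG + EMG, both in microvolts at 128 samples/s."""

    eeg: np.ndarray
    emg: np.ndarray
    start_zt_h: float = 0.0
    schedule: LightSchedule = field(default_factory=LightSchedule)
    sample_rate_hz: float = float(SAMPLE_RATE_HZ)

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg, dtype=float)
        self.emg = np.asarray(self.emg, dtype=float)
        if self.eeg.shape != self.emg.shape or self.eeg.ndim != 1:
            raise ValueError("eeg and emg must be 1-D arrays of the same length")
        if self.eeg.size % SAMPLES_PER_EPOCH != 0:
            raise ValueError(
                f"signal length {self.eeg.size} is not a whole number of "
                f"{EPOCH_SECONDS}-s epochs ({SAMPLES_PER_EPOCH} samples)"
            )

    @property
    def n_epochs(self) -> int:
        return self.eeg.size // SAMPLES_PER_EPOCH

    @property
    def duration_h(self) -> float:
        return self.eeg.size / self.sample_rate_hz / 3600.0


@dataclass
class Hypnogram:
    """Per-epoch vigilance states (integer codes WAKE/NREM/REM).

    Every epoch carries a state even when artifact-flagged: artifacts
    exclude an epoch from spectral averages, never from state counts.
    """

    states: np.ndarray
    artifact: np.ndarray | None = None
    epoch_seconds: float = float(EPOCH_SECONDS)
    start_zt_h: float = 0.0
    schedule: LightSchedule = field(default_factory=LightSchedule)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.ndim != 1 or self.states.size == 0:
            raise ValueError("states must be a non-empty 1-D array")
        if not np.all(np.isin(self.states, [WAKE, NREM, REM])):
            raise ValueError("states must be WAKE (0), NREM (1) or REM (2)")
        if self.artifact is None:
            self.artifact = np.zeros(self.states.size, dtype=bool)
        else:
            self.artifact = np.asarray(self.artifact, dtype=bool)
            if self.artifact.shape != self.states.shape:
                raise ValueError("artifact flags must align with states")

    @property
    def n_epochs(self) -> int:
        return int(self.states.size)

    @property
    def zt_h(self) -> np.ndarray:
        """ZT hour of each epoch start."""
        return self.start_zt_h + np.arange(self.n_epochs) * self.epoch_seconds / 3600.0

    def state_fraction(self, state: int) -> float:
        return float(np.mean(self.states == state))
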