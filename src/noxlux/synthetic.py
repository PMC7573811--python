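"""Ground-truth simulator for a dim-light-at-night (DLAN) mouse study.

Two generators with known structure drive the whole test surface:

* :func:`simulate_activity` — passive-infrared-style locomotor counts:
  a nocturnal circadian gate (optionally phase-delayed and degraded)
  plus a 1/f^beta fractal component synthesized in the frequency
  domain, rectified and Poisson-sampled.  The injected spectral
  exponent beta maps to a DFA scaling exponent alpha = (beta + 1) / 2,
  so the analysis chain can be checked against known truth.
* :func:`simulate_recording` — EEG/EMG at 128 Hz in 4-s epochs: a
  per-phase Markov chain yields the ground-truth hypnogram, each
  epoch's EEG is coloured noise shaped by the state's spectral
  template (delta-rich NREM, theta-rich REM), NREM slow-wave amplitude
  tracks a two-exponential sleep-pressure homeostat (Process S), and
  an optional forced-wake window emulates 6-h sleep deprivation by
  gentle handling.

All generators are bit-reproducible given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    EPOCH_SECONDS,
    NREM,
    REM,
    SAMPLES_PER_EPOCH,
    WAKE,
    ActivityTrace,
    Hypnogram,
    LightSchedule,
    SignalRecording,
)

__all__ = [
    "ActivityGenParams",
    "HomeostatParams",
    "SDProtocol",
    "EEGGenParams",
    "fractal_noise",
    "simulate_activity",
    "simulate_recording",
    "process_s_trajectory",
    "default_state_spectra",
    "default_transition_matrices",
    "FREQ_BINS_HZ",
]

EPOCHS_PER_DAY = 24 * 3600 // EPOCH_SECONDS  # 21600

# Spectral grid shared with the analysis side: 0.25–25.0 Hz in 0.25 steps.
FREQ_BINS_HZ = np.arange(1, 101) * 0.25


@dataclass(frozen=True)
class ActivityGenParams:
    """Parameters of the locomotor-count generator.

    ``fractal_beta`` is the spectral exponent of the 1/f^beta component;
    the DFA alpha it induces is (beta + 1) / 2, so beta = 1 (pink noise)
    targets the healthy alpha of 1.  ``disruption`` in [0, 1] scales the
    circadian amplitude down and adds white night-phase noise, degrading
    both rhythm strength and alpha.  ``phase_delay_h`` shifts the
    nocturnal activity gate later, emulating the delayed activity onset
    seen under dim light at night.
    """

    days: int = 15
    bin_seconds: float = 60.0
    mean_rate: float = 200.0
    circadian_amplitude: float = 0.9
    fractal_beta: float = 1.0
    fractal_cv: float = 1.0  # fractal RMS (in the 1.5–16 h band) relative to the local mean
    anchor_block_h: float | None = 12.0  # Zeitgeber re-anchoring block; None = free-running
    phase_delay_h: float = 0.0
    disruption: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.days < 2:
            raise ValueError("need at least 2 days of simulated activity")
        if self.bin_seconds <= 0:
            raise ValueError("bin_seconds must be positive")
        if self.mean_rate <= 0:
            raise ValueError("mean_rate must be positive")
        if self.fractal_beta <= -1:
            raise ValueError("fractal_beta must exceed -1")
        if not 0.0 <= self.circadian_amplitude <= 1.0:
            raise ValueError("circadian_amplitude must lie in [0, 1]")
        if not 0.0 <= self.disruption <= 1.0:
            raise ValueError("disruption must lie in [0, 1]")
        if self.phase_delay_h < 0:
            raise ValueError("phase_delay_h must be >= 0")
        if self.anchor_block_h is not None and self.anchor_block_h <= 0:
            raise ValueError("anchor_block_h must be positive or None")


@dataclass(frozen=True)
class HomeostatParams:
    """Two-exponential Process-S dynamics for NREM slow-wave amplitude.

    S rises toward 1 during WAKE/REM with time constant ``tau_rise_h``
    and decays toward 0 during NREM with ``tau_decay_h``; ``gain`` maps
    S to the amplitude multiplier of the NREM slow-wave band.
    """

    s0: float = 0.5
    tau_rise_h: float = 8.0
    tau_decay_h: float = 2.0
    gain: float = 2.0

    def validate(self) -> None:
        if not 0.0 <= self.s0 <= 1.0:
            raise ValueError("s0 must lie in [0, 1]")
        if self.tau_rise_h <= 0 or self.tau_decay_h <= 0:
            raise ValueError("time constants must be positive")
        if self.gain <= 0:
            raise ValueError("gain must be positive")


@dataclass(frozen=True)
class SDProtocol:
    """Forced-wake (sleep-deprivation) window, applied on the last
    simulated day, in ZT hours after lights-on."""

    start_zt_h: float = 0.0
    duration_h: float = 6.0

    def validate(self) -> None:
        if self.start_zt_h < 0:
            raise ValueError("start_zt_h must be >= 0")
        if self.start_zt_h + self.duration_h > 24:
            raise ValueError("sleep-deprivation window must end within the day")


def default_state_spectra(total_power_uv2: dict[int, float] | None = None) -> dict[int, np.ndarray]:
    """Per-state spectral templates over the 0.25–25 Hz grid (µV² per bin).

    NREM peaks in the delta band (0.75–4 Hz), REM in the theta band
    (6.25–9 Hz), WAKE is broadband 1/f with a modest theta component.
    The template value in each bin is the expected epoch power there.
    """
    f = FREQ_BINS_HZ
    base = 1.0 / (f + 0.5)  # 1/f-ish background shared by all states

    wake = base + 0.6 * np.exp(-0.5 * ((f - 7.5) / 1.5) ** 2)
    nrem = 0.6 * base + 3.0 * np.exp(-0.5 * ((f - 2.0) / 1.2) ** 2)
    rem = 0.5 * base + 2.0 * np.exp(-0.5 * ((f - 7.5) / 0.9) ** 2)

    totals = total_power_uv2 or {WAKE: 120.0, NREM: 250.0, REM: 120.0}
    out = {}
    for state, tpl in ((WAKE, wake), (NREM, nrem), (REM, rem)):
        out[state] = tpl / tpl.sum() * totals[state]
    return out


def default_transition_matrices() -> dict[str, np.ndarray]:
    """Per-phase 4-s epoch-to-epoch state transition matrices.

    Rows/columns are ordered WAKE, NREM, REM.  The light-phase chain is
    sleep-dominant, the dark-phase chain wake-dominant, and the "surge"
    chain (first hours of the active period) strongly wake-dominant —
    it produces the waking peak early in the dark phase.  Direct
    WAKE→REM transitions are disallowed by default.
    """
    light = np.array(
        [
            [0.9600, 0.0400, 0.0000],
            [0.0200, 0.9650, 0.0150],
            [0.0600, 0.0400, 0.9000],
        ]
    )
    dark = np.array(
        [
            [0.9880, 0.0120, 0.0000],
            [0.0300, 0.9600, 0.0100],
            [0.0800, 0.0200, 0.9000],
        ]
    )
    surge = np.array(
        [
            [0.9980, 0.0020, 0.0000],
            [0.0800, 0.9100, 0.0100],
            [0.1000, 0.0200, 0.8800],
        ]
    )
    return {"light": light, "dark": dark, "surge": surge}


@dataclass(frozen=True)
class EEGGenParams:
    """Parameters of the EEG/EMG + hypnogram generator."""

    days: int = 1
    state_spectra: dict[int, np.ndarray] = field(default_factory=default_state_spectra)
    emg_rms: dict[int, float] = field(
        default_factory=lambda: {WAKE: 40.0, NREM: 6.0, REM: 4.0}
    )
    transition_matrices: dict[str, np.ndarray] = field(
        default_factory=default_transition_matrices
    )
    homeostat: HomeostatParams = field(default_factory=HomeostatParams)
    phase_delay_h: float = 0.0  # delay of the active-phase onset within the dark half
    surge_hours: float = 2.0  # duration of the strongly-waking surge after onset
    # Two-process coupling: the WAKE->NREM transition probability is scaled
    # by (1 + coupling * (S - s_ref)), so elevated sleep pressure promotes
    # sleep onset and produces an NREM rebound after sleep deprivation.
    pressure_coupling: float = 1.5
    pressure_s_ref: float = 0.35
    seed: int = 0

    def validate(self) -> None:
        if self.days < 1:
            raise ValueError("need at least 1 day")
        for name, mat in self.transition_matrices.items():
            m = np.asarray(mat, dtype=float)
            if m.shape != (3, 3) or np.any(m < 0):
                raise ValueError(f"{name}: transition matrix must be 3x3 non-negative")
            if np.any(np.abs(m.sum(axis=1) - 1.0) > 1e-9):
                raise ValueError(f"{name}: transition-matrix rows must sum to 1")
        for state, tpl in self.state_spectra.items():
            tpl = np.asarray(tpl, dtype=float)
            if tpl.shape != (100,) or np.any(tpl < 0):
                raise ValueError("state templates must be 100 non-negative bin weights")
        f = FREQ_BINS_HZ
        nrem_peak = f[int(np.argmax(self.state_spectra[NREM]))]
        rem_peak = f[int(np.argmax(self.state_spectra[REM]))]
        if not (0.75 <= nrem_peak <= 4.0):
            raise ValueError(f"NREM template must peak in 0.75–4.0 Hz (peaks at {nrem_peak} Hz)")
        if not (6.25 <= rem_peak <= 9.0):
            raise ValueError(f"REM template must peak in 6.25–9.0 Hz (peaks at {rem_peak} Hz)")
        if not (self.emg_rms[WAKE] > self.emg_rms[NREM] >= self.emg_rms[REM]):
            raise ValueError("EMG levels must satisfy WAKE > NREM >= REM")
        if not 0 <= self.phase_delay_h < 12:
            raise ValueError("phase_delay_h must lie in [0, 12)")
        if self.pressure_coupling < 0:
            raise ValueError("pressure_coupling must be >= 0")
        if not 0.0 <= self.pressure_s_ref <= 1.0:
            raise ValueError("pressure_s_ref must lie in [0, 1]")
        self.homeostat.validate()


def fractal_noise(n: int, beta: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean noise of length ``n`` with power spectral density ∝ f^-beta.

    Synthesized by shaping complex Gaussian spectral amplitudes
    (amplitude ∝ f^(-beta/2), random phases) and inverse-transforming;
    the DC component is zero.  Returned un-normalised.
    """
    if n < 2:
        raise ValueError("need at least 2 samples")
    freqs = np.fft.rfftfreq(n)
    amp = np.zeros(freqs.size)
    amp[1:] = freqs[1:] ** (-beta / 2.0)
    coef = amp * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    coef[0] = 0.0
    return np.fft.irfft(coef, n)


def _band_normalise(z: np.ndarray, bin_seconds: float, lo_h: float = 1.5, hi_h: float = 16.0) -> np.ndarray:
    """Scale ``z`` to unit RMS of its component with periods in [lo_h, hi_h].

    Anchoring the amplitude in a band bracketing the 3–8 h DFA fit range
    (rather than to the total variance, which is dominated by the lowest
    frequencies for steep spectra) keeps the fluctuation magnitude at the
    analysed timescales comparable across beta, so the injected exponent
    stays recoverable for any beta.
    """
    freqs = np.fft.rfftfreq(z.size)  # cycles per bin
    period_h = np.full(freqs.size, np.inf)
    period_h[1:] = bin_seconds / freqs[1:] / 3600.0
    spec = np.fft.rfft(z)
    band = np.where((period_h >= lo_h) & (period_h <= hi_h), spec, 0.0)
    band_rms = np.fft.irfft(band, z.size).std()
    if band_rms == 0:
        raise ValueError("fractal component has no power in the normalisation band")
    return z / band_rms


def _circadian_gate(zt_h: np.ndarray, amplitude: float, phase_delay_h: float) -> np.ndarray:
    """Nocturnal square gate with half-swing (2/3) * amplitude.

    The active window is the dark half [ZT12, ZT24) shifted later by the
    phase delay (circularly, so a delayed animal is active into the
    early light phase), mirroring a delayed activity onset.  The sharp
    onset/offset edges are deliberate: entrained rodent activity starts
    and stops abruptly at the light transitions, and those edges are
    what makes the circadian period identifiable to within minutes.
    """
    half_swing = amplitude * (2.0 / 3.0)
    shifted = (zt_h - phase_delay_h) % 24.0
    active = shifted >= 12.0
    return np.where(active, 1.0 + half_swing, 1.0 - half_swing)


def simulate_activity(params: ActivityGenParams, schedule: LightSchedule | None = None) -> ActivityTrace:
    """Generate a PIR-like locomotor count trace with known ground truth.

    Counts are Poisson draws around a non-negative multiplicative
    intensity::

        lambda(t) = mean_rate * gate(t) * max(0, 1 + cv * z(t) + d(t))

    where ``gate`` is the (possibly delayed, possibly damped) nocturnal
    circadian gate, ``z`` is 1/f^beta fractal noise normalised to unit
    RMS in the 1.5–16 h band, and ``d`` is white night-phase noise
    proportional to ``disruption``.  Modulating the gated level (rather
    than adding counts independently of it) makes the fluctuation
    amplitude track the activity level, as in real actigraphy.

    When ``anchor_block_h`` is set (default: 12 h, the half-cycle), the
    fractal noise is synthesized as independent blocks of that length:
    an entrained animal is phase-reset by the Zeitgeber every
    transition, so its behavioural fluctuations carry no phase
    coherence across days.  ``anchor_block_h=None`` gives a single
    coherent fractal, appropriate for free-running or arrhythmic
    (``circadian_amplitude=0``) conditions.
    """
    params.validate()
    schedule = schedule or LightSchedule()
    rng = np.random.default_rng(params.seed)

    n = int(round(params.days * 86400 / params.bin_seconds))
    zt = np.arange(n) * params.bin_seconds / 3600.0 % 24.0

    amp = params.circadian_amplitude * (1.0 - params.disruption)
    gate = _circadian_gate(zt, amp, params.phase_delay_h)

    if params.anchor_block_h is None:
        z = fractal_noise(n, params.fractal_beta, rng)
    else:
        block = int(round(params.anchor_block_h * 3600 / params.bin_seconds))
        if block < 2 or n % block:
            raise ValueError(
                f"anchor block ({params.anchor_block_h} h) must hold >= 2 bins "
                "and divide the trace length"
            )
        z = np.concatenate(
            [fractal_noise(block, params.fractal_beta, rng) for _ in range(n // block)]
        )
    z = _band_normalise(z, params.bin_seconds)

    modulation = 1.0 + params.fractal_cv * z
    if params.disruption > 0:
        night = np.asarray(schedule.is_dark(zt))
        night_noise = rng.standard_normal(n) * (params.disruption * params.fractal_cv)
        modulation = modulation + np.where(night, night_noise, 0.0)
    lam = params.mean_rate * gate * np.clip(modulation, 0.0, None)
    counts = rng.poisson(lam).astype(float)
    return ActivityTrace(
        counts=counts,
        bin_seconds=params.bin_seconds,
        start_zt_h=0.0,
        schedule=schedule,
    )


def _simulate_hypnogram(params: EEGGenParams, schedule: LightSchedule, sd: SDProtocol | None, rng: np.random.Generator) -> Hypnogram:
    n_epochs = params.days * EPOCHS_PER_DAY
    zt = np.arange(n_epochs) * EPOCH_SECONDS / 3600.0
    zt_day = zt % 24.0
    day = (zt // 24.0).astype(int)

    mats = {k: np.asarray(v, dtype=float) for k, v in params.transition_matrices.items()}
    cum = {k: np.cumsum(v, axis=1) for k, v in mats.items()}

    onset = 12.0 + params.phase_delay_h
    in_dark = np.asarray(schedule.is_dark(zt_day))
    in_surge = in_dark & (zt_day >= onset) & (zt_day < min(onset + params.surge_hours, 24.0))
    in_active = in_dark & (zt_day >= onset)
    regime = np.where(in_surge, 2, np.where(in_active, 1, 0))  # 0 light, 1 dark, 2 surge
    regime_keys = ("light", "dark", "surge")

    forced = np.zeros(n_epochs, dtype=bool)
    if sd is not None:
        sd.validate()
        forced = (day == params.days - 1) & (zt_day >= sd.start_zt_h) & (
            zt_day < sd.start_zt_h + sd.duration_h
        )

    # Sleep-pressure coupling runs S online with the same dynamics as
    # process_s_trajectory, so recomputing S from the finished hypnogram
    # reproduces the trajectory the chain actually saw.
    h = params.homeostat
    dt_h = EPOCH_SECONDS / 3600.0
    up, down = np.exp(-dt_h / h.tau_rise_h), np.exp(-dt_h / h.tau_decay_h)

    states = np.empty(n_epochs, dtype=np.int8)
    u = rng.random(n_epochs)
    state = NREM  # recordings start at lights-on, a sleep-dominant time
    s_level = h.s0
    for i in range(n_epochs):
        if forced[i]:
            state = WAKE
        else:
            key = regime_keys[regime[i]]
            if state == WAKE and params.pressure_coupling > 0:
                p_wn = mats[key][WAKE, NREM] * max(
                    0.0, 1.0 + params.pressure_coupling * (s_level - params.pressure_s_ref)
                )
                p_wr = mats[key][WAKE, REM]
                p_wn = min(p_wn, 1.0 - p_wr)
                row = np.cumsum([1.0 - p_wn - p_wr, p_wn, p_wr])
            else:
                row = cum[key][state]
            state = int(np.searchsorted(row, u[i], side="right"))
        states[i] = state
        s_level = s_level * down if state == NREM else 1.0 - (1.0 - s_level) * up
    return Hypnogram(states=states, start_zt_h=0.0, schedule=schedule)


def process_s_trajectory(hyp: Hypnogram, params: HomeostatParams) -> np.ndarray:
    """Sleep-pressure level S per epoch (evaluated at each epoch's end).

    S relaxes toward 1 during WAKE/REM epochs with ``tau_rise_h`` and
    toward 0 during NREM epochs with ``tau_decay_h``; each 4-s epoch
    applies one exact exponential step, so the trajectory is continuous
    across epochs and bounded in [0, 1].
    """
    params.validate()
    if hyp.n_epochs == 0:
        raise ValueError("empty hypnogram")
    dt_h = hyp.epoch_seconds / 3600.0
    up = np.exp(-dt_h / params.tau_rise_h)
    down = np.exp(-dt_h / params.tau_decay_h)
    s = np.empty(hyp.n_epochs)
    level = params.s0
    for i, state in enumerate(hyp.states):
        if state == NREM:
            level = level * down
        else:
            level = 1.0 - (1.0 - level) * up
        s[i] = level
    return s


def simulate_recording(
    params: EEGGenParams,
    schedule: LightSchedule | None = None,
    sd: SDProtocol | None = None,
) -> tuple[SignalRecording, Hypnogram]:
    """Generate an EEG/EMG recording plus its ground-truth hypnogram.

    The hypnogram is drawn from the per-phase Markov chain in 4-s
    epochs (with the sleep-deprivation window, if given, forced to WAKE
    on the last day).  Each epoch's EEG is synthesized in the frequency
    domain: complex Gaussian coefficients on the 0.25–25 Hz grid scaled
    so the expected bin power matches the state template, with the NREM
    slow-wave (0.5–4 Hz) amplitude multiplied by gain * S(t).  The EMG
    is white noise at the state's RMS level.
    """
    params.validate()
    schedule = schedule or LightSchedule()
    rng = np.random.default_rng(params.seed)

    hyp = _simulate_hypnogram(params, schedule, sd, rng)
    s_traj = process_s_trajectory(hyp, params.homeostat)
    n_epochs = hyp.n_epochs

    # Expected power per bin per epoch (µV²), then amplitude spectra.
    power = np.empty((n_epochs, 100))
    for state, tpl in params.state_spectra.items():
        power[hyp.states == state] = np.asarray(tpl, dtype=float)
    swa_bins = (FREQ_BINS_HZ >= 0.5) & (FREQ_BINS_HZ <= 4.0)
    nrem_mask = hyp.states == NREM
    swa_scale = (params.homeostat.gain * s_traj[nrem_mask]) ** 2
    power[np.ix_(nrem_mask, swa_bins)] *= swa_scale[:, None]

    # One 512-point epoch per row; rfft grid of 512 @128 Hz is exactly
    # 0.25-Hz spaced, so template bin k sits at rfft index k+1.
    n_freq = SAMPLES_PER_EPOCH // 2 + 1
    coef = np.zeros((n_epochs, n_freq), dtype=complex)
    noise = rng.standard_normal((n_epochs, 100)) + 1j * rng.standard_normal((n_epochs, 100))
    # E|X_k|^2 scaling: bin power p_k (one-sided, non-DC/non-Nyquist)
    # corresponds to |X_k| = N * sqrt(p_k / 2).
    coef[:, 1:101] = noise / np.sqrt(2.0) * (SAMPLES_PER_EPOCH * np.sqrt(power / 2.0))
    eeg = np.fft.irfft(coef, SAMPLES_PER_EPOCH, axis=1).ravel()

    emg_level = np.empty(n_epochs)
    for state, level in params.emg_rms.items():
        emg_level[hyp.states == state] = level
    emg = (rng.standard_normal((n_epochs, SAMPLES_PER_EPOCH)) * emg_level[:, None]).ravel()

    rec = SignalRecording(eeg=eeg, emg=emg, start_zt_h=0.0, schedule=schedule)
    return rec, hyp
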