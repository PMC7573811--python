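"""Vigilance scoring and timecourse aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from noxlux import (
    EEGGenParams,
    Hypnogram,
    compare_recovery_to_baseline,
    daily_amplitude,
    score_epochs,
    simulate_recording,
    state_percent_timecourse,
    waking_peak,
)
from noxlux.core import NREM, REM, WAKE
from noxlux.spectral import EpochSpectra
from noxlux.synthetic import EPOCHS_PER_DAY, FREQ_BINS_HZ


def synthetic_spectra(n=600):
    """Hand-built spectra: first third wake-like, then NREM-like, then REM-like."""
    power = np.zeros((n, 100))
    emg = np.zeros(n)
    third = n // 3
    delta = (FREQ_BINS_HZ >= 0.75) & (FREQ_BINS_HZ <= 4.0)
    theta = (FREQ_BINS_HZ >= 6.25) & (FREQ_BINS_HZ <= 9.0)
    power[:, delta] = 1.0
    power[:third] += 0.5  # broadband waking
    emg[:third] = 50.0
    emg[third:] = 5.0
    power[2 * third :, delta] = 0.3
    power[2 * third :, theta] = 3.0  # theta-dominant REM block
    return EpochSpectra(power=power, emg_rms=emg, dropped_power=np.zeros(n))


class TestScorer:
    def test_agreement_with_ground_truth(self, baseline_spectra, baseline_recording):
        _, truth = baseline_recording
        scored = score_epochs(baseline_spectra)
        agreement = np.mean(scored.states == truth.states)
        assert agreement >= 0.90

    def test_deterministic(self, baseline_spectra):
        a = score_epochs(baseline_spectra)
        b = score_epochs(baseline_spectra)
        np.testing.assert_array_equal(a.states, b.states)

    def test_high_emg_forces_wake(self):
        spectra = synthetic_spectra()
        spectra.emg_rms[400] = 500.0  # huge EMG inside the sleep block
        hyp = score_epochs(spectra, smooth=False)
        assert hyp.states[400] == WAKE

    def test_theta_dominant_low_emg_is_rem(self):
        hyp = score_epochs(synthetic_spectra(), smooth=False)
        n = hyp.n_epochs
        assert np.mean(hyp.states[: n // 3] == WAKE) > 0.9
        assert np.mean(hyp.states[n // 3 : 2 * n // 3] == NREM) > 0.9
        assert np.mean(hyp.states[2 * n // 3 :] == REM) > 0.9

    def test_degenerate_distribution_falls_back_with_warning(self):
        power = np.ones((100, 100))
        spectra = EpochSpectra(
            power=power, emg_rms=np.full(100, 10.0), dropped_power=np.zeros(100)
        )
        with pytest.warns(UserWarning, match="bimodal"):
            hyp = score_epochs(spectra)
        assert hyp.n_epochs == 100  # every epoch still labelled

    def test_smoothing_removes_single_epoch_flicker(self):
        from noxlux.vigilance import _majority_smooth

        states = np.full(20, WAKE, dtype=np.int8)
        states[10] = NREM  # isolated single-epoch flicker
        smoothed = _majority_smooth(states)
        assert smoothed[10] == WAKE
        # a genuine 2-epoch bout survives
        states[14:16] = REM
        assert np.all(_majority_smooth(states)[14:16] == REM)


class TestTimecourse:
    def test_all_wake(self):
        hyp = Hypnogram(states=np.full(2 * 1800, WAKE))
        tc = state_percent_timecourse(hyp, 2.0)
        assert np.all(tc.percent[:, WAKE] == 100.0)
        assert np.all(tc.percent[:, 1:] == 0.0)

    def test_percentages_sum_to_100_and_conserve_epochs(self, baseline_recording):
        _, truth = baseline_recording
        tc = state_percent_timecourse(truth, 2.0)
        np.testing.assert_allclose(tc.percent.sum(axis=1), 100.0, atol=1e-9)
        for s in (WAKE, NREM, REM):
            assert tc.counts[:, s].sum() == np.sum(truth.states == s)

    def test_nocturnal_wake_percent(self, baseline_recording):
        _, truth = baseline_recording
        tc = state_percent_timecourse(truth, 12.0)
        assert tc.percent[1, WAKE] > tc.percent[0, WAKE]

    def test_partial_trailing_bin_rejected(self):
        hyp = Hypnogram(states=np.full(1801, WAKE))
        with pytest.raises(ValueError, match="whole"):
            state_percent_timecourse(hyp, 2.0)
        tc = state_percent_timecourse(hyp, 2.0, allow_partial=True)
        assert tc.n_bins == 2

    def test_interval_labels(self, sd_recording):
        _, truth = sd_recording
        tc = state_percent_timecourse(truth, 12.0)
        assert tc.interval_labels == ["L1", "D1", "L2", "D2"]

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_epoch_conservation_property(self, seed):
        rng = np.random.default_rng(seed)
        states = rng.integers(0, 3, size=3600).astype(np.int8)
        hyp = Hypnogram(states=states)
        tc = state_percent_timecourse(hyp, 2.0)
        assert tc.counts.sum() == hyp.n_epochs


def make_tc(wake_percent_per_bin):
    """A 2-h timecourse with prescribed WAKE% (rest split to NREM)."""
    wake = np.asarray(wake_percent_per_bin, float)
    percent = np.zeros((wake.size, 3))
    percent[:, WAKE] = wake
    percent[:, NREM] = 100.0 - wake
    from noxlux import StateTimecourse

    return StateTimecourse(
        bin_start_zt_h=np.arange(wake.size) * 2.0,
        percent=percent,
        counts=(percent * 18).astype(int),
        n_artifact=np.zeros(wake.size, int),
        bin_hours=2.0,
    )


class TestPeakAndAmplitude:
    def test_peak_bin_midpoint_convention(self):
        wake = np.zeros(12)
        wake[6] = 80.0  # bin ZT12-14
        assert waking_peak(make_tc(wake)).peak_zt_h == 13.0

    def test_tie_resolves_to_earliest_bin(self):
        wake = np.zeros(12)
        wake[6] = wake[10] = 80.0  # ZT12-14 and ZT20-22
        assert waking_peak(make_tc(wake)).peak_zt_h == 13.0

    def test_programmed_delay_recovered(self):
        peaks = []
        for delay in (0.0, 4.0):
            _, truth = simulate_recording(EEGGenParams(days=1, seed=21, phase_delay_h=delay))
            tc = state_percent_timecourse(truth, 2.0)
            peaks.append(waking_peak(tc, (12.0, 24.0)).peak_zt_h)
        assert peaks[1] - peaks[0] == pytest.approx(4.0, abs=2.0)

    def test_empty_interval_rejected(self):
        with pytest.raises(ValueError, match="interval"):
            waking_peak(make_tc(np.zeros(12)), (30.0, 40.0))

    def test_amplitude_arithmetic(self):
        wake = np.r_[np.full(6, 40.0), np.full(6, 80.0)]
        amp = daily_amplitude(make_tc(wake))
        assert amp.wake == pytest.approx(40.0)
        assert amp.nrem == pytest.approx(-40.0)
        assert amp.rem == 0.0

    def test_identical_halves_zero_amplitude(self):
        amp = daily_amplitude(make_tc(np.full(12, 55.0)))
        assert amp.wake == amp.nrem == amp.rem == 0.0

    def test_amplitude_decreases_with_disruption_analogue(self):
        # stronger dark-phase waking bias -> larger day-night amplitude
        from noxlux.synthetic import default_transition_matrices

        flat = default_transition_matrices()
        flat["dark"] = flat["light"]  # arrhythmic analogue
        flat["surge"] = flat["light"]
        amps = {}
        for name, mats in (("rhythmic", None), ("flat", flat)):
            kw = {"transition_matrices": mats} if mats else {}
            _, truth = simulate_recording(EEGGenParams(days=1, seed=17, **kw))
            amps[name] = daily_amplitude(state_percent_timecourse(truth, 2.0)).wake
        assert amps["rhythmic"] > amps["flat"]

    def test_missing_half_day_rejected(self):
        with pytest.raises(ValueError, match="24-h"):
            daily_amplitude(make_tc(np.zeros(6)))


class TestRecoveryComparison:
    def test_identical_days_zero_difference(self):
        tc = make_tc(np.linspace(20, 80, 12))
        df = compare_recovery_to_baseline(tc, tc)
        assert np.all(df["difference"] == 0.0)

    def test_nrem_rebound_after_sd(self, sd_recording):
        _, truth = sd_recording
        bl = state_percent_timecourse(
            Hypnogram(states=truth.states[:EPOCHS_PER_DAY]), 6.0
        )
        rec = state_percent_timecourse(
            Hypnogram(states=truth.states[EPOCHS_PER_DAY:]), 6.0
        )
        df = compare_recovery_to_baseline(bl, rec)
        # post-SD light segment = ZT6-12 (bin index 1)
        l2 = df[(df["state"] == "N") & (df["bin_start_zt"] == 6.0)]
        assert float(l2["difference"].iloc[0]) > 0

    def test_misaligned_bins_rejected(self):
        with pytest.raises(ValueError, match="misaligned"):
            compare_recovery_to_baseline(make_tc(np.zeros(12)), make_tc(np.zeros(6)))
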