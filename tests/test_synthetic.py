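"""Ground-truth generators: activity, hypnogram/EEG, and the homeostat."""

import dataclasses

import numpy as np
import pytest

from noxlux import (
    ActivityGenParams,
    EEGGenParams,
    HomeostatParams,
    Hypnogram,
    LightSchedule,
    SDProtocol,
    dfa,
    process_s_trajectory,
    simulate_activity,
    simulate_recording,
)
from noxlux.core import NREM, REM, WAKE
from noxlux.synthetic import (
    EPOCHS_PER_DAY,
    default_state_spectra,
    default_transition_matrices,
    fractal_noise,
)


def mean_phase_h(trace):
    """Activity-weighted circular mean phase, in ZT hours."""
    ang = 2 * np.pi * trace.zt_h / 24.0
    mean = np.angle(np.sum(trace.counts * np.exp(1j * ang)))
    return (mean % (2 * np.pi)) / (2 * np.pi) * 24.0


class TestActivityGenerator:
    def test_bit_reproducible(self):
        a = simulate_activity(ActivityGenParams(seed=42))
        b = simulate_activity(ActivityGenParams(seed=42))
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_shape_and_nonnegativity(self, control_trace):
        assert control_trace.n_bins == 15 * 1440
        assert np.all(control_trace.counts >= 0)

    def test_nocturnal_mean_phase(self, control_trace):
        assert 12.0 <= mean_phase_h(control_trace) < 24.0

    def test_phase_delay_shifts_mean_phase(self):
        base = simulate_activity(ActivityGenParams(seed=3))
        delayed = simulate_activity(ActivityGenParams(seed=3, phase_delay_h=4.0))
        shift = (mean_phase_h(delayed) - mean_phase_h(base)) % 24.0
        assert shift == pytest.approx(4.0, abs=1.0)

    def test_white_fractal_alpha_half(self):
        # amplitude=0 disables the gate; beta=0 is uncorrelated noise
        alphas = [
            dfa(
                simulate_activity(
                    ActivityGenParams(
                        seed=s, circadian_amplitude=0.0, fractal_beta=0.0,
                        anchor_block_h=None,
                    )
                )
            ).alpha
            for s in range(5)
        ]
        assert abs(np.mean(alphas) - 0.5) < 0.05

    @pytest.mark.parametrize(
        "bad",
        [
            {"fractal_beta": -1.5},
            {"bin_seconds": 0},
            {"days": 1},
            {"circadian_amplitude": 1.5},
            {"disruption": -0.1},
            {"mean_rate": 0},
        ],
    )
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ValueError):
            simulate_activity(ActivityGenParams(seed=0, **bad))


class TestFractalNoise:
    def test_spectral_slope_matches_beta(self, rng):
        # average periodogram over draws; fit log-log slope of the PSD
        n = 4096
        psd = np.zeros(n // 2 + 1)
        for _ in range(40):
            z = fractal_noise(n, 1.0, rng)
            psd += np.abs(np.fft.rfft(z)) ** 2
        f = np.fft.rfftfreq(n)[1:]
        slope = np.polyfit(np.log10(f), np.log10(psd[1:]), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.1)

    def test_zero_mean(self, rng):
        z = fractal_noise(2048, 2.0, rng)
        assert z.mean() == pytest.approx(0.0, abs=1e-10)


class TestHypnogramChain:
    def test_recording_shape_and_reproducibility(self, baseline_recording):
        rec, truth = baseline_recording
        assert rec.n_epochs == truth.n_epochs == EPOCHS_PER_DAY
        assert rec.eeg.size % 512 == 0
        rec2, truth2 = simulate_recording(EEGGenParams(days=1, seed=5))
        np.testing.assert_array_equal(truth.states, truth2.states)
        np.testing.assert_array_equal(rec.eeg, rec2.eeg)

    def test_nocturnal_wake_distribution(self, baseline_recording):
        _, truth = baseline_recording
        dark = truth.zt_h % 24 >= 12
        wake = truth.states == WAKE
        assert wake[dark].mean() > wake[~dark].mean()

    def test_dark_wake_self_transition_raises_dark_waking(self):
        mats = default_transition_matrices()
        boosted = {k: v.copy() for k, v in mats.items()}
        boosted["dark"][WAKE] = [0.998, 0.002, 0.0]
        frac = {}
        for name, m in (("base", mats), ("boosted", boosted)):
            _, truth = simulate_recording(
                EEGGenParams(days=1, seed=9, transition_matrices=m)
            )
            dark = truth.zt_h % 24 >= 12
            frac[name] = np.mean(truth.states[dark] == WAKE)
        assert frac["boosted"] > frac["base"]

    def test_sd_window_forces_wake(self, sd_recording):
        _, truth = sd_recording
        day2 = slice(EPOCHS_PER_DAY, EPOCHS_PER_DAY + 6 * 900)
        assert np.all(truth.states[day2] == WAKE)

    def test_sd_raises_sleep_pressure(self, sd_recording):
        _, truth = sd_recording
        s = process_s_trajectory(truth, HomeostatParams())
        end_sd = EPOCHS_PER_DAY + 6 * 900 - 1
        end_bl = 6 * 900 - 1
        assert s[end_sd] > s[end_bl]

    def test_invalid_transition_rows_rejected(self):
        mats = default_transition_matrices()
        mats["light"][0, 0] += 0.01
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_recording(EEGGenParams(days=1, seed=0, transition_matrices=mats))

    def test_template_band_constraints_enforced(self):
        spectra = default_state_spectra()
        spectra[NREM], spectra[REM] = spectra[REM], spectra[NREM]  # swap peaks
        with pytest.raises(ValueError, match="NREM template"):
            simulate_recording(EEGGenParams(days=1, seed=0, state_spectra=spectra))

    def test_sd_protocol_validation(self):
        with pytest.raises(ValueError, match="within the day"):
            simulate_recording(
                EEGGenParams(days=2, seed=0), sd=SDProtocol(20.0, 6.0)
            )


class TestHomeostat:
    def test_all_wake_closed_form(self):
        hyp = Hypnogram(states=np.full(900, WAKE))
        params = HomeostatParams(s0=0.0, tau_rise_h=8.0)
        s = process_s_trajectory(hyp, params)
        t_h = (np.arange(900) + 1) * 4 / 3600.0
        np.testing.assert_allclose(s, 1 - np.exp(-t_h / 8.0), rtol=1e-12)

    def test_all_nrem_closed_form(self):
        hyp = Hypnogram(states=np.full(900, NREM))
        params = HomeostatParams(s0=1.0, tau_decay_h=2.0)
        s = process_s_trajectory(hyp, params)
        t_h = (np.arange(900) + 1) * 4 / 3600.0
        np.testing.assert_allclose(s, np.exp(-t_h / 2.0), rtol=1e-12)

    def test_alternating_blocks_match_fine_integrator(self):
        # 2-h WAKE / 2-h NREM alternation vs a step-by-step Euler
        # integrator at 0.1-s resolution (independent oracle)
        block = 1800  # epochs per 2 h
        states = np.tile(np.r_[np.full(block, WAKE), np.full(block, NREM)], 3)
        hyp = Hypnogram(states=states)
        params = HomeostatParams(s0=0.5, tau_rise_h=8.0, tau_decay_h=2.0)
        s = process_s_trajectory(hyp, params)

        dt = 0.1 / 3600.0  # hours
        level = 0.5
        fine = np.empty(states.size)
        for i, st in enumerate(states):
            for _ in range(40):  # 4 s per epoch at 0.1 s steps
                if st == NREM:
                    level += -level / 2.0 * dt
                else:
                    level += (1 - level) / 8.0 * dt
            fine[i] = level
        np.testing.assert_allclose(s, fine, atol=2e-5)

    def test_bounded_and_monotone_within_bouts(self, baseline_recording):
        _, truth = baseline_recording
        s = process_s_trajectory(truth, HomeostatParams())
        assert np.all((0 <= s) & (s <= 1))
        same_next = truth.states[1:] == truth.states[:-1]
        rising = truth.states[1:] != NREM
        ds = np.diff(s)
        assert np.all(ds[same_next & rising] > 0)
        assert np.all(ds[same_next & ~rising] < 0)

    def test_invalid_time_constants_rejected(self):
        hyp = Hypnogram(states=np.full(10, WAKE))
        with pytest.raises(ValueError, match="positive"):
            process_s_trajectory(hyp, HomeostatParams(tau_rise_h=0))


class TestSchedule:
    def test_invalid_lux_rejected(self):
        with pytest.raises(ValueError):
            LightSchedule(light_lux=5.0, night_lux=5.0)

    def test_zt_dark_half(self):
        sched = LightSchedule()
        assert not sched.is_dark(3.0)
        assert sched.is_dark(12.0)
        assert not sched.is_dark(24.0)

    def test_dlan_is_a_label_only(self):
        ld = dataclasses.replace(ActivityGenParams(seed=1))
        a = simulate_activity(ld, LightSchedule(night_lux=0.0))
        b = simulate_activity(ld, LightSchedule(night_lux=5.0))
        np.testing.assert_array_equal(a.counts, b.counts)
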