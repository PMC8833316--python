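"""Phase-amplitude coupling: band extraction, MVL estimator, comodulograms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as stn
from scipy import signal

from megpac import (SubjectSimConfig, VirtualElectrode, comodulogram,
                    corrected_comodulogram, extract_amplitude, extract_phase,
                    mvl_ozkurt, simulate_subject)

from conftest import tone_ve


def _simulated_ve(m, seed=0, n_trials=20, m_base=0.0, noise=0.15):
    cfg = SubjectSimConfig(fs_raw=300.0, n_trials=n_trials, seed=seed,
                           coupling_m=m, coupling_m_base=m_base,
                           noise_amp=noise, alpha_freq=10.0, gamma_freq=55.0)
    return VirtualElectrode.from_epochs(simulate_subject(cfg))


class TestExtractPhase:
    def test_phase_advances_linearly_at_band_frequency(self):
        ve = tone_ve(10.0, n_trials=2)
        ph = extract_phase(ve, 10.0)
        core = slice(300, -300)
        slopes = np.diff(np.unwrap(ph[:, core], axis=1), axis=1) * ve.fs
        assert np.median(slopes) == pytest.approx(2 * np.pi * 10.0, rel=0.01)

    def test_out_of_band_tone_attenuated(self):
        ve = tone_ve(13.0, n_trials=1)
        spec10 = signal.butter(4, [9.0, 11.0], btype="bandpass", fs=ve.fs, output="sos")
        filtered = signal.sosfiltfilt(spec10, ve.data)
        in_amp = np.abs(ve.data[:, 300:-300]).max()
        out_amp = np.abs(filtered[:, 300:-300]).max()
        assert 20 * np.log10(in_amp / out_amp) > 10.0

    def test_cosine_convention_zero_phase_at_peaks(self):
        ve = tone_ve(10.0, n_trials=1, seed=2)
        ph = extract_phase(ve, 10.0)
        x = signal.sosfiltfilt(
            signal.butter(4, [9.0, 11.0], btype="bandpass", fs=ve.fs, output="sos"),
            ve.data)
        core = slice(300, -300)
        peaks, _ = signal.find_peaks(x[0, core])
        peak_phases = ph[0, core][peaks]
        err = np.degrees(np.angle(np.exp(1j * peak_phases)))
        assert np.max(np.abs(err)) < 5.0


class TestExtractAmplitude:
    def test_unmodulated_tone_has_flat_envelope(self):
        ve = tone_ve(60.0, n_trials=2)
        env = extract_amplitude(ve, 60.0, half_bw=13.0)[:, 300:-300]
        assert np.std(env) / np.mean(env) < 0.05
        assert np.mean(env) == pytest.approx(1.0, rel=0.05)

    def test_am_modulation_recovered_in_envelope_spectrum(self):
        fs = 300.0
        t = np.arange(int(6 * fs)) / fs
        x = (1 + 0.8 * np.cos(2 * np.pi * 10.0 * t)) * np.cos(2 * np.pi * 60.0 * t)
        times = t - 3.0
        ve = VirtualElectrode(data=x[None, :], fs=fs, times=times)
        env = extract_amplitude(ve, 60.0, half_bw=13.0)[0, 300:-300]
        f, p = signal.periodogram(env - env.mean(), fs=fs)
        assert f[np.argmax(p)] == pytest.approx(10.0, abs=0.5)

    def test_narrow_amplitude_band_degrades_modulation_recovery(self):
        fs = 300.0
        t = np.arange(int(6 * fs)) / fs
        x = (1 + 0.8 * np.cos(2 * np.pi * 10.0 * t)) * np.cos(2 * np.pi * 60.0 * t)
        ve = VirtualElectrode(data=x[None, :], fs=fs, times=t - 3.0)

        def depth(half_bw):
            env = extract_amplitude(ve, 60.0, half_bw=half_bw)[0, 300:-300]
            return (env.max() - env.min()) / (env.max() + env.min())

        assert depth(5.0) < depth(13.0)

    def test_band_above_nyquist_rejected(self):
        ve = tone_ve(60.0, n_trials=1)
        with pytest.raises(ValueError):
            extract_amplitude(ve, 145.0, half_bw=13.0)


class TestMvlOzkurt:
    def test_uniform_phases_constant_amplitude_is_zero(self):
        n = 1000
        phase = np.linspace(0, 10 * 2 * np.pi, n, endpoint=False)
        assert mvl_ozkurt(phase, np.ones(n)) < 1e-10

    def test_constant_phase_is_exactly_one(self):
        assert mvl_ozkurt(np.full(50, 1.3), np.full(50, 2.7)) == pytest.approx(1.0)

    def test_four_point_worked_example(self):
        # |2*e^0 + e^{i pi/2} + e^{i pi} + e^{3i pi/2}| = 1
        # MVL = 1 / (sqrt(4) * sqrt(7)) = 1 / (2 sqrt(7))
        val = mvl_ozkurt([0, np.pi / 2, np.pi, 3 * np.pi / 2], [2, 1, 1, 1])
        assert val == pytest.approx(1 / (2 * np.sqrt(7)), abs=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(stn.integers(min_value=2, max_value=200), stn.integers(0, 2 ** 31 - 1))
    def test_bounded_in_unit_interval_for_arbitrary_input(self, n, seed):
        rng = np.random.default_rng(seed)
        phase = rng.uniform(-np.pi, np.pi, n)
        amp = rng.gamma(1.0, 1.0, n) + 1e-12
        assert 0.0 <= mvl_ozkurt(phase, amp) <= 1.0

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(stn.floats(min_value=1e-6, max_value=1e6), stn.integers(0, 2 ** 31 - 1))
    def test_amplitude_scale_invariance(self, c, seed):
        rng = np.random.default_rng(seed)
        phase = rng.uniform(-np.pi, np.pi, 64)
        amp = rng.random(64) + 0.01
        assert mvl_ozkurt(phase, c * amp) == pytest.approx(mvl_ozkurt(phase, amp),
                                                           rel=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            mvl_ozkurt([0.0, 1.0], [0.0, 0.0])
        with pytest.raises(ValueError):
            mvl_ozkurt([0.0], [1.0])
        with pytest.raises(ValueError):
            mvl_ozkurt([0.0, 1.0], [1.0, -1.0])


class TestComodulogram:
    def test_default_grid_is_7_by_34(self, coupled_ve):
        comod = comodulogram(coupled_ve)
        assert comod.values.shape == (7, 34)
        np.testing.assert_array_equal(comod.phase_freqs, np.arange(7, 14))
        np.testing.assert_array_equal(comod.amp_freqs, np.arange(34, 101, 2))

    def test_white_noise_stays_near_mvl_null_scale(self):
        rng = np.random.default_rng(4)
        n = 1500
        times = (np.arange(n) - n // 2) / 300.0
        ve = VirtualElectrode(data=rng.standard_normal((100, n)), fs=300.0, times=times)
        comod = comodulogram(ve)
        assert comod.values.max() < 0.1

    def test_programmed_coupling_peak_recovered(self, coupled_ve):
        comod = corrected_comodulogram(coupled_ve)
        fp, fa = comod.peak_bin()
        assert abs(fp - 10.0) <= 1.0
        assert abs(fa - 55.0) <= 3.0

    def test_mvl_monotone_in_modulation_depth(self):
        # noiseless signals, m in {0, 0.25, 0.5, 0.75, 1}
        vals = []
        for m in (0.0, 0.25, 0.5, 0.75, 1.0):
            ve = _simulated_ve(m, n_trials=6, noise=0.0)
            comod = comodulogram(ve, phase_freqs=np.array([10.0]),
                                 amp_freqs=np.array([54.0]))
            vals.append(comod.values[0, 0])
        assert all(a <= b + 1e-9 for a, b in zip(vals, vals[1:]))
        assert vals[-1] > vals[0]

    def test_trial_shuffled_surrogates_match_uncoupled_mean(self):
        # null behaviour: uncoupled PAC lies within 3 SE of the mean of
        # surrogates built by pairing phase and amplitude from different trials
        ve = _simulated_ve(0.0, seed=5, n_trials=30)
        ph = extract_phase(ve, 10.0)
        am = extract_amplitude(ve, 56.0)
        mask = ve.time_mask(0.3, 1.5)
        obs = mvl_ozkurt(ph[:, mask], am[:, mask])
        rng = np.random.default_rng(6)
        sur = np.array([
            mvl_ozkurt(ph[rng.permutation(ve.n_trials)][:, mask], am[:, mask])
            for _ in range(200)
        ])
        se = sur.std(ddof=1)
        assert abs(obs - sur.mean()) < 3 * se + 1e-6


class TestCorrectedComodulogram:
    def test_stationary_coupling_cancels(self):
        ve = _simulated_ve(0.5, m_base=0.5, seed=7, n_trials=40)
        comod = corrected_comodulogram(ve)
        # residual within the MVL null scale for ~14k samples per window
        assert np.max(np.abs(comod.values)) < 0.05

    def test_post_onset_coupling_equals_uncorrected_at_peak(self):
        ve = _simulated_ve(0.9, seed=8, n_trials=30)
        unc = comodulogram(ve, window=(0.3, 1.5))
        cor = corrected_comodulogram(ve)
        i, j = np.unravel_index(np.argmax(unc.values), unc.values.shape)
        base = comodulogram(ve, window=(-1.5, -0.3))
        assert cor.values[i, j] == pytest.approx(
            unc.values[i, j] - base.values[i, j], abs=1e-12)
        assert cor.values[i, j] == pytest.approx(unc.values[i, j], abs=0.08)

    def test_unequal_windows_rejected(self, coupled_ve):
        with pytest.raises(ValueError):
            corrected_comodulogram(coupled_ve, stim_win=(0.3, 1.5),
                                   base_win=(-1.0, -0.3))

    def test_decimation_order_regression(self):
        # running PAC at 1000 Hz vs the decimated 300 Hz rate must agree
        cfg = SubjectSimConfig(n_trials=20, seed=9, coupling_m=0.8)
        from megpac import decimate
        ep = simulate_subject(cfg)
        c_raw = corrected_comodulogram(VirtualElectrode.from_epochs(ep))
        c_dec = corrected_comodulogram(
            VirtualElectrode.from_epochs(decimate(ep, 300.0)))
        assert np.max(np.abs(c_raw.values - c_dec.values)) < 0.05
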