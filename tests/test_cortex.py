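"""Nonlinear cortex simulator: susceptibilities, mixing products, noise."""

import dataclasses

import numpy as np
import pytest
from numpy.fft import rfft

from ssvep_bci import (
    CortexModel,
    Waveform,
    chi2_profile,
    compute_npsd,
    sfg_lines_noisy,
    sfg_spectrum_analytic,
    simulate_eeg,
    synthesize_waveform,
)
from ssvep_bci.fdm import FrequencyComb

from conftest import random_two_band_combs


def _line_amplitude(eeg: Waveform, f: float) -> float:
    """Cosine amplitude at an exact DFT bin of the full record."""
    spec = rfft(eeg.samples)
    k = int(round(f * eeg.duration))
    assert abs(k - f * eeg.duration) < 1e-9, "frequency must be an exact bin"
    return 2.0 * abs(spec[k]) / eeg.n_samples


class TestChi2Profile:
    def test_value_at_zero_is_scale(self):
        m = CortexModel(chi2_scale=2.5)
        assert chi2_profile(0.0, m) == pytest.approx(2.5)

    def test_exponential_ratio_per_decay_constant(self):
        m = CortexModel(chi2_decay=10.0)
        for f in (0.0, 7.3, 40.0):
            assert chi2_profile(f + 10.0, m) / chi2_profile(f, m) == pytest.approx(np.exp(-1))

    def test_monotone_decreasing(self):
        m = CortexModel()
        grid = chi2_profile(np.linspace(0, 100, 401), m)
        assert np.all(np.diff(grid) < 0)

    def test_negative_frequency_rejected(self):
        with pytest.raises(ValueError):
            chi2_profile(-1.0, CortexModel())


class TestSimulateEEG:
    def test_linear_identity(self):
        # chi2 off, unit gain, no noise: the simulator is the identity
        model = CortexModel(chi2_scale=0.0).noiseless()
        comb = FrequencyComb(10.0, 0.5, np.array([1.0, 0.4, 0.2]))
        stim = synthesize_waveform(comb, sample_rate=100.0)
        out = simulate_eeg(stim, model)
        np.testing.assert_allclose(out.samples, stim.samples, atol=1e-9)

    def test_two_tone_mixing_products(self, flat_chi2_model):
        # x = cos(2pi 15t) + cos(2pi 20t); x^2 has lines at 5, 30, 35, 40 Hz
        # with the 35 Hz sum line exactly twice the harmonic lines
        comb = FrequencyComb(15.0, 5.0, np.array([1.0, 1.0]))
        stim = synthesize_waveform(comb, sample_rate=1000.0, n_periods=2)
        out = simulate_eeg(stim, flat_chi2_model)
        amp = {f: _line_amplitude(out, f) for f in (5, 15, 20, 30, 35, 40)}
        for f in (15, 20):  # first order preserved
            assert amp[f] == pytest.approx(1.0, abs=1e-9)
        assert amp[35] == pytest.approx(2 * amp[30], rel=1e-9)
        assert amp[35] == pytest.approx(2 * amp[40], rel=1e-9)
        assert amp[5] == pytest.approx(amp[35], rel=1e-9)  # difference line
        assert amp[35] == pytest.approx(1.0, abs=1e-9)

    def test_second_order_homogeneity_in_gain(self, noiseless_model):
        comb = FrequencyComb(15.0, 5.0, np.array([0.5, 0.5]))
        stim = synthesize_waveform(comb, sample_rate=500.0)
        single = simulate_eeg(stim, noiseless_model)
        double = simulate_eeg(stim, dataclasses.replace(noiseless_model, gain_sigma=2.0))
        assert _line_amplitude(double, 15.0) == pytest.approx(
            2 * _line_amplitude(single, 15.0), rel=1e-9
        )
        assert _line_amplitude(double, 35.0) == pytest.approx(
            4 * _line_amplitude(single, 35.0), rel=1e-9
        )

    def test_blindfold_spectrum_peaks_at_alpha_rhythm(self, default_model):
        # no stimulus: the expected NPSD maximum is the 10 Hz alpha bump
        argmaxes = []
        for seed in range(5):
            eeg = simulate_eeg(Waveform(np.zeros(30 * 500), 500.0), default_model, seed=seed)
            argmaxes.append(round(compute_npsd(eeg).argmax_frequency()))
        assert max(set(argmaxes), key=argmaxes.count) == 10

    def test_seeded_noise_is_bitwise_reproducible(self, default_model):
        stim = Waveform(np.zeros(2000), 500.0)
        a = simulate_eeg(stim, default_model, seed=42)
        b = simulate_eeg(stim, default_model, seed=42)
        c = simulate_eeg(stim, default_model, seed=43)
        assert np.array_equal(a.samples, b.samples)
        assert not np.array_equal(a.samples, c.samples)

    def test_nyquist_guard_for_second_order_products(self, noiseless_model):
        comb = FrequencyComb(15.0, 5.0, np.array([1.0, 1.0]))
        stim = synthesize_waveform(comb, sample_rate=60.0)  # 2*20 = 40 > 30
        with pytest.raises(ValueError, match="Nyquist"):
            simulate_eeg(stim, noiseless_model)

    def test_yaml_dict_roundtrip(self, default_model):
        again = CortexModel.from_dict(default_model.to_dict())
        assert again == default_model


class TestAnalyticSFG:
    def test_single_line_pair_weight(self):
        model = CortexModel(chi2_scale=1.0, chi2_decay=np.inf).noiseless()
        X = FrequencyComb(15.0, 0.5, np.array([1.0]))
        A = FrequencyComb(20.0, 0.5, np.array([1.0]))
        freqs, w = sfg_spectrum_analytic(X, A, model)
        np.testing.assert_allclose(freqs, [35.0])
        assert w[0] == pytest.approx(np.pi / 2)

    def test_dense_comb_line_count_and_convolution_weights(self, noiseless_model):
        rng = np.random.default_rng(0)
        a, b = rng.random(64), rng.random(64)
        X = FrequencyComb(15.0, 0.5 / 64, a)
        A = FrequencyComb(20.0, 0.5 / 64, b)
        freqs, w = sfg_spectrum_analytic(X, A, noiseless_model)
        # two 64-line combs of equal spacing have 127 distinct sums
        assert freqs.size == 127
        # independent pairwise-sum oracle
        expected = np.zeros(127)
        for m in range(64):
            for n in range(64):
                expected[m + n] += a[m] * b[n]
        expected *= (np.pi / 2) * chi2_profile(freqs, noiseless_model)
        np.testing.assert_allclose(w, expected, rtol=1e-12)

    def test_overlapping_bands_rejected(self, noiseless_model):
        X = FrequencyComb(15.0, 0.1, np.ones(4))
        A = FrequencyComb(15.2, 0.1, np.ones(4))
        with pytest.raises(ValueError):
            sfg_spectrum_analytic(X, A, noiseless_model)

    def test_matches_time_domain_simulation_on_sum_band(self, noiseless_model):
        # oracle equivalence: analytic weights vs DFT of the full nonlinear
        # simulation restricted to the sum band (rel. error < 1e-6)
        rng = np.random.default_rng(11)
        for _ in range(20):
            X, A = random_two_band_combs(rng)
            freqs, w = sfg_spectrum_analytic(X, A, noiseless_model)
            gap = int(round((A.f0 - X.f0) / X.delta_f))
            amps = np.zeros(gap + A.n_lines)
            amps[: X.n_lines] = X.amplitudes
            amps[gap:] = A.amplitudes
            stim = synthesize_waveform(FrequencyComb(X.f0, X.delta_f, amps), 512.0, 1)
            eeg = simulate_eeg(stim, noiseless_model)
            measured = (np.pi / 2) * np.array([_line_amplitude(eeg, f) for f in freqs])
            np.testing.assert_allclose(measured, w, rtol=1e-6)

    def test_noisy_line_simulator_reduces_to_analytic_without_noise(self, noiseless_model):
        rng = np.random.default_rng(3)
        X, A = random_two_band_combs(rng)
        freqs_a, w = sfg_spectrum_analytic(X, A, noiseless_model)
        freqs_n, power = sfg_lines_noisy(X, A, noiseless_model, seed=0)
        np.testing.assert_allclose(freqs_n, freqs_a)
        np.testing.assert_allclose(power, w**2, rtol=1e-12)

    def test_noisy_line_simulator_is_seed_reproducible(self, default_model):
        rng = np.random.default_rng(4)
        X, A = random_two_band_combs(rng)
        _, p1 = sfg_lines_noisy(X, A, default_model, seed=5)
        _, p2 = sfg_lines_noisy(X, A, default_model, seed=5)
        _, p3 = sfg_lines_noisy(X, A, default_model, seed=6)
        assert np.array_equal(p1, p2)
        assert not np.array_equal(p1, p3)
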