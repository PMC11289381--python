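"""Physical neural network: encoding, readout, GA training, stacking."""

import numpy as np
import pytest

from ssvep_bci import (
    CortexModel,
    GAConfig,
    NPSD,
    PNNLayer,
    attention_gain,
    calibrate_segment_edges,
    classify,
    encode_pnn_input,
    layer_output_npsd,
    plan_bands,
    predict_proba,
    predict_proba_two_layer,
    quantize_features,
    stack_layer,
    train_alpha_ga,
)
from ssvep_bci.fixtures import digit_template
from ssvep_bci.pipeline import make_two_layer_network


@pytest.fixture
def small_layer():
    plan = plan_bands(10, 10, 15.0, 20.0, 0.5)
    return PNNLayer(band_plan=plan, n_classes=3)


class TestEncodePNNInput:
    def test_combined_comb_geometry_and_power(self, pnn_plan):
        rng = np.random.default_rng(0)
        layer = PNNLayer(band_plan=pnn_plan, n_classes=2, alpha=rng.random(64))
        comb = encode_pnn_input(rng.random(64), layer)
        assert comb.period == pytest.approx(128.0)
        assert comb.f0 == 15.0
        assert comb.max_frequency == pytest.approx(20.5 - 0.5 / 64)
        # one unit of squared amplitude per band after balancing
        assert np.sum(comb.amplitudes**2) == pytest.approx(2.0, abs=1e-12)

    def test_all_zero_data_rejected(self, pnn_plan):
        layer = PNNLayer(band_plan=pnn_plan, n_classes=2, alpha=np.ones(64))
        with pytest.raises(ValueError, match="all-zero"):
            encode_pnn_input(np.zeros(64), layer)

    def test_length_mismatch_rejected(self, pnn_plan):
        layer = PNNLayer(band_plan=pnn_plan, n_classes=2, alpha=np.ones(64))
        with pytest.raises(ValueError, match="64"):
            encode_pnn_input(np.ones(63), layer)


class TestQuantizeFeatures:
    def test_five_features_two_bits_give_ten_components(self):
        out = quantize_features(np.array([0.0, 0.3, 0.5, 0.8, 1.0]), 0.0, 1.0, bits=2)
        assert out.shape == (10,)
        assert set(out.tolist()) <= {0.0, 1.0}

    def test_extreme_values_hit_extreme_codes(self):
        out = quantize_features(np.array([0.0, 1.0]), 0.0, 1.0, bits=2)
        np.testing.assert_array_equal(out, [0, 0, 1, 1])

    def test_msb_first_binary_expansion(self):
        # level 2 of 4 (value in [0.5, 0.75)) is binary 10
        np.testing.assert_array_equal(quantize_features(np.array([0.6]), 0.0, 1.0, 2), [1, 0])

    def test_out_of_range_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            out = quantize_features(np.array([-0.5, 1.5]), 0.0, 1.0, bits=1)
        np.testing.assert_array_equal(out, [0, 1])

    def test_table_input_quantizes_rowwise(self):
        table = np.tile(np.array([0.0, 1.0]), (3, 1))
        assert quantize_features(table, 0.0, 1.0, 2).shape == (3, 4)


class TestClassify:
    def _npsd(self, plan, power):
        return NPSD(plan.sum_frequencies(), power, plan.delta_f)

    def test_single_hot_segment(self, small_layer):
        power = np.zeros(19)
        power[9] = 1.0  # central line -> middle segment
        probs = classify(self._npsd(small_layer.band_plan, power), small_layer)
        np.testing.assert_allclose(probs, [0, 1, 0])

    def test_uniform_power_with_equal_line_counts(self):
        plan = plan_bands(8, 8, 15.0, 20.0, 0.5)
        # 15 sum lines; edges chosen so each segment holds exactly 5 lines
        layer = PNNLayer(
            band_plan=plan,
            n_classes=3,
            segment_edges=np.array([35.0, 35.28125, 35.59375, 36.0]),
        )
        probs = classify(NPSD(plan.sum_frequencies(), np.ones(15), plan.delta_f), layer)
        np.testing.assert_allclose(probs, [1 / 3, 1 / 3, 1 / 3])

    def test_probabilities_sum_to_one_for_random_spectra(self, small_layer):
        rng = np.random.default_rng(0)
        for _ in range(20):
            probs = classify(self._npsd(small_layer.band_plan, rng.random(19)), small_layer)
            assert probs.sum() == pytest.approx(1.0, abs=1e-12)
            assert (probs >= 0).all()

    def test_scale_invariance(self, small_layer):
        rng = np.random.default_rng(1)
        power = rng.random(19)
        p1 = classify(self._npsd(small_layer.band_plan, power), small_layer)
        p2 = classify(self._npsd(small_layer.band_plan, 37.5 * power), small_layer)
        np.testing.assert_allclose(p1, p2, atol=1e-12)

    def test_quadratic_readout_sharpens(self, small_layer):
        import dataclasses

        power = np.concatenate([np.full(7, 0.5), np.full(6, 1.0), np.full(6, 0.5)])
        quad = dataclasses.replace(small_layer, readout="quadratic")
        p_lin = classify(self._npsd(small_layer.band_plan, power), small_layer)
        p_quad = classify(self._npsd(small_layer.band_plan, power), quad)
        assert p_quad[1] > p_lin[1]

    def test_zero_sum_band_power_warns_and_returns_uniform(self, small_layer):
        with pytest.warns(UserWarning, match="zero total"):
            probs = classify(self._npsd(small_layer.band_plan, np.zeros(19)), small_layer)
        np.testing.assert_allclose(probs, [1 / 3, 1 / 3, 1 / 3])

    def test_calibrated_edges_make_featureless_input_uniform(self, default_model):
        plan = plan_bands(10, 10, 15.0, 20.0, 0.5)
        layer = PNNLayer(
            band_plan=plan,
            n_classes=3,
            alpha=np.ones(10),
            segment_edges=calibrate_segment_edges(plan, default_model, 3),
        )
        probs = predict_proba(np.ones(10), layer, default_model.noiseless())
        assert np.abs(probs - 1 / 3).max() < 0.12  # far from the ~(0.2, 0.6, 0.2) of equal width


class TestTrainAlphaGA:
    def test_fitness_trace_is_monotone_under_elitism(self, pnn_plan, noiseless_model):
        x = np.array([digit_template(0, 8).reshape(-1), digit_template(1, 8).reshape(-1)])
        layer = PNNLayer(band_plan=pnn_plan, n_classes=2)
        ga = GAConfig(population=8, generations=10, seed=0)
        result = train_alpha_ga(x, np.array([0, 1]), layer, noiseless_model, ga)
        assert np.all(np.diff(result.fitness_trace) >= 0)

    def test_training_is_seed_reproducible(self, pnn_plan, noiseless_model):
        x = np.array([digit_template(0, 8).reshape(-1), digit_template(1, 8).reshape(-1)])
        layer = PNNLayer(band_plan=pnn_plan, n_classes=2)
        ga = GAConfig(population=8, generations=5, seed=3)
        r1 = train_alpha_ga(x, np.array([0, 1]), layer, noiseless_model, ga)
        r2 = train_alpha_ga(x, np.array([0, 1]), layer, noiseless_model, ga)
        assert np.array_equal(r1.alpha, r2.alpha)
        assert np.array_equal(r1.fitness_trace, r2.fitness_trace)

    def test_separates_template_digits(self, pnn_plan, noiseless_model):
        x = np.array([digit_template(0, 8).reshape(-1), digit_template(1, 8).reshape(-1)])
        labels = np.array([0, 1])
        layer = PNNLayer(band_plan=pnn_plan, n_classes=2)
        ga = GAConfig(population=32, generations=30, seed=1)
        result = train_alpha_ga(x, labels, layer, noiseless_model, ga)
        trained = layer.with_alpha(result.alpha)
        probs = np.array([predict_proba(xi, trained, noiseless_model) for xi in x])
        assert np.array_equal(np.argmax(probs, axis=1), labels)

    def test_single_class_labels_rejected(self, pnn_plan, noiseless_model):
        x = np.ones((3, 64))
        layer = PNNLayer(band_plan=pnn_plan, n_classes=2)
        with pytest.raises(ValueError, match="fewer than 2"):
            train_alpha_ga(x, np.zeros(3), layer, noiseless_model, GAConfig(seed=0))


class TestStacking:
    def test_translation_preserves_amplitude_ratios(self, noiseless_model):
        plan1 = plan_bands(4, 4, 15.0, 20.0, 0.2)
        plan2 = plan_bands(7, 7, 15.0, 20.0, 0.35)  # same 0.05 Hz spacing
        layer1 = PNNLayer(band_plan=plan1, n_classes=2, alpha=np.array([1.0, 0.2, 0.4, 0.8]))
        layer2 = PNNLayer(band_plan=plan2, n_classes=2, alpha=np.ones(7))
        npsd1 = layer_output_npsd(np.array([1.0, 0.5, 0.3, 0.9]), layer1, noiseless_model)
        comb2 = stack_layer(npsd1, layer1, layer2)
        re_encoded = comb2.amplitudes[:7]
        ratios = re_encoded[npsd1.power > 0] / npsd1.power[npsd1.power > 0]
        assert np.ptp(ratios) < 1e-9 * ratios[0]
        assert comb2.f0 == 15.0

    def test_capacity_overflow_rejected(self, noiseless_model):
        plan1 = plan_bands(4, 4, 15.0, 20.0, 0.2)
        plan2 = plan_bands(3, 3, 15.0, 20.0, 0.15)  # 7 output lines > 3 slots
        layer1 = PNNLayer(band_plan=plan1, n_classes=2, alpha=np.ones(4))
        layer2 = PNNLayer(band_plan=plan2, n_classes=2, alpha=np.ones(3))
        npsd1 = layer_output_npsd(np.ones(4), layer1, noiseless_model)
        with pytest.raises(ValueError, match="capacity"):
            stack_layer(npsd1, layer1, layer2)

    def test_second_layer_products_stay_in_its_sum_band(self, noiseless_model):
        # end-to-end time-domain run: all layer-2 intermodulation lines lie
        # inside layer 2's planned sum band
        from numpy.fft import rfft, rfftfreq

        from ssvep_bci import compute_npsd, simulate_eeg, synthesize_waveform

        plan1 = plan_bands(4, 4, 15.0, 20.0, 0.2)
        plan2 = plan_bands(7, 7, 15.0, 20.0, 0.35)
        layer1 = PNNLayer(band_plan=plan1, n_classes=2, alpha=np.array([1.0, 0.3, 0.6, 0.2]))
        layer2 = PNNLayer(band_plan=plan2, n_classes=2, alpha=np.linspace(0.2, 1, 7))
        comb1 = encode_pnn_input(np.array([0.9, 0.1, 0.5, 0.7]), layer1)
        eeg1 = simulate_eeg(synthesize_waveform(comb1, 200.0), noiseless_model)
        npsd1 = compute_npsd(eeg1, record_length=comb1.period)
        comb2 = stack_layer(npsd1, layer1, layer2)
        eeg2 = simulate_eeg(synthesize_waveform(comb2, 200.0), noiseless_model)
        spec = np.abs(rfft(eeg2.samples))
        freqs = rfftfreq(eeg2.n_samples, 1 / 200.0)
        in_products = freqs > plan2.control_band.stop + 1e-9
        significant = spec > 1e-9 * spec.max()
        prods = freqs[in_products & significant]
        sum_band = (prods >= plan2.sum_band.start) & (prods <= plan2.sum_band.stop)
        harm = (prods >= plan2.harmonic_image.start) & (prods <= plan2.harmonic_control.stop)
        assert np.all(sum_band | harm)
        assert sum_band.any()

    def test_two_layer_probabilities_are_valid_in_both_modes(self, default_model):
        layer1, layer2 = make_two_layer_network(default_model)
        layer1 = layer1.with_alpha(np.linspace(0.1, 1, 10))
        layer2 = layer2.with_alpha(np.array([0.9, 0.5, 0.2]))
        x = quantize_features(np.array([0.1, 0.9, 0.4, 0.7, 0.2]), 0.0, 1.0, 2)
        for stack in ("readout", "lines"):
            l2 = layer2
            if stack == "lines":
                plan2 = plan_bands(19, 19, 15.0, 20.0, 0.95)
                l2 = PNNLayer(band_plan=plan2, n_classes=3, alpha=np.ones(19))
            for sim in ("analytic", "time_domain"):
                probs = predict_proba_two_layer(
                    x, layer1, l2, default_model, sim=sim, seed=0, sample_rate=200.0, stack=stack
                )
                assert probs.shape == (3,)
                assert probs.sum() == pytest.approx(1.0, abs=1e-9)
                assert (probs >= 0).all()


class TestAttentionGain:
    def test_full_focus_returns_model_unchanged(self, default_model):
        assert attention_gain(default_model, 1.0) is default_model

    def test_sum_band_power_scales_quadratically(self, noiseless_model, small_layer):
        layer = small_layer.with_alpha(np.linspace(0.2, 1, 10))
        x = np.linspace(0.1, 1, 10)
        full = layer_output_npsd(x, layer, noiseless_model)
        disrupted = layer_output_npsd(x, layer, attention_gain(noiseless_model, 0.5))
        # NPSD is max-normalized, so compare raw line powers via the model
        from ssvep_bci import sfg_spectrum_analytic
        from ssvep_bci.fdm import FrequencyComb, normalize_balanced

        xb, ab = normalize_balanced(x, layer.alpha)
        X = FrequencyComb(15.0, 0.05, xb)
        A = FrequencyComb(20.0, 0.05, ab)
        _, w_full = sfg_spectrum_analytic(X, A, noiseless_model)
        _, w_disr = sfg_spectrum_analytic(X, A, attention_gain(noiseless_model, 0.5))
        np.testing.assert_allclose(w_disr**2, 0.25 * w_full**2, rtol=1e-12)
        # normalized spectra are identical (uniform scaling)
        np.testing.assert_allclose(full.power, disrupted.power, atol=1e-12)

    def test_correct_class_probability_degrades_with_disruption(self, default_model):
        # lower attention gain -> weaker intermodulation vs noise -> the
        # trained class is read out less confidently (mean over seeds)
        plan = plan_bands(10, 10, 15.0, 20.0, 0.5)
        layer = PNNLayer(
            band_plan=plan,
            n_classes=3,
            alpha=np.linspace(0.2, 1, 10),
            segment_edges=calibrate_segment_edges(plan, default_model, 3),
        )
        x = np.array([1, 1, 0, 0, 1, 1, 0, 0, 1, 1.0])
        cls = int(np.argmax(predict_proba(x, layer, default_model.noiseless())))
        def mean_top_prob(model):
            return np.mean([predict_proba(x, layer, model, seed=s)[cls] for s in range(20)])
        focus = mean_top_prob(default_model)
        disrupt = mean_top_prob(attention_gain(default_model, 0.05))
        assert disrupt <= focus

    @pytest.mark.parametrize("gain", [0.0, 1.5, -0.2])
    def test_gain_outside_unit_interval_rejected(self, default_model, gain):
        with pytest.raises(ValueError):
            attention_gain(default_model, gain)
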