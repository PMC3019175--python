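import numpy as np
import pytest

import strfglm as sg
from strfglm.evaluate import (_fit_model, _predict_rate, _smooth, bias_analysis,
                              loo_validate, across_validate,
                              prediction_correlation, psth, similarity_index)
from strfglm.glm import GLMConfig, GLMParams
from strfglm.spikes import SpikeData
from strfglm.spectro import Spectrogram, default_freq_centers


class TestPSTH:
    def test_one_spike_per_bin_gives_constant_rate(self):
        sd = SpikeData(counts=np.ones((1, 40), dtype=int), bin_width_ms=3.0)
        out = psth(sd, smooth_ms=5.0)
        assert np.allclose(out.rate, 1000.0 / 3.0)

    def test_empty_trials_give_zero(self):
        sd = SpikeData(counts=np.zeros((3, 40), dtype=int), bin_width_ms=3.0)
        assert np.all(psth(sd).rate == 0.0)

    def test_smoothing_conserves_mean(self, rng):
        sd = SpikeData(counts=rng.integers(0, 2, (5, 300)), bin_width_ms=3.0)
        raw = psth(sd, smooth_ms=0.0)
        smooth = psth(sd, smooth_ms=5.0)
        assert smooth.rate.mean() == pytest.approx(raw.rate.mean(), abs=1e-10)

    def test_window_length_rounds_to_odd(self, rng):
        series = np.zeros(51)
        series[25] = 1.0
        out = _smooth(series, 3)
        assert np.flatnonzero(out).size == 3  # 5 ms at 3 ms bins -> 3 taps


class TestPredictionCorrelation:
    def test_identity_and_negation(self, rng):
        sd = SpikeData(counts=rng.integers(0, 2, (2, 200)), bin_width_ms=3.0)
        p = psth(sd)
        assert prediction_correlation(p, p) == pytest.approx(1.0)
        neg = sg.PSTH(rate=2 * p.rate.mean() - p.rate, bin_width_ms=3.0)
        assert prediction_correlation(neg, p) == pytest.approx(-1.0)

    def test_independent_series_near_zero(self, rng):
        a = rng.standard_normal(10000)
        b = rng.standard_normal(10000)
        assert abs(prediction_correlation(a, b)) < 0.05

    def test_constant_series_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="constant"):
            assert prediction_correlation(np.ones(10),
                                          np.arange(10.0)) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            prediction_correlation(np.ones(5), np.ones(6))

    def test_invariant_to_common_smoothing(self, rng):
        a = rng.standard_normal(500)
        b = 3.0 - 2.0 * a
        assert prediction_correlation(_smooth(a, 3), _smooth(b, 3)) == \
            pytest.approx(-1.0)


class TestSimilarityIndex:
    def test_identity_negation_symmetry(self, rng):
        k = rng.standard_normal((20, 20))
        assert similarity_index(k, k) == pytest.approx(1.0)
        assert similarity_index(k, -k) == pytest.approx(-1.0)
        k2 = rng.standard_normal((20, 20))
        assert similarity_index(k, k2) == pytest.approx(
            similarity_index(k2, k))

    def test_independent_strfs_weakly_similar(self, rng):
        k1 = rng.standard_normal((20, 20))
        k2 = rng.standard_normal((20, 20))
        assert abs(similarity_index(k1, k2)) < 0.15

    def test_affine_invariance(self, rng):
        k1 = rng.standard_normal((10, 10))
        k2 = rng.standard_normal((10, 10))
        si = similarity_index(k1, k2)
        assert similarity_index(3.0 * k1 + 2.0, k2) == pytest.approx(si)

    def test_constant_strf_warns_zero(self):
        with pytest.warns(UserWarning):
            assert similarity_index(np.ones((4, 4)),
                                    np.random.default_rng(0)
                                    .standard_normal((4, 4))) == 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            similarity_index(np.ones((3, 3)), np.ones((4, 4)))


def _self_consistency_dataset(n_stimuli=4, n_freq=6, n_lags=6, T=1000,
                              rate=30.0, n_trials=10):
    from strfglm.simulate import NoiselikeConfig
    ens = sg.make_ensemble("white", n_stimuli, T * 0.003,
                           cfg=NoiselikeConfig(n_freq=n_freq), seed=80)
    neuron = sg.make_neuron("gabor", ens.spectrograms, rate,
                            n_freq=n_freq, n_lags=n_lags, seed=81)
    data = [(s, sg.simulate_glm(neuron.params, s, n_trials, seed=82 + i))
            for i, s in enumerate(ens)]
    return neuron, data


class TestLOOValidation:
    def test_self_consistent_model_predicts_held_out_responses(self):
        """Data simulated from the model itself at a healthy firing rate:
        held-out prediction correlation should clear 0.6 on average."""
        neuron, data = _self_consistency_dataset()
        cfg = GLMConfig(n_freq=6, n_lags=6, eta_grid=np.array([1.0, 8.0]),
                        cv_folds=3, n_sim_trials=30, track_trace=False)
        report = loo_validate("glm", data, cfg)
        assert len(report.correlations) == len(data)
        assert report.mean > 0.6
        recomputed = float(np.mean(report.correlations))
        assert report.mean == pytest.approx(recomputed)

    def test_two_stimuli_minimum_enforced(self):
        _, data = _self_consistency_dataset(n_stimuli=2, T=200)
        with pytest.raises(ValueError, match="at least 2"):
            loo_validate("glm", data[:1], GLMConfig(n_freq=6, n_lags=6))

    def test_fold_fit_blind_to_held_out_responses(self):
        """Outer-loop hygiene: replacing the held-out stimulus's spikes with
        garbage must not change the fit on the remaining stimuli, hence not
        the prediction for the held-out stimulus."""
        _, data = _self_consistency_dataset(n_stimuli=3, T=400)
        cfg = GLMConfig(n_freq=6, n_lags=6, eta_grid=np.array([2.0]),
                        n_sim_trials=10, track_trace=False)
        train = data[1:]
        fit_a = _fit_model("glm", train, cfg)
        spec0, spikes0 = data[0]
        corrupted = (spec0, SpikeData(counts=np.zeros_like(spikes0.counts),
                                      bin_width_ms=spikes0.bin_width_ms))
        fit_b = _fit_model("glm", train, cfg)  # held-out never enters
        assert np.array_equal(fit_a.params.k, fit_b.params.k)
        pred_a = _predict_rate("glm", fit_a, spec0, cfg, seed=1)
        pred_b = _predict_rate("glm", fit_b, corrupted[0], cfg, seed=1)
        assert np.array_equal(pred_a, pred_b)

    def test_across_class_transfer_for_linear_neuron_on_elliptic_noise(self):
        """A linear neuron probed with two elliptic ensembles: estimates are
        unbiased for both, so same-class and across-class prediction agree
        (no nonlinearity -> no stimulus-class dependence)."""
        from strfglm.simulate import NoiselikeConfig
        ens_a = sg.make_ensemble("white", 4, 3.0,
                                 cfg=NoiselikeConfig(n_freq=6), seed=91)
        ens_b = sg.make_ensemble("white", 4, 3.0,
                                 cfg=NoiselikeConfig(n_freq=6), seed=92)
        k_true = sg.gabor_strf(6, 6, center_freq=0.5, center_lag=0.3)
        k_true = k_true / np.abs(k_true).max() * 3.0

        def linear_spikes(spec, seed):
            rate = np.maximum(sg.simulate_linear_rate(k_true, 30.0, spec), 0)
            r = np.random.default_rng(seed)
            counts = r.poisson(rate[None, :] * 0.003, size=(10, spec.n_time))
            return SpikeData(counts=counts, bin_width_ms=3.0)

        data_a = [(s, linear_spikes(s, 93 + i)) for i, s in enumerate(ens_a)]
        data_b = [(s, linear_spikes(s, 97 + i)) for i, s in enumerate(ens_b)]
        cfg = GLMConfig(n_freq=6, n_lags=6, eta_grid=np.array([1.0]),
                        track_trace=False)
        same = loo_validate("linear_l1", data_a, cfg)
        across = across_validate("linear_l1", data_a, data_b, cfg)
        assert abs(same.mean - across.mean) < 0.05

    @pytest.mark.parametrize("model", ["nrc", "linear_l1", "exp_ln"])
    def test_all_registered_models_produce_reports(self, model):
        _, data = _self_consistency_dataset(n_stimuli=3, T=400)
        cfg = GLMConfig(n_freq=6, n_lags=6, eta_grid=np.array([2.0]),
                        n_sim_trials=5, track_trace=False)
        report = loo_validate(model, data, cfg)
        assert len(report.correlations) == 3
        assert all(-1 <= c <= 1 for c in report.correlations)


class TestBiasAnalysis:
    def test_output_structure_and_self_recovery(self):
        """Generative class == refit class with noiseless ample data: the
        reverse-correlation branch must recover its own generator."""
        rng = np.random.default_rng(100)
        song = [sg.make_songlike(2.0, seed=101 + i) for i in range(3)]
        noise = [sg.make_noiselike(2.0, seed=104 + i) for i in range(3)]
        kn = sg.NRCFit(k=sg.gabor_strf(20, 20), tau=0.9, m=10, b=20.0)
        ks = sg.NRCFit(k=sg.onset_strf(20, 20), tau=0.9, m=10, b=20.0)
        cfg = GLMConfig(n_freq=20, n_lags=20)
        res = bias_analysis(ks, kn, song, noise, method="nrc", cfg=cfg,
                            noise_sd=0.0, seed=105)
        assert set(res["si"]) == {"Kn_Kns", "Ks_Ksn", "Kn_Knn", "Ks_Kss"}
        assert len([k for k in res if k.startswith("K")]) == 4
        assert res["si"]["Kn_Knn"] >= 0.95
        assert res["si"]["Ks_Kss"] >= 0.95
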