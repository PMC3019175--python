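import numpy as np
import pytest
from scipy.optimize import minimize

import strfglm as sg
from strfglm.glm import (GLMConfig, GLMParams, conditional_intensity,
                         fit_glm, fit_linear_l1, log_likelihood,
                         log_likelihood_gradient, penalized_objective,
                         select_eta)
from strfglm.spectro import Spectrogram, default_freq_centers
from strfglm.spikes import SpikeData

from conftest import tiny_instance, tiny_params


def _flat_spec(values, bw=3.0):
    values = np.asarray(values, dtype=float)
    return Spectrogram(values=values, bin_width_ms=bw,
                       freq_centers_hz=default_freq_centers(values.shape[1]),
                       is_log=True)


def central_differences(f, x, h=1e-6):
    grad = np.zeros_like(x)
    for i in range(x.size):
        step = np.zeros_like(x)
        step[i] = h
        grad[i] = (f(x + step) - f(x - step)) / (2 * h)
    return grad


def brute_force_intensity(params, spec, counts):
    """Direct double-loop evaluation of the conditional intensity."""
    x = spec.values
    T, F = x.shape
    out = np.zeros((counts.shape[0], T))
    for trial in range(counts.shape[0]):
        for t in range(T):
            u = params.b
            for f in range(F):
                for lag in range(params.n_lags):
                    if t - lag >= 0:
                        u += params.k[f, lag] * x[t - lag, f]
            for j in range(1, params.J + 1):
                if t - j >= 0:
                    u += params.h[j - 1] * counts[trial, t - j]
            from strfglm.nonlinearity import eval_nl
            out[trial, t] = eval_nl(params.nonlinearity, min(u, 30.0))
    return out


def brute_force_loglik(theta, x, counts, delta, n_lags, J):
    """Independent, loop-based point-process log-likelihood used as the
    second-opinion objective for optimizer cross-checks."""
    F = x.shape[1]
    b = theta[0]
    k = theta[1:1 + F * n_lags].reshape(F, n_lags)
    h = theta[1 + F * n_lags:]
    ll = 0.0
    for trial in range(counts.shape[0]):
        for t in range(x.shape[0]):
            u = b
            for f in range(F):
                for lag in range(n_lags):
                    if t - lag >= 0:
                        u += k[f, lag] * x[t - lag, f]
            for j in range(1, J + 1):
                if t - j >= 0:
                    u += h[j - 1] * counts[trial, t - j]
            lam = np.exp(min(u, 30.0))
            n = counts[trial, t]
            if n > 0:
                ll += n * np.log(lam * delta)
            ll -= lam * delta
    return ll


class TestConditionalIntensity:
    def test_constant_rate_for_zero_filters(self):
        p = GLMParams(k=np.zeros((3, 4)), h=np.zeros(2), b=1.3)
        spec = _flat_spec(np.random.default_rng(0).standard_normal((50, 3)))
        lam = conditional_intensity(p, spec, np.zeros((2, 50)))
        assert np.allclose(lam, np.exp(1.3))

    def test_single_weight_impulse_convolution_identity(self):
        k = np.zeros((3, 4))
        k[1, 2] = 0.7
        p = GLMParams(k=k, h=np.zeros(0), b=0.0)
        x = np.zeros((30, 3))
        x[10, 1] = 1.0  # impulse at (t0=10, f0=1)
        lam = conditional_intensity(p, _flat_spec(x), np.zeros((1, 30)))
        assert lam[0, 12] == pytest.approx(np.exp(0.7))
        mask = np.ones(30, bool)
        mask[12] = False
        assert np.allclose(lam[0, mask], 1.0)

    def test_matches_brute_force_double_loop(self):
        spec, spikes, params = tiny_instance(T=60, seed=5)
        lam = conditional_intensity(params, spec, spikes.counts)
        expected = brute_force_intensity(params, spec, spikes.counts)
        assert np.max(np.abs(lam / expected - 1.0)) < 1e-12

    def test_mismatched_bin_width_rejected(self):
        p = tiny_params()
        spec, spikes, _ = tiny_instance()
        bad = SpikeData(counts=spikes.counts, bin_width_ms=1.0)
        with pytest.raises(ValueError, match="bin width"):
            conditional_intensity(p, spec, bad)


class TestLogLikelihood:
    def test_constant_rate_no_spikes_integral_term_only(self):
        T, lam_hz = 80, 7.0
        p = GLMParams(k=np.zeros((2, 3)), h=np.zeros(0), b=np.log(lam_hz))
        spec = _flat_spec(np.zeros((T, 2)))
        spikes = SpikeData(counts=np.zeros((1, T), dtype=int), bin_width_ms=3.0)
        assert log_likelihood(p, spec, spikes) == pytest.approx(
            -lam_hz * T * 0.003)

    def test_constant_rate_one_spike(self):
        T, lam_hz = 80, 7.0
        p = GLMParams(k=np.zeros((2, 3)), h=np.zeros(0), b=np.log(lam_hz))
        spec = _flat_spec(np.zeros((T, 2)))
        counts = np.zeros((1, T), dtype=int)
        counts[0, 17] = 1
        spikes = SpikeData(counts=counts, bin_width_ms=3.0)
        assert log_likelihood(p, spec, spikes) == pytest.approx(
            np.log(lam_hz * 0.003) - lam_hz * T * 0.003)

    def test_analytic_gradient_matches_central_differences(self):
        spec, spikes, params = tiny_instance(T=200, seed=11)
        db, dk, dh = log_likelihood_gradient(params, spec, spikes)
        grad = np.concatenate([[db], dk.ravel(), dh])

        def f(theta):
            p = GLMParams(k=theta[1:13].reshape(3, 4), h=theta[13:],
                          b=theta[0])
            return log_likelihood(p, spec, spikes)

        theta0 = np.concatenate([[params.b], params.k.ravel(), params.h])
        num = central_differences(f, theta0)
        assert np.max(np.abs(grad - num)) < 1e-6


class TestPenalizedObjective:
    def test_zero_eta_equals_loglik(self):
        spec, spikes, params = tiny_instance(seed=3)
        assert penalized_objective(params, (spec, spikes), 0.0) == \
            pytest.approx(log_likelihood(params, spec, spikes))

    def test_l1_arithmetic(self):
        spec, spikes, params = tiny_instance(seed=4)
        k = np.zeros((3, 4))
        k[0, 0], k[1, 1] = 1.0, -2.0
        p = GLMParams(k=k, h=params.h, b=params.b)
        diff = penalized_objective(p, (spec, spikes), 0.0) - \
            penalized_objective(p, (spec, spikes), 0.5)
        assert diff == pytest.approx(0.5 * 3.0)

    def test_negative_eta_rejected(self):
        spec, spikes, params = tiny_instance()
        with pytest.raises(ValueError):
            penalized_objective(params, (spec, spikes), -1.0)

    @pytest.mark.parametrize("tag", ["exp", "subexp"])
    def test_midpoint_concavity_100_random_instances(self, tag):
        spec, spikes, _ = tiny_instance(T=120, seed=21, nonlinearity=tag)
        r = np.random.default_rng(99)
        for _ in range(100):
            pa = tiny_params(seed=r.integers(1e6), nonlinearity=tag)
            pb = tiny_params(seed=r.integers(1e6), nonlinearity=tag)
            mid = GLMParams(k=(pa.k + pb.k) / 2, h=(pa.h + pb.h) / 2,
                            b=(pa.b + pb.b) / 2, nonlinearity=tag)
            fa = penalized_objective(pa, (spec, spikes), 0.3)
            fb = penalized_objective(pb, (spec, spikes), 0.3)
            fm = penalized_objective(mid, (spec, spikes), 0.3)
            assert fm >= 0.5 * (fa + fb) - 1e-9


class TestFitting:
    def test_huge_eta_zeroes_strf_and_recovers_mean_rate(self):
        spec, spikes, _ = tiny_instance(T=400, seed=31)
        cfg = GLMConfig(n_freq=3, n_lags=4, J=0, track_trace=False)
        fit = fit_glm([(spec, spikes)], 1e6, cfg)
        assert np.abs(fit.params.k).max() < 1e-8
        # intercept-only model: exp(b) * Delta = mean spikes per bin
        mean_per_bin = spikes.counts.mean()
        assert np.exp(fit.params.b) * 0.003 == pytest.approx(mean_per_bin,
                                                             rel=1e-4)

    def test_unpenalized_fit_matches_independent_optimizer(self):
        """eta=0 solution vs a generic derivative-free concave maximizer
        run on an independently coded double-loop likelihood."""
        r = np.random.default_rng(7)
        x = r.standard_normal((400, 2))
        spec = _flat_spec(x)
        # mild history dependence and a high rate keep every coordinate
        # identified (adjacent-bin spike pairs must actually occur)
        true = GLMParams(k=0.5 * r.standard_normal((2, 2)),
                         h=np.array([-0.5]), b=np.log(60.0))
        spikes = sg.simulate_glm(true, spec, n_trials=3, seed=8)
        cfg = GLMConfig(n_freq=2, n_lags=2, J=1, track_trace=False)
        fit = fit_glm([(spec, spikes)], 0.0, cfg)
        ours = np.concatenate([[fit.params.b], fit.params.k.ravel(),
                               fit.params.h])

        res = minimize(lambda th: -brute_force_loglik(
            th, x, spikes.counts, 0.003, 2, 1), ours + 0.05,
            method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 20000})
        assert np.max(np.abs(ours - res.x)) < 1e-4

    def test_l1_path_monotone_in_eta(self, white_fit_pair):
        _, _, data, cfg = white_fit_pair
        norms = []
        for eta in [0.5, 2.0, 8.0, 32.0, 128.0]:
            fit = fit_glm(data[:3], eta, cfg)
            norms.append(np.abs(fit.params.k).sum())
        assert all(a >= b - 1e-6 for a, b in zip(norms, norms[1:]))

    def test_parameter_recovery_on_white_noise(self, white_fit_pair):
        true_params, fit, _, _ = white_fit_pair
        assert sg.similarity_index(true_params.k, fit.params.k) >= 0.9
        assert abs(fit.params.b - true_params.b) <= 0.1
        # refractory/recovery sign pattern of the history filter preserved
        assert np.array_equal(np.sign(fit.params.h), np.sign(true_params.h))

    def test_fit_is_deterministic(self):
        spec, spikes, _ = tiny_instance(T=300, seed=41)
        cfg = GLMConfig(n_freq=3, n_lags=4, J=2, seed=5)
        f1 = fit_glm([(spec, spikes)], 1.0, cfg)
        f2 = fit_glm([(spec, spikes)], 1.0, cfg)
        assert np.array_equal(f1.params.k, f2.params.k)
        assert np.array_equal(f1.params.h, f2.params.h)
        assert f1.params.b == f2.params.b
        assert f1.objective_trace == f2.objective_trace

    def test_ascent_trace_non_decreasing(self):
        spec, spikes, _ = tiny_instance(T=300, seed=43)
        cfg = GLMConfig(n_freq=3, n_lags=4, J=2)
        fit = fit_glm([(spec, spikes)], 2.0, cfg)
        assert np.all(np.diff(fit.objective_trace) >= 0)

    def test_no_spikes_rejected(self):
        spec, spikes, _ = tiny_instance(T=100, seed=44)
        empty = SpikeData(counts=np.zeros_like(spikes.counts),
                          bin_width_ms=3.0)
        with pytest.raises(ValueError, match="no spikes"):
            fit_glm([(spec, empty)], 1.0, GLMConfig(n_freq=3, n_lags=4, J=2))


class TestEtaSelection:
    def test_single_value_grid_returned(self):
        data = _small_dataset(3)
        cfg = GLMConfig(n_freq=4, n_lags=4, J=2, eta_grid=np.array([3.0]),
                        n_sim_trials=5, track_trace=False)
        eta, table = select_eta(data, cfg)
        assert eta == 3.0 and len(table) == 1

    def test_cv_scores_bounded_and_table_covers_grid(self):
        data = _small_dataset(3)
        grid = np.array([0.5, 5.0, 50.0])
        cfg = GLMConfig(n_freq=4, n_lags=4, J=2, eta_grid=grid,
                        n_sim_trials=5, track_trace=False)
        eta, table = select_eta(data, cfg)
        assert len(table) == grid.size
        assert all(-1.0 <= s <= 1.0 for _, s in table)
        assert eta in grid

    def test_selected_eta_sparser_than_unregularized(self, white_fit_pair):
        true_params, _, data, _ = white_fit_pair
        cfg = GLMConfig(eta_grid=np.array([1.0, 8.0, 64.0]), cv_folds=3,
                        n_sim_trials=10, track_trace=False)
        fit_auto = sg.fit_glm(data, "auto", cfg)
        fit_ml = sg.fit_glm(data, 0.0, cfg)
        thresh = 1e-6 * np.abs(fit_ml.params.k).max()
        nnz_auto = np.sum(np.abs(fit_auto.params.k) > thresh)
        nnz_ml = np.sum(np.abs(fit_ml.params.k) > thresh)
        assert nnz_auto < nnz_ml

    def test_too_few_stimuli_rejected(self):
        data = _small_dataset(2)
        with pytest.raises(ValueError, match="at least 3"):
            select_eta(data, GLMConfig(n_freq=4, n_lags=4, J=2))


def _small_dataset(n_stimuli, n_freq=4, T=200):
    r = np.random.default_rng(50)
    true = GLMParams(k=0.4 * r.standard_normal((n_freq, 4)),
                     h=np.array([-3.0, -1.0]), b=np.log(15.0))
    data = []
    for i in range(n_stimuli):
        spec = _flat_spec(r.standard_normal((T, n_freq)))
        data.append((spec, sg.simulate_glm(true, spec, 4, seed=60 + i)))
    return data


class TestLinearL1:
    def test_matches_lasso_oracle(self):
        """The linear-L1 ablation against scikit-learn's Lasso on the same
        design (objective scaled to sklearn's 1/(2n) convention)."""
        from sklearn.linear_model import Lasso
        from strfglm.design import lag_design

        r = np.random.default_rng(70)
        spec = _flat_spec(r.standard_normal((500, 4)))
        k_true = np.zeros((4, 4))
        k_true[1, 2], k_true[2, 0] = 1.5, -1.0
        resp = sg.simulate_linear_rate(k_true, 2.0, spec, noise_sd=0.5,
                                       seed=71)
        eta = 20.0
        cfg = GLMConfig(n_freq=4, n_lags=4, J=0)
        fit = fit_linear_l1([(spec, None)], eta, cfg, responses=[resp])

        X = lag_design(spec.values, 4)
        model = Lasso(alpha=eta / X.shape[0], fit_intercept=True,
                      tol=1e-12, max_iter=100000)
        model.fit(X, resp)
        assert np.max(np.abs(fit.params.k.ravel() - model.coef_)) < 1e-5

    def test_noiseless_identity_recovery(self):
        r = np.random.default_rng(72)
        specs = [_flat_spec(r.standard_normal((400, 4))) for _ in range(3)]
        k_true = 0.8 * r.standard_normal((4, 4))
        resp = [sg.simulate_linear_rate(k_true, 1.0, s) for s in specs]
        fit = fit_linear_l1([(s, None) for s in specs], 0.01,
                            GLMConfig(n_freq=4, n_lags=4, J=0),
                            responses=resp)
        assert sg.similarity_index(k_true, fit.params.k) > 0.999
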