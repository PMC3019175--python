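"""Validation machinery: PSTHs, prediction correlation, leave-one-stimulus-
out cross-validation, STRF similarity, and the generative bias analysis.

Prediction accuracy is the Pearson correlation between predicted and
observed PSTHs, both computed at the model bin width and smoothed with a
5 ms Hanning window.  The similarity index (SI) between two STRFs is their
pixel-by-pixel Pearson correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .glm import (GLMConfig, GLMParams, _smooth_bins, fit_glm,
                  fit_linear_l1)
from .nonlinearity import fit_spline_nl, reconstruct_nl
from .nrc import DEFAULT_TAU_GRID, fit_nrc
from .design import lag_design
from .spectro import Spectrogram
from .spikes import SpikeData

__all__ = ["PSTH", "EvalReport", "psth", "prediction_correlation",
           "similarity_index", "loo_validate", "across_validate",
           "bias_analysis", "bias_direction_pair", "MODEL_TAGS"]

MODEL_TAGS = ("glm", "nrc", "linear_l1", "exp_ln", "spline_glm")


@dataclass
class PSTH:
    """Trial-averaged firing rate (spikes/s) per stimulus bin."""

    rate: np.ndarray
    bin_width_ms: float
    smoothing_window_ms: float = 0.0

    def __post_init__(self) -> None:
        self.rate = np.asarray(self.rate, dtype=float)


@dataclass
class EvalReport:
    """Per-stimulus prediction correlations for one model / class pairing."""

    correlations: list[float]
    model_tag: str
    class_tag: str = "same-class"

    @property
    def mean(self) -> float:
        return float(np.mean(self.correlations))

    @property
    def se(self) -> float:
        c = np.asarray(self.correlations)
        return float(c.std(ddof=1) / np.sqrt(c.size)) if c.size > 1 else 0.0


def _hann(n_bins: int) -> np.ndarray:
    """Unit-sum symmetric Hann taper with nonzero endpoints."""
    w = np.hanning(n_bins + 2)[1:-1]
    return w / w.sum()


def _smooth(series: np.ndarray, n_bins: int) -> np.ndarray:
    """Convolve with a unit-sum Hann window using symmetric edge padding,
    which conserves the total sum exactly."""
    if n_bins <= 1:
        return np.asarray(series, dtype=float)
    return ndimage.convolve1d(np.asarray(series, dtype=float), _hann(n_bins),
                              mode="reflect")


def psth(spikes: SpikeData, smooth_ms: float = 5.0) -> PSTH:
    """Trial-mean rate smoothed with a Hanning window of ``smooth_ms``.

    The continuous-time window is sampled at bin centers; its length rounds
    to the nearest odd bin count >= 3 (so 5 ms at 3 ms bins uses 3 taps).
    """
    if spikes.n_trials < 1:
        raise ValueError("need at least one trial")
    delta = spikes.bin_width_ms / 1000.0
    rate = spikes.counts.mean(axis=0) / delta
    n_bins = _smooth_bins(smooth_ms, spikes.bin_width_ms) if smooth_ms > 0 else 1
    return PSTH(rate=_smooth(rate, n_bins), bin_width_ms=spikes.bin_width_ms,
                smoothing_window_ms=smooth_ms)


def prediction_correlation(predicted, observed) -> float:
    """Pearson correlation between two PSTHs (or raw rate series).

    Returns 0 with a warning when either series is constant (the
    correlation is undefined there).
    """
    p = predicted.rate if isinstance(predicted, PSTH) else np.asarray(predicted, float)
    o = observed.rate if isinstance(observed, PSTH) else np.asarray(observed, float)
    if p.size != o.size:
        raise ValueError("length mismatch between predicted and observed")
    if p.std() == 0 or o.std() == 0:
        warnings.warn("constant series: correlation undefined, returning 0")
        return 0.0
    return float(np.corrcoef(p, o)[0, 1])


def similarity_index(k1: np.ndarray, k2: np.ndarray) -> float:
    """Pixel-by-pixel Pearson correlation between two STRFs."""
    k1 = np.asarray(k1, dtype=float)
    k2 = np.asarray(k2, dtype=float)
    if k1.shape != k2.shape:
        raise ValueError("STRFs must share a shape")
    a = k1.ravel() - k1.mean()
    b = k2.ravel() - k2.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        warnings.warn("constant STRF: similarity undefined, returning 0")
        return 0.0
    return float(a @ b / (na * nb))


# ---------------------------------------------------------------------------
# model registry used by validation and the orchestrator

def _fit_model(model_tag: str, data, cfg: GLMConfig, tau_grid=DEFAULT_TAU_GRID):
    """Fit one of the registered models; returns an object with .k/.b etc.

    With fewer than three stimuli the inner hyperparameter cross-validation
    is impossible; the middle grid value is used with a warning.
    """
    eta: float | str = "auto"
    tau: float | str = "auto"
    if len(data) < 3:
        grid = np.sort(np.asarray(cfg.eta_grid if cfg.eta_grid is not None
                                  else [1.0], dtype=float))
        eta = float(grid[grid.size // 2])
        tau = sorted(tau_grid)[len(tau_grid) // 2]
        warnings.warn("fewer than 3 estimation stimuli: skipping inner "
                      "hyperparameter selection, using grid midpoint")
    if model_tag == "glm":
        return fit_glm(data, eta, cfg)
    if model_tag == "exp_ln":
        from dataclasses import replace
        return fit_glm(data, eta, replace(cfg, J=0))
    if model_tag == "spline_glm":
        fit = fit_glm(data, eta, cfg)
        fit.spline = _fit_prediction_spline(fit.params, data)
        return fit
    if model_tag == "linear_l1":
        return fit_linear_l1(data, eta, cfg)
    if model_tag == "nrc":
        return fit_nrc(data, tau, n_lags=cfg.n_lags, grid=tau_grid,
                       smooth_ms=cfg.smooth_ms)
    raise ValueError(f"unknown model {model_tag!r}")


def _fit_prediction_spline(params: GLMParams, data, n_bins: int = 25):
    """Post-hoc spline nonlinearity on the fitted filter output; the filter
    parameters themselves are left untouched."""
    from .design import history_design
    us, counts = [], []
    for spec, spikes in data:
        sk = params.b + lag_design(spec.values, params.n_lags) @ params.k.ravel()
        for row in spikes.counts:
            u = sk.copy()
            if params.J > 0:
                u = u + history_design(row, params.J) @ params.h
            us.append(u)
            counts.append(row)
    emp = reconstruct_nl(np.concatenate(us), np.concatenate(counts), n_bins)
    return fit_spline_nl(emp)


def _predict_rate(model_tag: str, fit, spec: Spectrogram, cfg: GLMConfig,
                  seed: int) -> np.ndarray:
    """Predicted rate series (spikes/s) for a held-out stimulus."""
    from .simulate import simulate_glm

    if model_tag in ("glm", "exp_ln"):
        sim = simulate_glm(fit.params, spec, cfg.n_sim_trials, seed=seed)
        return sim.counts.mean(axis=0) / (spec.bin_width_ms / 1000.0)
    if model_tag == "spline_glm":
        delta = spec.bin_width_ms / 1000.0
        # the spline maps filter output to per-bin spike probability
        sim = simulate_glm(fit.params, spec, cfg.n_sim_trials, seed=seed,
                           nonlinearity_override=lambda u: fit.spline(u) / delta)
        return sim.counts.mean(axis=0) / delta
    if model_tag == "linear_l1":
        return fit.params.b + lag_design(spec.values, cfg.n_lags) @ fit.params.k.ravel()
    if model_tag == "nrc":
        X = lag_design(spec.values, cfg.n_lags)
        return fit.b + (X - X.mean(axis=0)) @ fit.k.ravel()
    raise ValueError(f"unknown model {model_tag!r}")


def loo_validate(model_tag: str, dataset, cfg: GLMConfig | None = None,
                 class_tag: str = "same-class") -> EvalReport:
    """Leave-one-stimulus-out prediction accuracy.

    For each stimulus, the model is refitted on the remaining stimuli (with
    its inner hyperparameter selection restricted to that estimation set),
    the held-out PSTH is predicted, and the Pearson correlation recorded.
    GLM-family predictions average ``cfg.n_sim_trials`` simulated trials.
    """
    cfg = cfg or GLMConfig()
    if len(dataset) < 2:
        raise ValueError("need at least 2 stimuli for leave-one-out")
    corrs = []
    for held in range(len(dataset)):
        train = [dataset[i] for i in range(len(dataset)) if i != held]
        fit = _fit_model(model_tag, train, cfg)
        spec, spikes = dataset[held]
        pred = _predict_rate(model_tag, fit, spec, cfg,
                             seed=_seed_for(cfg.seed, held))
        n_bins = _smooth_bins(cfg.smooth_ms, spec.bin_width_ms)
        r = prediction_correlation(_smooth(pred, n_bins),
                                   psth(spikes, cfg.smooth_ms))
        corrs.append(r)
    return EvalReport(correlations=corrs, model_tag=model_tag,
                      class_tag=class_tag)


def across_validate(model_tag: str, train_dataset, test_dataset,
                    cfg: GLMConfig | None = None) -> EvalReport:
    """Fit on one stimulus ensemble, predict every stimulus of the other."""
    cfg = cfg or GLMConfig()
    fit = _fit_model(model_tag, train_dataset, cfg)
    corrs = []
    for held, (spec, spikes) in enumerate(test_dataset):
        pred = _predict_rate(model_tag, fit, spec, cfg,
                             seed=_seed_for(cfg.seed, held))
        n_bins = _smooth_bins(cfg.smooth_ms, spec.bin_width_ms)
        corrs.append(prediction_correlation(_smooth(pred, n_bins),
                                            psth(spikes, cfg.smooth_ms)))
    return EvalReport(correlations=corrs, model_tag=model_tag,
                      class_tag="across-class")


def _seed_for(seed: int, held: int) -> int:
    return int(np.random.SeedSequence([seed, 7919, held]).generate_state(1)[0]
               % (2 ** 31))


# ---------------------------------------------------------------------------
# generative bias analysis

def bias_analysis(fit_song, fit_noise, stim_song, stim_noise,
                  method: str = "glm", cfg: GLMConfig | None = None,
                  n_trials: int = 10, noise_sd: float = 0.0,
                  seed: int = 0) -> dict:
    """Second-generation STRFs from generative re-simulation.

    The class-specific fits Ks (song) and Kn (noise) are used as generative
    models to synthesize responses to both stimulus classes; refitting with
    the same method yields four second-generation STRFs: Knn, Kns (generator
    Kn probed with noise / song) and Ksn, Kss (generator Ks probed with
    noise / song).  An unbiased estimator recovers the generator regardless
    of the probe class, so SI(Kn, Kns) and SI(Ks, Ksn) measure the
    stimulus-class bias of the method.

    For ``method="glm"`` the generative model emits spikes through the full
    conditional intensity; for ``method="nrc"`` it is the continuous linear
    rate r = k*x + b (plus optional Gaussian noise).
    """
    from .simulate import simulate_glm, simulate_linear_rate

    cfg = cfg or GLMConfig()

    def _refit(generator, stimuli, seeds):
        if method == "glm":
            gp = generator.params if hasattr(generator, "params") else generator
            data = [(spec, simulate_glm(gp, spec, n_trials, seed=int(s)))
                    for spec, s in zip(stimuli, seeds)]
            return fit_glm(data, "auto", cfg).params.k
        if method == "nrc":
            data_k = generator.k if hasattr(generator, "k") else generator.params.k
            data_b = generator.b if hasattr(generator, "b") else generator.params.b
            resp = [simulate_linear_rate(data_k, data_b, spec,
                                         noise_sd=noise_sd, seed=int(s))
                    for spec, s in zip(stimuli, seeds)]
            return fit_nrc(list(stimuli), "auto", n_lags=cfg.n_lags,
                           responses=resp, smooth_ms=cfg.smooth_ms).k
        raise ValueError(f"unknown method {method!r}")

    stim_song = list(stim_song)
    stim_noise = list(stim_noise)

    def _seeds(tag: int, n: int):
        return np.random.SeedSequence([seed, tag]).generate_state(n) % 2 ** 31

    Knn = _refit(fit_noise, stim_noise, _seeds(0, len(stim_noise)))
    Kns = _refit(fit_noise, stim_song, _seeds(1, len(stim_song)))
    Ksn = _refit(fit_song, stim_noise, _seeds(2, len(stim_noise)))
    Kss = _refit(fit_song, stim_song, _seeds(3, len(stim_song)))

    Kn = fit_noise.params.k if hasattr(fit_noise, "params") else fit_noise.k
    Ks = fit_song.params.k if hasattr(fit_song, "params") else fit_song.k
    return {
        "Knn": Knn, "Kns": Kns, "Ksn": Ksn, "Kss": Kss,
        "si": {
            "Kn_Kns": similarity_index(Kn, Kns),
            "Ks_Ksn": similarity_index(Ks, Ksn),
            "Kn_Knn": similarity_index(Kn, Knn),
            "Ks_Kss": similarity_index(Ks, Kss),
        },
    }


def bias_direction_pair(neuron_params: GLMParams, stim_noise, stim_song,
                        cfg: GLMConfig, n_trials: int = 10,
                        seed: int = 0) -> dict:
    """Paired stimulus-class bias of the two estimators for one neuron.

    First generation: the synthetic neuron responds to the noise ensemble
    and each method fits its own Kn.  Second generation: each method's Kn
    becomes the generative model for responses to the *song* ensemble
    (spiking through the conditional intensity for the GLM; linear rate plus
    Gaussian noise matched to the trial-averaged spiking variability for
    reverse correlation) and the method refits, giving Kns.  An unbiased,
    self-consistent estimator yields SI(Kn, Kns) near 1; the returned dict
    holds that index per method.
    """
    from .simulate import simulate_glm, simulate_linear_rate

    def _seeds(tag: int, n: int):
        return np.random.SeedSequence([seed, tag]).generate_state(n) % 2 ** 31

    stim_noise = list(stim_noise)
    stim_song = list(stim_song)
    delta = stim_noise[0].bin_width_ms / 1000.0

    data_noise = [(s, simulate_glm(neuron_params, s, n_trials, seed=int(sd)))
                  for s, sd in zip(stim_noise, _seeds(0, len(stim_noise)))]

    # first generation
    kn_glm = fit_glm(data_noise, "auto", cfg).params
    kn_nrc = fit_nrc(data_noise, "auto", n_lags=cfg.n_lags,
                     smooth_ms=cfg.smooth_ms)

    # second generation on the song ensemble
    song_data = [(s, simulate_glm(kn_glm, s, n_trials, seed=int(sd)))
                 for s, sd in zip(stim_song, _seeds(1, len(stim_song)))]
    kns_glm = fit_glm(song_data, "auto", cfg).params.k

    # Gaussian noise matched to the sampling noise of an n-trial PSTH at
    # the observed mean rate: sd = sqrt(rate / (n_trials * Delta))
    mean_rate = (sum(d[1].total_spikes for d in data_noise)
                 / (sum(d[1].counts.size for d in data_noise) * delta))
    noise_sd = float(np.sqrt(max(mean_rate, 1e-9) / (n_trials * delta)))
    resp = [simulate_linear_rate(kn_nrc.k, kn_nrc.b, s, noise_sd=noise_sd,
                                 seed=int(sd))
            for s, sd in zip(stim_song, _seeds(2, len(stim_song)))]
    kns_nrc = fit_nrc(stim_song, "auto", n_lags=cfg.n_lags, responses=resp,
                      smooth_ms=cfg.smooth_ms).k

    return {"glm": similarity_index(kn_glm.k, kns_glm),
            "nrc": similarity_index(kn_nrc.k, kns_nrc)}
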