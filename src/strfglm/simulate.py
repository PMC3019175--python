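"""Synthetic neurons and stimulus ensembles.

This module is both the prediction engine (simulated rasters from a fitted
model) and the synthetic-data generator that emulates the structure of the
source recordings: ~2 s stimuli in two classes (a temporally sparse,
strongly autocorrelated "songlike" class and a modulation-limited,
near-Gaussian "noiselike" class), neurons with 20x20 STRFs, 5-bin post-spike
filters, and firing rates in the 10-20 Hz range.

Spikes are emitted sequentially per bin with probability
p_t = 1 - exp(-lambda_t * Delta), where lambda_t comes from the conditional
intensity driven by the trial's own emitted history.  At 3 ms bins this
Bernoulli emission matches the observation that multi-spike bins are
negligible; a Poisson mode exists behind a flag.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .design import lag_design
from .glm import _CLIP, GLMParams
from .nonlinearity import eval_nl
from .spectro import Spectrogram, default_freq_centers
from .spikes import SpikeData

__all__ = [
    "SyntheticNeuron", "StimulusEnsemble", "NoiselikeConfig", "SonglikeConfig",
    "simulate_glm", "simulate_linear_rate", "make_noiselike", "make_songlike",
    "make_white_noise",
    "make_ensemble", "gabor_strf", "onset_strf", "broadband_inhibition_strf",
    "default_history_filter", "make_neuron", "calibrate_offset",
]


@dataclass
class SyntheticNeuron:
    """Ground-truth generative neuron."""

    params: GLMParams
    description: str = ""


@dataclass
class StimulusEnsemble:
    """A list of spectrograms sharing one bin grid and frequency axis."""

    spectrograms: list[Spectrogram]
    class_tag: str = "noiselike"   # songlike | noiselike | white
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_tag not in ("songlike", "noiselike", "white"):
            raise ValueError("class_tag must be songlike, noiselike or white")
        grids = {(s.bin_width_ms, s.n_freq) for s in self.spectrograms}
        if len(grids) > 1:
            raise ValueError("ensemble members must share one bin grid")

    def __iter__(self):
        return iter(self.spectrograms)

    def __len__(self) -> int:
        return len(self.spectrograms)


# ---------------------------------------------------------------------------
# spike generation

def simulate_glm(params: GLMParams, spec: Spectrogram, n_trials: int,
                 seed: int = 0, mode: str = "bernoulli",
                 nonlinearity_override=None) -> SpikeData:
    """Emit spike trains from the model, trial histories evolving freely.

    Per bin, p_t = 1 - exp(-lambda_t * Delta) and a Bernoulli draw is made
    (``mode="poisson"`` draws Poisson counts with mean lambda_t * Delta
    instead).  Trials are independent; the draw sequence is fixed by the
    seed.  ``nonlinearity_override`` may supply a callable (e.g. a fitted
    spline) to replace the tagged closed-form nonlinearity at prediction
    time.
    """
    rng = np.random.default_rng(seed)
    delta = spec.bin_width_ms / 1000.0
    T = spec.n_time
    J = params.J
    sk = params.b + lag_design(spec.values, params.n_lags) @ params.k.ravel()
    if np.any(sk > _CLIP):
        warnings.warn("linear predictor exceeds overflow clip during "
                      "simulation; rates clipped")
    if nonlinearity_override is not None:
        f = nonlinearity_override
    else:
        def f(u):
            return eval_nl(params.nonlinearity, u)
    counts = np.zeros((n_trials, T), dtype=np.int64)
    for t in range(T):
        u = np.full(n_trials, sk[t])
        for j in range(1, min(J, t) + 1):
            u += params.h[j - 1] * counts[:, t - j]
        lam = f(np.minimum(u, _CLIP))
        if mode == "bernoulli":
            p = 1.0 - np.exp(-lam * delta)
            counts[:, t] = rng.random(n_trials) < p
        elif mode == "poisson":
            counts[:, t] = rng.poisson(lam * delta)
        else:
            raise ValueError(f"unknown emission mode {mode!r}")
    return SpikeData(counts=counts, bin_width_ms=spec.bin_width_ms,
                     stimulus_id=spec.stimulus_id)


def simulate_linear_rate(k: np.ndarray, b: float, spec: Spectrogram,
                         noise_sd: float = 0.0, seed: int = 0) -> np.ndarray:
    """Continuous linear response r(t) = (k*x)(t) + b + Gaussian noise.

    This is the generative model used for reverse-correlation bias analyses;
    it produces a rate series, not spikes.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    k = np.asarray(k, dtype=float)
    r = b + lag_design(spec.values, k.shape[1]) @ k.ravel()
    if noise_sd > 0:
        r = r + np.random.default_rng(seed).normal(0.0, noise_sd, r.size)
    return r


# ---------------------------------------------------------------------------
# stimulus ensembles

@dataclass
class NoiselikeConfig:
    """Modulation-limited noise: Gaussian in the log-spectrogram domain,
    low-passed to stated temporal / spectral modulation bounds."""

    n_freq: int = 20
    bin_width_ms: float = 3.0
    fmin_hz: float = 250.0
    fmax_hz: float = 8000.0
    max_temporal_mod_hz: float = 50.0
    max_spectral_mod_cyc_per_khz: float = 2.0
    target_sd: float = 1.0
    mean_level: float = 0.0


@dataclass
class SonglikeConfig:
    """Syllable-based stimuli: harmonic stacks and sweeps separated by
    silent gaps, rendered straight into the log-spectrogram grid."""

    n_freq: int = 20
    bin_width_ms: float = 3.0
    fmin_hz: float = 250.0
    fmax_hz: float = 8000.0
    syllable_rate_hz: float = 6.0
    syllable_dur_ms: tuple[float, float] = (80.0, 200.0)
    n_harmonics: int = 4
    floor_level: float = -2.0
    peak_level: float = 3.0
    background_sd: float = 0.25   # low-level texture over the silent floor


def make_noiselike(duration_s: float, cfg: NoiselikeConfig | None = None,
                   seed: int = 0, stimulus_id: str = "") -> Spectrogram:
    """Synthesize a stationary noiselike log-spectrogram.

    2-D Gaussian noise is low-pass filtered in the modulation domain to the
    configured temporal and spectral modulation bounds, then scaled to the
    target variance.  Band-energy statistics are near-Gaussian (elliptic),
    the property that makes reverse correlation unbiased on this class.
    """
    cfg = cfg or NoiselikeConfig()
    rng = np.random.default_rng(seed)
    T = int(math.ceil(duration_s * 1000.0 / cfg.bin_width_ms - 1e-9))
    noise = rng.standard_normal((T, cfg.n_freq))
    spec_f = np.fft.fft2(noise)
    ft = np.fft.fftfreq(T, d=cfg.bin_width_ms / 1000.0)        # Hz
    khz_span = (cfg.fmax_hz - cfg.fmin_hz) / 1000.0
    fs = np.fft.fftfreq(cfg.n_freq, d=khz_span / cfg.n_freq)   # cyc/kHz
    mask = ((np.abs(ft)[:, None] <= cfg.max_temporal_mod_hz)
            & (np.abs(fs)[None, :] <= cfg.max_spectral_mod_cyc_per_khz))
    vals = np.real(np.fft.ifft2(spec_f * mask))
    sd = vals.std()
    if sd > 0:
        vals = vals / sd * cfg.target_sd
    vals = vals + cfg.mean_level
    return Spectrogram(values=vals, bin_width_ms=cfg.bin_width_ms,
                       freq_centers_hz=default_freq_centers(
                           cfg.n_freq, cfg.fmin_hz, cfg.fmax_hz),
                       is_log=True, stimulus_id=stimulus_id)


def make_white_noise(duration_s: float, cfg: NoiselikeConfig | None = None,
                     seed: int = 0, stimulus_id: str = "") -> Spectrogram:
    """Flat-spectrum (white) log-spectrogram noise: i.i.d. Gaussian cells.

    The fully elliptic, uncorrelated probe used for parameter-recovery and
    estimator-agreement checks; equivalent to ``make_noiselike`` with both
    modulation cutoffs at or above Nyquist.
    """
    cfg = cfg or NoiselikeConfig()
    nyq_t = 500.0 / cfg.bin_width_ms
    nyq_s = cfg.n_freq / (2.0 * (cfg.fmax_hz - cfg.fmin_hz) / 1000.0)
    from dataclasses import replace as _dc_replace
    cfg = _dc_replace(cfg, max_temporal_mod_hz=nyq_t,
                      max_spectral_mod_cyc_per_khz=nyq_s)
    return make_noiselike(duration_s, cfg, seed=seed, stimulus_id=stimulus_id)


def make_songlike(duration_s: float, cfg: SonglikeConfig | None = None,
                  seed: int = 0, stimulus_id: str = "") -> Spectrogram:
    """Synthesize a songlike log-spectrogram: a sparse sequence of syllables
    (harmonic stacks, some frequency-swept) over a silent floor.

    The result is temporally sparse, strongly autocorrelated within
    syllables, and has heavy-tailed (non-elliptic) band-energy statistics --
    the higher-order structure that biases subspace-truncated reverse
    correlation.
    """
    cfg = cfg or SonglikeConfig()
    rng = np.random.default_rng(seed)
    T = int(math.ceil(duration_s * 1000.0 / cfg.bin_width_ms - 1e-9))
    centers = default_freq_centers(cfg.n_freq, cfg.fmin_hz, cfg.fmax_hz)
    vals = np.full((T, cfg.n_freq), cfg.floor_level)
    if cfg.background_sd > 0:
        vals = vals + rng.normal(0.0, cfg.background_sd, vals.shape)

    n_syll = rng.poisson(cfg.syllable_rate_hz * duration_s)
    bin_s = cfg.bin_width_ms / 1000.0
    for _ in range(n_syll):
        t0 = int(rng.integers(0, max(T - 1, 1)))
        dur = rng.uniform(*cfg.syllable_dur_ms) / 1000.0
        n_bins = max(2, int(round(dur / bin_s)))
        t1 = min(T, t0 + n_bins)
        f0 = rng.uniform(cfg.fmin_hz + 200.0, cfg.fmax_hz / cfg.n_harmonics)
        sweep = rng.uniform(-1.5, 1.5) * f0 / dur  # Hz/s
        tt = (np.arange(t0, t1) - t0) * bin_s
        env = np.sin(np.pi * np.linspace(0.05, 0.95, t1 - t0)) ** 0.5
        # within-syllable amplitude modulation
        env = env * (1.0 + 0.3 * np.sin(2 * np.pi * rng.uniform(2, 8) * tt
                                        + rng.uniform(0, 2 * np.pi)))
        rows = np.arange(t0, t1)
        for harm in range(1, cfg.n_harmonics + 1):
            fh = harm * (f0 + sweep * tt)
            fidx = np.clip(np.searchsorted(centers, fh), 0, cfg.n_freq - 1)
            amp = cfg.peak_level * env / harm ** 0.5
            np.maximum.at(vals, (rows, fidx), cfg.floor_level + amp)
            # spectral spread around the harmonic line
            for off, gain in ((-2, 0.35), (-1, 0.7), (1, 0.7), (2, 0.35)):
                fo = np.clip(fidx + off, 0, cfg.n_freq - 1)
                np.maximum.at(vals, (rows, fo),
                              cfg.floor_level + gain * amp)
    return Spectrogram(values=vals, bin_width_ms=cfg.bin_width_ms,
                       freq_centers_hz=centers, is_log=True,
                       stimulus_id=stimulus_id)


def make_ensemble(class_tag: str, n_stimuli: int, duration_s: float = 2.0,
                  cfg=None, seed: int = 0) -> StimulusEnsemble:
    """Generate an ensemble of songlike or noiselike stimuli."""
    maker = {"songlike": make_songlike, "noiselike": make_noiselike,
             "white": make_white_noise}[class_tag]
    seeds = np.random.SeedSequence(seed).generate_state(n_stimuli) % (2 ** 31)
    specs = [maker(duration_s, cfg, seed=int(s),
                   stimulus_id=f"{class_tag}_{i:03d}")
             for i, s in enumerate(seeds)]
    return StimulusEnsemble(spectrograms=specs, class_tag=class_tag, seed=seed)


# ---------------------------------------------------------------------------
# ground-truth STRF library

def gabor_strf(n_freq: int = 20, n_lags: int = 20, center_freq: float = 0.5,
               center_lag: float = 0.25, freq_sigma: float = 0.12,
               lag_sigma: float = 0.12, orientation: float = 0.0,
               phase: float = 0.0, freq_period: float = 0.5,
               amplitude: float = 1.0) -> np.ndarray:
    """Gabor-like STRF patch: an oriented grating under a 2-D Gaussian
    envelope.  Positions and widths are fractions of the axis lengths."""
    f = (np.arange(n_freq)[:, None] + 0.5) / n_freq - center_freq
    l = (np.arange(n_lags)[None, :] + 0.5) / n_lags - center_lag
    envelope = np.exp(-0.5 * (f / freq_sigma) ** 2
                      - 0.5 * (l / lag_sigma) ** 2)
    angle = f * math.cos(orientation) + l * math.sin(orientation)
    return amplitude * envelope * np.cos(2 * np.pi * angle / freq_period
                                         + phase)


def onset_strf(n_freq: int = 20, n_lags: int = 20, center_freq: float = 0.5,
               freq_sigma: float = 0.15, peak_lag: float = 0.15,
               trough_lag: float = 0.4, amplitude: float = 1.0) -> np.ndarray:
    """Biphasic onset kernel: excitation at short latency followed by
    delayed suppression, gaussian in frequency."""
    f = (np.arange(n_freq)[:, None] + 0.5) / n_freq - center_freq
    l = (np.arange(n_lags)[None, :] + 0.5) / n_lags
    fenv = np.exp(-0.5 * (f / freq_sigma) ** 2)
    temporal = (np.exp(-0.5 * ((l - peak_lag) / 0.08) ** 2)
                - 0.7 * np.exp(-0.5 * ((l - trough_lag) / 0.12) ** 2))
    return amplitude * fenv * temporal


def broadband_inhibition_strf(n_freq: int = 20, n_lags: int = 20,
                              center_freq: float = 0.5,
                              amplitude: float = 1.0) -> np.ndarray:
    """Narrow excitation flanked by broad spectral inhibition (the broader
    tuning / stronger inhibition archetype)."""
    f = (np.arange(n_freq)[:, None] + 0.5) / n_freq - center_freq
    l = (np.arange(n_lags)[None, :] + 0.5) / n_lags
    tenv = np.exp(-0.5 * ((l - 0.2) / 0.1) ** 2)
    excite = np.exp(-0.5 * (f / 0.08) ** 2)
    inhibit = 0.6 * np.exp(-0.5 * (f / 0.35) ** 2)
    return amplitude * tenv * (excite - inhibit)


def default_history_filter() -> np.ndarray:
    """Refractory-then-recovery post-spike filter (log-rate gain per bin)."""
    return np.array([-5.0, -2.0, -1.0, -0.3, 0.2])


def calibrate_offset(k: np.ndarray, h: np.ndarray, stimuli, target_rate_hz: float,
                     bin_width_ms: float = 3.0, nonlinearity: str = "exp",
                     n_trials: int = 4, seed: int = 0,
                     n_rounds: int = 4) -> float:
    """Choose the offset b so the simulated mean rate is near the target.

    Deterministic fixed-point iteration: simulate a few trials on a subset of
    stimuli, then shift b by log(target / achieved).
    """
    b = math.log(target_rate_hz)
    subset = list(stimuli)[:4]
    total_s = sum(s.duration_s for s in subset) * n_trials
    for it in range(n_rounds):
        params = GLMParams(k=k, h=h, b=b, nonlinearity=nonlinearity,
                           bin_width_ms=bin_width_ms)
        n_spk = sum(simulate_glm(params, s, n_trials,
                                 seed=seed + 977 * it).total_spikes
                    for s in subset)
        rate = max(n_spk / total_s, 0.1)
        b += math.log(target_rate_hz / rate)
    return b


def make_neuron(kind: str, stimuli, target_rate_hz: float = 15.0,
                drive_sd: float = 1.0, n_freq: int = 20, n_lags: int = 20,
                seed: int = 0, with_history: bool = True) -> SyntheticNeuron:
    """Build a ground-truth neuron of the given archetype, with the STRF
    scaled so its linear drive has standard deviation ``drive_sd`` over the
    supplied stimuli, and the offset calibrated to the target firing rate."""
    rng = np.random.default_rng(seed)
    if kind == "gabor":
        k = gabor_strf(n_freq, n_lags,
                       center_freq=rng.uniform(0.25, 0.75),
                       center_lag=rng.uniform(0.15, 0.4),
                       orientation=rng.uniform(0, np.pi),
                       phase=rng.uniform(0, 2 * np.pi))
    elif kind == "onset":
        k = onset_strf(n_freq, n_lags, center_freq=rng.uniform(0.25, 0.75))
    elif kind == "broadband":
        k = broadband_inhibition_strf(n_freq, n_lags,
                                      center_freq=rng.uniform(0.3, 0.7))
    else:
        raise ValueError(f"unknown neuron kind {kind!r}")

    drives = np.concatenate([lag_design(s.values - s.values.mean(), n_lags)
                             @ k.ravel() for s in list(stimuli)[:4]])
    sd = drives.std()
    if sd > 0:
        k = k * (drive_sd / sd)
    h = default_history_filter() if with_history else np.zeros(0)
    bw = list(stimuli)[0].bin_width_ms
    b = calibrate_offset(k, h, stimuli, target_rate_hz, bin_width_ms=bw,
                         seed=seed)
    params = GLMParams(k=k, h=h, b=b, nonlinearity="exp", bin_width_ms=bw)
    return SyntheticNeuron(params=params, description=f"{kind} seed={seed}")
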