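"""Stimulus spectrograms: filterbank analysis, log compression, rebinning.

Sound-pressure waveforms are converted to time-frequency energy matrices by
short-time spectral analysis aggregated into linearly spaced 125 Hz channels
spanning 250-8000 Hz (the audible range of the songbird species the package
targets).  A compressive logarithm mimicking peripheral auditory processing is
applied before model fitting, and the fine grid (1 ms x 63 channels) is
rebinned to the model grid (typically 3 ms x 20 channels).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "Spectrogram",
    "FilterbankConfig",
    "compute_spectrogram",
    "log_compress",
    "rebin",
    "default_freq_centers",
]


@dataclass
class FilterbankConfig:
    """Short-time filterbank settings.

    Channels are linearly spaced between ``fmin`` and ``fmax`` with
    ``bandwidth_hz`` spacing; the analysis window is chosen to give a
    frequency resolution of about one channel bandwidth.
    """

    fmin_hz: float = 250.0
    fmax_hz: float = 8000.0
    bandwidth_hz: float = 125.0
    bin_width_ms: float = 1.0
    window_ms: float = 8.0
    mode: str = "power"  # "power" or "amplitude"

    @property
    def n_channels(self) -> int:
        return int(math.floor((self.fmax_hz - self.fmin_hz) / self.bandwidth_hz)) + 1

    @property
    def freq_centers_hz(self) -> np.ndarray:
        return self.fmin_hz + self.bandwidth_hz * np.arange(self.n_channels)


@dataclass
class Spectrogram:
    """Time-frequency stimulus energy matrix with bin metadata.

    ``values`` has shape [time_bins, freq_bins].  Before ``log_compress`` the
    entries are nonnegative energies; afterwards they are natural-log energies
    and ``is_log`` is set.
    """

    values: np.ndarray
    bin_width_ms: float
    freq_centers_hz: np.ndarray
    is_log: bool = False
    stimulus_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.freq_centers_hz = np.asarray(self.freq_centers_hz, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D [time_bins, freq_bins]")
        if self.values.shape[1] != self.freq_centers_hz.size:
            raise ValueError("freq_centers_hz length must match freq_bins")
        if np.any(np.diff(self.freq_centers_hz) <= 0):
            raise ValueError("freq_centers_hz must be strictly ascending")
        if np.isnan(self.values).any():
            raise ValueError("values contain NaN")
        if self.bin_width_ms <= 0:
            raise ValueError("bin_width_ms must be positive")

    @property
    def n_time(self) -> int:
        return self.values.shape[0]

    @property
    def n_freq(self) -> int:
        return self.values.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_time * self.bin_width_ms / 1000.0


def default_freq_centers(n_freq: int = 20, fmin_hz: float = 250.0,
                         fmax_hz: float = 8000.0) -> np.ndarray:
    """Centers of ``n_freq`` equal-width bands covering [fmin, fmax]."""
    edges = np.linspace(fmin_hz, fmax_hz, n_freq + 1)
    return 0.5 * (edges[:-1] + edges[1:])


def compute_spectrogram(waveform: np.ndarray, fs: float,
                        cfg: FilterbankConfig | None = None,
                        stimulus_id: str = "") -> Spectrogram:
    """Short-time filterbank energy of a mono waveform.

    A Hann-windowed FFT is taken every ``cfg.bin_width_ms`` and magnitudes
    (squared, for the default power mode) are summed into contiguous
    ``cfg.bandwidth_hz``-wide channels centered on the filterbank grid.  The
    number of time bins is ``ceil(duration / bin_width)``.
    """
    cfg = cfg or FilterbankConfig()
    waveform = np.asarray(waveform, dtype=float)
    if waveform.ndim != 1:
        raise ValueError("waveform must be mono (1-D)")
    if waveform.size == 0:
        raise ValueError("empty input")
    if not np.all(np.isfinite(waveform)):
        raise ValueError("waveform must be finite")
    if fs < 2.0 * cfg.fmax_hz:
        raise ValueError(f"nyquist: fs={fs} below 2*fmax={2 * cfg.fmax_hz}")

    hop = max(1, int(round(fs * cfg.bin_width_ms / 1000.0)))
    nwin = max(2, int(round(fs * cfg.window_ms / 1000.0)))
    n_time = int(math.ceil(waveform.size / hop))

    # Zero-pad so each frame is centered on its bin start; frames beyond the
    # signal end see zeros.
    half = nwin // 2
    padded = np.concatenate([np.zeros(half), waveform,
                             np.zeros(nwin + hop * n_time - waveform.size)])
    window = np.hanning(nwin)
    frames = np.lib.stride_tricks.sliding_window_view(padded, nwin)[::hop][:n_time]
    spec = np.abs(np.fft.rfft(frames * window, axis=1))
    if cfg.mode == "power":
        spec = spec ** 2
    elif cfg.mode != "amplitude":
        raise ValueError(f"unknown mode {cfg.mode!r}")

    fft_freqs = np.fft.rfftfreq(nwin, d=1.0 / fs)
    centers = cfg.freq_centers_hz
    # Assign each FFT bin to the channel whose band [c - bw/2, c + bw/2)
    # contains it; bins outside all bands are dropped.
    idx = np.floor((fft_freqs - (centers[0] - cfg.bandwidth_hz / 2.0))
                   / cfg.bandwidth_hz).astype(int)
    valid = (idx >= 0) & (idx < centers.size)
    values = np.zeros((n_time, centers.size))
    np.add.at(values.T, idx[valid], spec[:, valid].T)

    return Spectrogram(values=values, bin_width_ms=cfg.bin_width_ms,
                       freq_centers_hz=centers, is_log=False,
                       stimulus_id=stimulus_id)


def log_compress(spec: Spectrogram, floor_db: float = -80.0) -> Spectrogram:
    """Natural-log compression with a dynamic-range floor.

    The floor is ``floor_db`` decibels below the maximum energy in the
    spectrogram, so silence maps to a finite constant.
    """
    if spec.is_log:
        raise ValueError("spectrogram already log-compressed")
    if floor_db >= 0:
        raise ValueError("floor too high")
    peak = float(spec.values.max())
    if peak <= 0:
        # All-silent stimulus: no reference level; use an arbitrary unit
        # reference so output is the constant floor.
        peak = 1.0
    floor = peak * 10.0 ** (floor_db / 10.0)
    values = np.log(np.maximum(spec.values, floor))
    return replace(spec, values=values, is_log=True)


def rebin(spec: Spectrogram, n_freq: int | None = None,
          time_factor: int = 1) -> Spectrogram:
    """Average frequency channels into ``n_freq`` contiguous groups and time
    bins into non-overlapping windows of ``time_factor``.

    Frequency groups differ in size by at most one channel when the channel
    count does not divide evenly.  A trailing partial time window is dropped.
    """
    if time_factor < 1:
        raise ValueError("time_factor must be >= 1")
    n_freq = spec.n_freq if n_freq is None else int(n_freq)
    if n_freq > spec.n_freq or n_freq < 1:
        raise ValueError("n_freq must be in [1, channel count]")

    values = spec.values
    n_keep = (values.shape[0] // time_factor) * time_factor
    if time_factor > 1:
        values = values[:n_keep].reshape(-1, time_factor, values.shape[1]).mean(axis=1)

    groups = np.array_split(np.arange(spec.n_freq), n_freq)
    new_vals = np.column_stack([values[:, g].mean(axis=1) for g in groups])
    new_centers = np.array([spec.freq_centers_hz[g].mean() for g in groups])

    return Spectrogram(values=new_vals,
                       bin_width_ms=spec.bin_width_ms * time_factor,
                       freq_centers_hz=new_centers, is_log=spec.is_log,
                       stimulus_id=spec.stimulus_id)
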