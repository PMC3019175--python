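"""On-disk formats: WAV audio, spike-time text files, stimulus manifests,
and matrix artifacts in both a delimited-text dialect and HDF5.

Text matrices carry a 3-line ``#`` header (shape, bin width, frequency range)
so spectrograms and STRFs survive a round trip at full stored precision.
"""

from __future__ import annotations

import os
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.io import wavfile

from .spectro import Spectrogram
from .spikes import SpikeData

__all__ = [
    "read_wav", "read_spike_times", "read_manifest",
    "write_matrix_text", "read_matrix_text",
    "write_spectrogram_h5", "read_spectrogram_h5",
    "write_spikes_h5", "read_spikes_h5",
]

_PCM_SCALE = {np.dtype(np.int16): 2 ** 15, np.dtype(np.int32): 2 ** 31,
              np.dtype(np.uint8): 2 ** 7}


def read_wav(path: str | os.PathLike) -> tuple[np.ndarray, float]:
    """Read a mono WAV file, returning (waveform in [-1, 1], fs in Hz).

    PCM integer formats are scaled to float; multichannel files are rejected.
    """
    fs, data = wavfile.read(os.fspath(path))
    if data.ndim != 1:
        raise ValueError(f"{path}: multichannel audio not supported")
    if data.dtype in _PCM_SCALE:
        scale = _PCM_SCALE[data.dtype]
        if data.dtype == np.uint8:
            data = data.astype(float) - 128.0
        data = np.asarray(data, dtype=float) / scale
    else:
        data = np.asarray(data, dtype=float)
    return data, float(fs)


def read_spike_times(path: str | os.PathLike) -> list[np.ndarray]:
    """Read a plain-text spike file: one trial per line, whitespace-separated
    spike times in seconds; ``#`` lines are comments.  Blank lines encode
    zero-spike trials."""
    trials = []
    with open(path) as fh:
        for line in fh:
            stripped = line.strip()
            if stripped.startswith("#"):
                continue
            trials.append(np.array([float(tok) for tok in stripped.split()]))
    return trials


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    """Read the stimulus manifest CSV mapping stimulus_id -> audio file ->
    spike file.  Relative paths are resolved against the manifest's folder."""
    df = pd.read_csv(path)
    required = {"stimulus_id", "audio_file", "spike_file"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    base = Path(path).parent
    for col in ("audio_file", "spike_file"):
        df[col] = [str(base / p) if not os.path.isabs(p) else p for p in df[col]]
    return df


# -- delimited-text matrices -------------------------------------------------

def write_matrix_text(path: str | os.PathLike, values: np.ndarray,
                      bin_width_ms: float = 0.0,
                      freq_range_hz: tuple[float, float] = (0.0, 0.0)) -> None:
    values = np.atleast_2d(np.asarray(values, dtype=float))
    header = (f"shape {values.shape[0]} {values.shape[1]}\n"
              f"bin_width_ms {bin_width_ms!r}\n"
              f"freq_range_hz {freq_range_hz[0]!r} {freq_range_hz[1]!r}")
    np.savetxt(os.fspath(path), values, header=header, fmt="%.17g")


def read_matrix_text(path: str | os.PathLike):
    """Return (values, bin_width_ms, (fmin, fmax)) from the text dialect."""
    with open(path) as fh:
        lines = [fh.readline() for _ in range(3)]
    shape = tuple(int(x) for x in lines[0].split()[2:4])
    bin_width_ms = float(lines[1].split()[2])
    freq_range = (float(lines[2].split()[2]), float(lines[2].split()[3]))
    values = np.loadtxt(os.fspath(path)).reshape(shape)
    return values, bin_width_ms, freq_range


# -- HDF5 containers ---------------------------------------------------------

def write_spectrogram_h5(path: str | os.PathLike, spec: Spectrogram) -> None:
    with h5py.File(os.fspath(path), "w") as f:
        g = f.create_group("spectrogram")
        g.create_dataset("values", data=spec.values)
        g.create_dataset("freq_centers_hz", data=spec.freq_centers_hz)
        g.attrs["bin_width_ms"] = spec.bin_width_ms
        g.attrs["is_log"] = spec.is_log
        g.attrs["stimulus_id"] = spec.stimulus_id


def read_spectrogram_h5(path: str | os.PathLike) -> Spectrogram:
    with h5py.File(os.fspath(path), "r") as f:
        g = f["spectrogram"]
        return Spectrogram(values=g["values"][()],
                           freq_centers_hz=g["freq_centers_hz"][()],
                           bin_width_ms=float(g.attrs["bin_width_ms"]),
                           is_log=bool(g.attrs["is_log"]),
                           stimulus_id=str(g.attrs["stimulus_id"]))


def write_spikes_h5(path: str | os.PathLike, spikes: SpikeData) -> None:
    with h5py.File(os.fspath(path), "w") as f:
        g = f.create_group("spikes")
        g.create_dataset("counts", data=spikes.counts)
        g.attrs["bin_width_ms"] = spikes.bin_width_ms
        g.attrs["stimulus_id"] = spikes.stimulus_id


def read_spikes_h5(path: str | os.PathLike) -> SpikeData:
    with h5py.File(os.fspath(path), "r") as f:
        g = f["spikes"]
        return SpikeData(counts=g["counts"][()],
                         bin_width_ms=float(g.attrs["bin_width_ms"]),
                         stimulus_id=str(g.attrs["stimulus_id"]))
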