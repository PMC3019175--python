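"""Lag embedding of spectrograms into regression design matrices.

Column order is frequency-major, lag-minor: column f * n_lags + l holds
x[t - l, f].  The stimulus is zero-padded before onset, so lags reaching
before t = 0 contribute nothing.  This order matches ``GLMParams.k.ravel()``
for a [n_freq, n_lags] STRF matrix.
"""

from __future__ import annotations

import numpy as np

__all__ = ["lag_design", "history_design"]


def lag_design(values: np.ndarray, n_lags: int) -> np.ndarray:
    """Embed a [T, n_freq] spectrogram into a [T, n_freq * n_lags] matrix."""
    values = np.asarray(values, dtype=float)
    T, n_freq = values.shape
    X = np.zeros((T, n_freq * n_lags))
    for lag in range(n_lags):
        # rows t >= lag see x[t - lag, :]
        X[lag:, lag::n_lags] = values[:T - lag, :]
    return X


def history_design(counts_row: np.ndarray, J: int) -> np.ndarray:
    """Embed one trial's spike counts into a [T, J] history matrix.

    Column j-1 holds r(t - j); history before stimulus onset is zero and
    never crosses trial boundaries.
    """
    counts_row = np.asarray(counts_row, dtype=float)
    T = counts_row.size
    H = np.zeros((T, J))
    for j in range(1, J + 1):
        H[j:, j - 1] = counts_row[:T - j]
    return H
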