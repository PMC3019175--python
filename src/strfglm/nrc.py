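"""Normalized reverse correlation (NRC).

The least-squares STRF is k = C_XX^{-1} (X^T r / D), with C_XX = X^T X / D
the stimulus autocorrelation.  For naturalistic stimuli C_XX is badly
conditioned, so its inverse is approximated by eigendecomposition truncated
to the leading dimensions that carry a fraction tau of the stimulus
variance: C^{-1}_app = U diag(1/lambda_1 .. 1/lambda_m, 0, ...) U^T.  The
tolerance tau is picked by leave-one-stimulus-out cross-validation of the
linear prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import lag_design
from .spectro import Spectrogram
from .spikes import SpikeData

__all__ = ["DesignMatrix", "Eigensystem", "NRCFit", "build_design",
           "covariance_eigensystem", "nrc_filter", "select_tau",
           "DEFAULT_TAU_GRID", "fit_nrc"]

DEFAULT_TAU_GRID = (0.5, 0.6, 0.7, 0.8, 0.9, 0.95, 0.99, 1.0)


@dataclass
class DesignMatrix:
    """Lag-embedded, column-centered stimulus matrix.

    Column order is frequency-major, lag-minor (column f * n_lags + l holds
    x[t - l, f]); stimuli are concatenated along rows and the per-column
    mean (stored in ``col_means``) is subtracted.
    """

    X: np.ndarray
    col_means: np.ndarray
    n_freq: int
    n_lags: int
    row_slices: list[slice] = field(default_factory=list)

    @property
    def D(self) -> int:
        return self.X.shape[0]


@dataclass
class Eigensystem:
    """Eigenvectors (columns of U) and descending eigenvalues of C_XX."""

    U: np.ndarray
    lambdas: np.ndarray


@dataclass
class NRCFit:
    k: np.ndarray                 # STRF, [n_freq, n_lags]
    tau: float
    m: int                        # retained eigen-dimensions
    b: float = 0.0                # mean-rate offset used for prediction
    cv_table: list[tuple[float, float]] = field(default_factory=list)
    eig: Eigensystem | None = None


def build_design(specs: list[Spectrogram], n_lags: int) -> DesignMatrix:
    """Stack lag-embedded spectrograms and center columns."""
    if not specs:
        raise ValueError("no spectrograms")
    grids = {(round(s.bin_width_ms, 9), s.n_freq) for s in specs}
    if len(grids) > 1:
        raise ValueError("mixed bin grids across spectrograms")
    blocks = [lag_design(s.values, n_lags) for s in specs]
    X = np.vstack(blocks)
    col_means = X.mean(axis=0)
    X = X - col_means
    slices, start = [], 0
    for blk in blocks:
        slices.append(slice(start, start + blk.shape[0]))
        start += blk.shape[0]
    return DesignMatrix(X=X, col_means=col_means, n_freq=specs[0].n_freq,
                        n_lags=n_lags, row_slices=slices)


def covariance_eigensystem(design: DesignMatrix | np.ndarray) -> Eigensystem:
    """Eigendecomposition of C_XX = X^T X / D, eigenvalues descending.

    Tiny negative eigenvalues from roundoff are clipped at zero and never
    inverted.
    """
    X = design.X if isinstance(design, DesignMatrix) else np.asarray(design)
    D = X.shape[0]
    C = X.T @ X / D
    lambdas, U = np.linalg.eigh(C)
    order = np.argsort(lambdas)[::-1]
    lambdas = np.maximum(lambdas[order], 0.0)
    return Eigensystem(U=U[:, order], lambdas=lambdas)


def _retained_dims(lambdas: np.ndarray, tau: float) -> int:
    """Largest m with cumulative variance fraction <= tau (minimum 1)."""
    total = lambdas.sum()
    if total <= 0:
        return 1
    frac = np.cumsum(lambdas) / total
    m = int(np.searchsorted(frac, tau + 1e-12, side="right"))
    return max(m, 1)


def nrc_filter(design: DesignMatrix, r: np.ndarray, tau: float,
               eig: Eigensystem | None = None) -> NRCFit:
    """Tolerance-truncated pseudoinverse estimate of the STRF.

    ``r`` is the mean response series aligned with the design rows; it is
    centered by its mean internally, and that mean becomes the prediction
    offset.
    """
    if tau <= 0 or tau > 1:
        raise ValueError("tau must lie in (0, 1]")
    r = np.asarray(r, dtype=float)
    if r.size != design.D:
        raise ValueError("response not aligned with design rows")
    if eig is None:
        eig = covariance_eigensystem(design)
    rbar = float(r.mean())
    sta = design.X.T @ (r - rbar) / design.D
    m = _retained_dims(eig.lambdas, tau)
    # guard exactly-zero eigenvalues inside the retained block
    lam = eig.lambdas[:m]
    nz = lam > max(lam[0], 1e-300) * 1e-12
    Um = eig.U[:, :m][:, nz]
    k_vec = Um @ ((Um.T @ sta) / lam[nz])
    k = k_vec.reshape(design.n_freq, design.n_lags)
    return NRCFit(k=k, tau=float(tau), m=m, b=rbar, eig=eig)


def select_tau(specs: list[Spectrogram], responses: list[np.ndarray],
               grid=DEFAULT_TAU_GRID, n_lags: int = 20,
               smooth_ms: float = 5.0):
    """Choose tau by leave-one-stimulus-out CV of the linear prediction.

    The score per fold is the Pearson correlation between the (smoothed)
    linear prediction k*x + mean rate and the held-out (smoothed) response.
    Ties are broken toward the smaller retained dimension count.
    """
    from .evaluate import _smooth, prediction_correlation
    from .glm import _smooth_bins

    grid = np.asarray(sorted(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("tau grid is empty")
    if len(specs) < 3:
        raise ValueError("need at least 3 stimuli for inner cross-validation")
    scores = np.zeros(grid.size)
    for held in range(len(specs)):
        tr_specs = [s for i, s in enumerate(specs) if i != held]
        tr_resp = [r for i, r in enumerate(responses) if i != held]
        design = build_design(tr_specs, n_lags)
        eig = covariance_eigensystem(design)
        r_train = np.concatenate(tr_resp)
        X_held = lag_design(specs[held].values, n_lags) - design.col_means
        n_bins = _smooth_bins(smooth_ms, specs[held].bin_width_ms)
        obs = _smooth(np.asarray(responses[held], dtype=float), n_bins)
        for gi, tau in enumerate(grid):
            fit = nrc_filter(design, r_train, tau, eig=eig)
            pred = _smooth(fit.b + X_held @ fit.k.ravel(), n_bins)
            scores[gi] += prediction_correlation(pred, obs)
    scores /= len(specs)
    cv_table = [(float(t), float(s)) for t, s in zip(grid, scores)]
    best = int(np.argmax(scores))  # argmax takes the first (smallest tau/m) tie
    return float(grid[best]), cv_table


def fit_nrc(data, tau: float | str = "auto", n_lags: int = 20,
            grid=DEFAULT_TAU_GRID, responses: list[np.ndarray] | None = None,
            smooth_ms: float = 5.0) -> NRCFit:
    """Convenience wrapper: NRC fit from (Spectrogram, SpikeData) pairs.

    The response series is the trial-mean firing rate per bin.  With
    ``tau="auto"`` the tolerance is selected by inner cross-validation.
    ``responses`` may supply continuous rate series instead (generative
    analyses).
    """
    if isinstance(data, tuple):
        data = [data]
    specs = [d[0] if isinstance(d, tuple) else d for d in data]
    if responses is None:
        responses = []
        for spec, spikes in data:
            delta = spec.bin_width_ms / 1000.0
            responses.append(spikes.counts.mean(axis=0) / delta)
    cv_table = []
    if tau == "auto":
        tau, cv_table = select_tau(specs, responses, grid=grid,
                                   n_lags=n_lags, smooth_ms=smooth_ms)
    design = build_design(specs, n_lags)
    fit = nrc_filter(design, np.concatenate(responses), float(tau))
    fit.cv_table = cv_table
    return fit
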