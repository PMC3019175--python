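"""Output nonlinearities for the point-process encoding model.

Two closed-form nonlinearities are provided — the exponential and a
sub-exponential alternative that grows quadratically for positive input and
decays exponentially for negative input.  Both are convex with concave log,
the two conditions that keep the point-process likelihood concave in the
parameters.  Two data-driven procedures complement them: a direct empirical
reconstruction of the rate-vs-input curve from quantile bins of the filter
output, and a cubic-spline refit of that curve used post hoc for prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .spikes import SpikeData

__all__ = ["eval_nl", "eval_nl_deriv", "EmpiricalNL", "reconstruct_nl",
           "SplineNL", "fit_spline_nl"]


def eval_nl(tag: str, u):
    """Evaluate the named nonlinearity f(u) elementwise.

    ``exp``: e^u.  ``subexp``: e^u for u <= 0, 1 + u + u^2/2 for u > 0
    (C2 at 0; quadratic growth, exponential decay).
    """
    u = np.asarray(u, dtype=float)
    if tag == "exp":
        return np.exp(u)
    if tag == "subexp":
        return np.where(u <= 0, np.exp(np.minimum(u, 0.0)),
                        1.0 + u + 0.5 * u * u)
    raise ValueError(f"unknown nonlinearity {tag!r}")


def eval_nl_deriv(tag: str, u):
    """df/du for the named nonlinearity."""
    u = np.asarray(u, dtype=float)
    if tag == "exp":
        return np.exp(u)
    if tag == "subexp":
        return np.where(u <= 0, np.exp(np.minimum(u, 0.0)), 1.0 + u)
    raise ValueError(f"unknown nonlinearity {tag!r}")


@dataclass
class EmpiricalNL:
    """Empirical nonlinearity: mean spike probability per filter-output bin."""

    bin_centers: np.ndarray
    rates: np.ndarray          # per-bin spike probability (per time bin)
    counts_per_bin: np.ndarray

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        self.counts_per_bin = np.asarray(self.counts_per_bin, dtype=np.int64)


def reconstruct_nl(filter_output: np.ndarray, spikes: SpikeData | np.ndarray,
                   n_bins: int = 25) -> EmpiricalNL:
    """Direct reconstruction of the nonlinearity from the raw distribution of
    filter outputs and the observed spikes.

    ``filter_output`` u_t is aligned with the spike bins; if spikes are
    multi-trial the trial-mean count per bin is used.  Time steps are grouped
    into ``n_bins`` equal-count quantile bins of u and the mean spike count in
    each group is the bin's rate.
    """
    u = np.asarray(filter_output, dtype=float).ravel()
    if isinstance(spikes, SpikeData):
        counts = spikes.counts.mean(axis=0)
    else:
        counts = np.asarray(spikes, dtype=float).ravel()
    if u.size != counts.size:
        raise ValueError("filter output and spike bins misaligned")
    if u.size < n_bins:
        raise ValueError("fewer time bins than requested nonlinearity bins")
    order = np.argsort(u, kind="stable")
    groups = np.array_split(order, n_bins)
    centers = np.array([u[g].mean() for g in groups])
    rates = np.array([counts[g].mean() for g in groups])
    sizes = np.array([g.size for g in groups])
    return EmpiricalNL(bin_centers=centers, rates=rates, counts_per_bin=sizes)


class SplineNL:
    """Cubic-spline nonlinearity fitted to an empirical rate curve.

    The spline interpolates log-rate against filter output, so evaluation is
    ``exp(spline(u))`` and is strictly positive.  Outside the fitted range the
    log-rate is extrapolated linearly from the boundary slope, keeping
    evaluations finite and positive everywhere.
    """

    def __init__(self, bin_centers: np.ndarray, log_rates: np.ndarray):
        self.bin_centers = np.asarray(bin_centers, dtype=float)
        self.log_rates = np.asarray(log_rates, dtype=float)
        self._spline = CubicSpline(self.bin_centers, self.log_rates,
                                   bc_type="natural")
        self.lo = float(self.bin_centers[0])
        self.hi = float(self.bin_centers[-1])
        self._slope_lo = float(self._spline(self.lo, 1))
        self._slope_hi = float(self._spline(self.hi, 1))

    def __call__(self, u):
        u = np.asarray(u, dtype=float)
        logr = np.asarray(self._spline(np.clip(u, self.lo, self.hi)))
        logr = logr + np.where(u < self.lo, (u - self.lo) * self._slope_lo, 0.0)
        logr = logr + np.where(u > self.hi, (u - self.hi) * self._slope_hi, 0.0)
        return np.exp(logr)


def fit_spline_nl(empirical: EmpiricalNL) -> SplineNL:
    """Fit the spline nonlinearity to an empirical curve.

    Zero-rate bins are floored at half a count (0.5 / counts_per_bin) before
    the log, the standard small-sample continuity correction.  The spline is
    a post-hoc replacement for prediction only; it never alters fitted filter
    parameters.
    """
    if empirical.bin_centers.size < 5:
        raise ValueError("need at least 5 bins to fit a spline nonlinearity")
    floor = 0.5 / np.maximum(empirical.counts_per_bin, 1)
    rates = np.maximum(empirical.rates, floor)
    # Collapse duplicate centers (possible with heavily tied filter outputs).
    centers, inverse = np.unique(empirical.bin_centers, return_inverse=True)
    logr = np.zeros(centers.size)
    for i in range(centers.size):
        logr[i] = np.log(rates[inverse == i]).mean()
    return SplineNL(centers, logr)
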