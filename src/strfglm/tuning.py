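"""Tuning parameters extracted from an STRF.

Rectify the STRF (keep only excitatory or only inhibitory weights), average
along one axis, smooth the marginal curve with a 5-point symmetric Hanning
window, and read off the best frequency (peak / valley position) and the
half-height bandwidth around it.  Spectral metrics are in Hz, temporal ones
in ms.  Metrics that do not exist for a given STRF (e.g. the inhibitory set
of an all-positive STRF) are returned as flagged missing values, never as
silent zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["TuningSummary", "spectral_curve", "temporal_curve",
           "best_frequency", "bandwidth_half_height",
           "temporal_curve_and_bandwidth", "tuning_summary"]

_W5 = np.hanning(7)[1:-1]  # [0.25, 0.75, 1, 0.75, 0.25]
_W5 = _W5 / _W5.sum()


@dataclass
class TuningSummary:
    """Best frequencies (Hz), spectral bandwidths (Hz), temporal bandwidths
    (ms), with per-metric validity flags."""

    eBF: float | None = None
    iBF: float | None = None
    eBW: float | None = None
    iBW: float | None = None
    etBW: float | None = None
    itBW: float | None = None
    flags: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"eBF_hz": self.eBF, "eBW_hz": self.eBW, "etBW_ms": self.etBW,
                "iBF_hz": self.iBF, "iBW_hz": self.iBW, "itBW_ms": self.itBW,
                "flags": dict(self.flags)}


def _rectify(k: np.ndarray, sign: str) -> np.ndarray:
    k = np.asarray(k, dtype=float)
    if sign == "excitatory":
        return np.maximum(k, 0.0)
    if sign == "inhibitory":
        return np.maximum(-k, 0.0)
    raise ValueError("sign must be 'excitatory' or 'inhibitory'")


def _smooth5(curve: np.ndarray) -> np.ndarray:
    return ndimage.convolve1d(curve, _W5, mode="reflect")


def spectral_curve(k: np.ndarray, sign: str) -> np.ndarray:
    """Rectified STRF averaged over lags, smoothed with the 5-point window.

    For the inhibitory sign the STRF is negated before rectification, so the
    returned curve is nonnegative with the valley appearing as a peak.
    """
    return _smooth5(_rectify(k, sign).mean(axis=1))


def temporal_curve(k: np.ndarray, sign: str) -> np.ndarray:
    """Rectified STRF averaged over frequency, smoothed; indexed by lag."""
    return _smooth5(_rectify(k, sign).mean(axis=0))


def best_frequency(curve: np.ndarray, freq_centers: np.ndarray) -> float | None:
    """Frequency center of the global extremum of a rectified smoothed
    curve; ties go to the lower frequency.  All-zero curve -> None."""
    curve = np.asarray(curve, dtype=float)
    if curve.max() <= 0:
        return None
    return float(np.asarray(freq_centers)[int(np.argmax(curve))])


def bandwidth_half_height(curve: np.ndarray, centers: np.ndarray):
    """Width between the half-maximum crossings bracketing the peak.

    Crossings are located by linear interpolation between bins (sub-bin
    resolution); the half level is measured against the zero baseline of
    the rectified curve.  If a flank never drops below half before the edge
    the edge is used and the result flagged ``edge-truncated``.

    Returns (width, flag) where flag is "ok", "edge-truncated", or
    "undefined" (with width None).
    """
    curve = np.asarray(curve, dtype=float)
    centers = np.asarray(centers, dtype=float)
    peak_val = curve.max()
    if peak_val <= 0 or np.all(curve == curve[0]):
        return None, "undefined"
    peak = int(np.argmax(curve))
    half = 0.5 * peak_val
    flag = "ok"

    # walk left from the peak to the first crossing below half
    left = centers[0]
    truncated_left = True
    for i in range(peak, 0, -1):
        if curve[i - 1] < half <= curve[i]:
            frac = (curve[i] - half) / (curve[i] - curve[i - 1])
            left = centers[i] + frac * (centers[i - 1] - centers[i])
            truncated_left = False
            break
    right = centers[-1]
    truncated_right = True
    for i in range(peak, curve.size - 1):
        if curve[i + 1] < half <= curve[i]:
            frac = (curve[i] - half) / (curve[i] - curve[i + 1])
            right = centers[i] + frac * (centers[i + 1] - centers[i])
            truncated_right = False
            break
    if truncated_left or truncated_right:
        flag = "edge-truncated"
    return float(right - left), flag


def temporal_curve_and_bandwidth(k: np.ndarray, sign: str,
                                 bin_width_ms: float = 3.0):
    """Temporal half-height bandwidth (ms) of the rectified STRF.

    Mirrors the spectral pipeline along the lag axis; lag centers are at
    (lag + 0.5) * bin width.
    """
    curve = temporal_curve(k, sign)
    lag_centers = (np.arange(curve.size) + 0.5) * bin_width_ms
    return bandwidth_half_height(curve, lag_centers)


def tuning_summary(k: np.ndarray, freq_centers: np.ndarray,
                   bin_width_ms: float = 3.0) -> TuningSummary:
    """Full tuning parameter set for one STRF."""
    out = TuningSummary()
    for sign, bf_attr, bw_attr, tbw_attr in (
            ("excitatory", "eBF", "eBW", "etBW"),
            ("inhibitory", "iBF", "iBW", "itBW")):
        sc = spectral_curve(k, sign)
        bf = best_frequency(sc, freq_centers)
        setattr(out, bf_attr, bf)
        out.flags[bf_attr] = "ok" if bf is not None else "undefined"
        bw, flag = bandwidth_half_height(sc, freq_centers)
        setattr(out, bw_attr, bw)
        out.flags[bw_attr] = flag
        tbw, tflag = temporal_curve_and_bandwidth(k, sign, bin_width_ms)
        setattr(out, tbw_attr, tbw)
        out.flags[tbw_attr] = tflag
    return out
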