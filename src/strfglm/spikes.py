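"""Multi-trial spike trains binned onto the stimulus time base."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["SpikeData", "bin_spikes", "downsample_counts"]


@dataclass
class SpikeData:
    """Integer spike counts, shape [trials, time_bins], for one stimulus."""

    counts: np.ndarray
    bin_width_ms: float
    stimulus_id: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D [trials, time_bins]")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if self.bin_width_ms <= 0:
            raise ValueError("bin_width_ms must be positive")
        self.counts = self.counts.astype(np.int64)

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    @property
    def n_time(self) -> int:
        return self.counts.shape[1]

    @property
    def total_spikes(self) -> int:
        return int(self.counts.sum())


def bin_spikes(spike_times: list[np.ndarray], bin_width_ms: float,
               duration_s: float, stimulus_id: str = "") -> SpikeData:
    """Bin per-trial spike times (seconds) into half-open bins
    [t*D, (t+1)*D) measured from stimulus onset.

    Spikes at or beyond ``duration_s`` are discarded with a warning; negative
    times are an error.  Zero-spike trials are retained.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    delta = bin_width_ms / 1000.0
    n_bins = int(np.ceil(duration_s / delta - 1e-9))
    edges = np.arange(n_bins + 1) * delta
    rows = []
    n_dropped = 0
    for times in spike_times:
        t = np.sort(np.asarray(times, dtype=float))
        if t.size and t[0] < 0:
            raise ValueError("negative time")
        kept = t[t < duration_s]
        n_dropped += t.size - kept.size
        # np.histogram's last bin is closed; clip edge so [t*D,(t+1)*D) holds.
        counts, _ = np.histogram(kept, bins=edges)
        rows.append(counts)
    if n_dropped:
        warnings.warn(f"discarded {n_dropped} spike(s) at or beyond stimulus "
                      f"duration {duration_s} s")
    counts = np.vstack(rows) if rows else np.zeros((0, n_bins), dtype=np.int64)
    return SpikeData(counts=counts, bin_width_ms=bin_width_ms,
                     stimulus_id=stimulus_id)


def downsample_counts(spikes: SpikeData, time_factor: int) -> SpikeData:
    """Sum counts over non-overlapping windows of ``time_factor`` bins.

    Counts are summed (never averaged) so the total spike count is conserved
    up to the dropped trailing partial window.
    """
    if time_factor < 1:
        raise ValueError("time_factor must be >= 1")
    if time_factor == 1:
        return spikes
    n_keep = (spikes.n_time // time_factor) * time_factor
    c = spikes.counts[:, :n_keep]
    c = c.reshape(spikes.n_trials, -1, time_factor).sum(axis=2)
    return SpikeData(counts=c, bin_width_ms=spikes.bin_width_ms * time_factor,
                     stimulus_id=spikes.stimulus_id)
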