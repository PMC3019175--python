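"""From a WAV waveform and spike-time text files to aligned model inputs.

Synthesizes a tone-burst stimulus, writes it as 16-bit PCM, writes a
two-trial spike file, then runs the standard preprocessing: 63-channel
filterbank spectrogram at 1 ms, log compression with a -80 dB floor,
rebinning to 20 frequency channels at 3 ms, spike binning and downsampling
(counts summed, never averaged).
"""

import tempfile
from pathlib import Path

import numpy as np
from scipy.io import wavfile

import strfglm as sg
import strfglm.io as sio
from strfglm.spikes import downsample_counts

fs = 24000
t = np.arange(int(2.0 * fs)) / fs
burst = np.sin(2 * np.pi * 3000 * t) * (np.sin(2 * np.pi * 4.0 * t) > 0)

tmp = Path(tempfile.mkdtemp())
wavfile.write(tmp / "stim.wav", fs, (0.7 * burst * 32767).astype(np.int16))
(tmp / "spikes.txt").write_text("# two trials\n0.010 0.135 0.260 1.010\n"
                                "0.012 0.140 1.500\n")

wave, fs_read = sio.read_wav(tmp / "stim.wav")
spec = sg.compute_spectrogram(wave, fs_read)
spec = sg.log_compress(spec, floor_db=-80.0)
spec = sg.rebin(spec, n_freq=20, time_factor=3)

trials = sio.read_spike_times(tmp / "spikes.txt")
spikes = sg.bin_spikes(trials, bin_width_ms=1.0, duration_s=2.0)
spikes = downsample_counts(spikes, 3)

print(f"spectrogram: {spec.n_time} bins x {spec.n_freq} channels at "
      f"{spec.bin_width_ms:.0f} ms (log energies)")
print(f"spikes: {spikes.n_trials} trials x {spikes.n_time} bins, "
      f"{spikes.total_spikes} spikes total (conserved through binning)")
print(f"frequency centers: {spec.freq_centers_hz[0]:.0f} .. "
      f"{spec.freq_centers_hz[-1]:.0f} Hz")
# The two arrays now share the 3 ms grid the encoding models operate on.
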