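"""Tuning parameters extracted from an STRF.

Best excitatory/inhibitory frequency (peak/valley of the rectified,
lag-averaged, 5-point-Hanning-smoothed spectral curve) and the spectral /
temporal bandwidths at half height.
"""

import strfglm as sg
from strfglm.spectro import default_freq_centers

k = sg.broadband_inhibition_strf(20, 20, center_freq=0.5)
centers = default_freq_centers(20)
summary = sg.tuning_summary(k, centers, bin_width_ms=3.0)

d = summary.as_dict()
print(f"eBF  = {d['eBF_hz']:.0f} Hz   (best excitatory frequency)")
print(f"eBW  = {d['eBW_hz']:.0f} Hz   (excitatory spectral bandwidth)")
print(f"etBW = {d['etBW_ms']:.1f} ms  (excitatory temporal bandwidth)")
print(f"iBF  = {d['iBF_hz']:.0f} Hz,  iBW = {d['iBW_hz']:.0f} Hz, "
      f"itBW = {d['itBW_ms']:.1f} ms")
print("flags:", d["flags"])
# This archetype has narrow excitation flanked by broad inhibition, so the
# inhibitory spectral bandwidth comes out much wider than the excitatory one.
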