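"""Non-stationary signals: where information really lives in time-frequency.

A two-channel chirp sweeps 5 -> 50 Hz.  Instantaneous (broadband) decoding
sees information content spread up to ~100 Hz — double the signal band —
while the band-resolved complex-spectrum map peaks at the true instantaneous
frequency of the sweep.
"""

import numpy as np

from repdyn.scenarios import scenario_chirp

res = scenario_chirp()
band = np.asarray(res.summary["map_band_hz"])
info = np.asarray(res.summary["map_info"])
map_t = np.asarray(res.summary["map_time_s"])

print(f"signal frequency cap            : {res.summary['signal_cap_hz']:g} Hz")
print(f"broadband info support edge     : "
      f"{res.summary['info_support_edge_hz']:g} Hz (~ double the cap)")
print("complex-spectrum ridge (50 ms window):")
for probe in (0.1, 0.2, 0.3, 0.4):
    j = int(np.argmin(np.abs(map_t - probe)))
    ridge = band[np.argmax(info[:, j])]
    print(f"  t = {probe:.1f} s -> strongest band {ridge:g} Hz")
print()
print("The ridge follows the sweep; the broadband spectrum does not.")
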