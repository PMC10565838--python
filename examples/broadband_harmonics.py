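"""Broadband harmonics: two evoked components mix into four information lines.

With evoked components at 10 and 15 Hz (slightly different amplitudes per
condition), the squared class separation contains the doubled lines 20 and
30 Hz plus cross-band harmonics at |15-10| = 5 Hz and 15+10 = 25 Hz; the
highest information frequency is twice the highest evoked frequency.
"""

from repdyn import broadband_separation
from repdyn.scenarios import scenario_example2

res = scenario_example2()
model = res.model
params = broadband_separation(model)

print(f"evoked component frequencies : {model.freqs_hz.tolist()} Hz")
print(f"information harmonics        : {res.summary['harmonics_hz']} Hz")
print(f"highest supported frequency  : {res.summary['support_edge_hz']:g} Hz")
print(f"peaks per fundamental period : "
      f"{res.summary['peaks_per_fundamental_period']}")
print()
print("Multiple evoked components create a multi-peaked information")
print("timecourse; such successive peaks need no cognitive explanation.")
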