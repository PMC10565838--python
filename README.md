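# repdyn

**Representational dynamics of stimulus-evoked neural decoding.**

Time-resolved multivariate decoding of epoched MEG/EEG data interprets the
*timecourse* of classification accuracy as the brain's representational
dynamics. `repdyn` is a toolkit for reasoning about — and simulating — a
fundamental property of such analyses: **the frequency content of decodable
information is not the frequency content of the signal.** A sinusoidal evoked
component at frequency ω produces information content (and hence
decoding-accuracy structure) at **2ω**, because classifiers separate
conditions best at the oscillation's peaks and troughs and fail at its zero
crossings. This has three practical consequences, all of which the package
computes, simulates and tests:

1. **Frequency doubling.** For a two-condition Gaussian model
   `x(t) = μ(t) + y·Σ_ω A_ω cos(ωt + φ_ω) + noise`, the mutual information of
   the narrowband signal is `I(Z_t,ω; Y) = f(c_ω + r_ω cos(2ωt + ξ_ω))` — a
   sinusoid at twice the evoked frequency passed through a monotone concave
   link `f`. Broadband (instantaneous) decoding mixes bands, adding harmonics
   at `|ω_i ± ω_j|`, bounded by `2Ω` (twice the highest evoked frequency).
2. **Representational aliasing.** Because information occupies up to `2Ω`,
   accuracy timecourses alias unless `Fs ≥ 4Ω` — *four* samples per evoked
   cycle, twice the usual Nyquist requirement. A 30 Hz evoked component under
   100 Hz sampling produces a spurious accuracy peak at 40 Hz (60 Hz folded
   about Nyquist).
3. **Complex spectrum decoding.** Decoding with both real and imaginary STFT
   coefficients (signal value *and* gradient) gives information
   `I(W_t,ω; Y) = f(2c_ω)`: constant over time, at least the narrowband peak,
   and alias-free.

All information metrics are monotone functions of one scalar — the squared
Mahalanobis separation `d²(t)` between the class-conditional means — so the
package exposes mutual information (bits), Bayes accuracy `Φ(√d²/2)` and
discriminant distance through a common link-function interface, and validates
every closed form against a Monte-Carlo plug-in oracle sampled from the exact
class conditionals.

## Who this is for

Researchers running time-resolved decoding / MVPA on epoched
electrophysiology who want to (a) check whether features of their accuracy
timecourses (double peaks, fast rhythms) are artefacts of evoked spectral
content, (b) choose sampling rates and low-pass filters that avoid
representational aliasing, or (c) adopt complex spectrum decoding. The
simulator emulates the structure of standard epoched datasets (multichannel
trials at 100 samples/s, 0.5 s epochs, binary condition labels).

## Worked example

```python
import numpy as np
from repdyn import (broadband_info_timecourse, dominant_frequency,
                    simulate_trials, stft_epochs, decode_narrowband,
                    decode_complex, accuracy_psd)
from repdyn.scenarios import example1_model

model = example1_model()          # 2 channels; condition 1 evokes 10 Hz
mi = broadband_info_timecourse(model)
print(dominant_frequency(mi.value, model.sample_rate_hz))   # 20.0

ds = simulate_trials(model, 400, seed=0)
feats = stft_epochs(ds, window_ms=100.0)
nb = decode_narrowband(feats, 10.0, seed=0, labels=ds.labels)
cx = decode_complex(feats, 10.0, seed=0, labels=ds.labels)
print(round(nb.mean_accuracy, 3), round(cx.mean_accuracy, 3))  # 0.734 0.837
f, p = accuracy_psd(nb)
print(f[np.argmax(p)])            # 20.0  — accuracy oscillates at 2ω
```

The printed numbers say: a 10 Hz evoked component yields information peaking
at 20 Hz; cross-validated narrowband decoding averages 73% because its
accuracy oscillates through chance at the oscillation's zero crossings, while
complex spectrum decoding holds a stable ~84% (the Bayes accuracy of the
time-averaged separation); the PSD of the narrowband accuracy timecourse
confirms the 20 Hz rhythm.

The `examples/` directory holds one short script per capability
(`frequency_doubling.py`, `broadband_harmonics.py`, `aliasing_demo.py`,
`complex_stability.py`, `chirp_timefrequency.py`, `decode_simulated.py`);
each builds a small input, runs the method and explains what it prints.

## Command line

A thin CLI wraps the library for shell use:

```bash
repdyn simulate  --config model.yaml --n-trials 200 --seed 0 --out trials.h5
repdyn info      --config model.yaml --scope narrowband --band 10 --out mi.csv
repdyn aliascheck --config model.yaml --fs 30          # flags aliased bands
repdyn stft      --data trials.h5 --window-ms 100 --out features.h5
repdyn decode    --data trials.h5 --paradigm complex --band 10 --seed 0 --out acc.csv
repdyn scenario  example1 --out outdir/
```

Epoched data travel as an HDF5 container (`data`, `labels`, `time_s`) with a
JSON metadata sidecar; model configs are YAML/JSON.

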