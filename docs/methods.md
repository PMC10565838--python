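# Methods

## The generative model

Epoched data from `P` channels under two equiprobable conditions
`y ∈ {+1, −1}` are modelled as a Fourier series with stationary bandlimited
Gaussian noise:

```
x_n(t) = μ(t) + Σ_ω Re(w_n,t,ω)
w_n,t,ω = y_n A_ω e^{i(ωt + φ_ω)} + ε_n,ω e^{iωt}
ε_n,ω  = N(0, Σ_ω) + i·N(0, Σ_ω)
```

`A_ω` is the diagonal matrix of per-channel evoked amplitudes, `φ_ω` the
per-channel phase offsets, and `Σ_ω` a symmetric positive-definite spatial
covariance per band. The complex residual `ε` is drawn **once per trial per
band** and rotated around the epoch by `e^{iωt}`: the residual therefore has
fixed within-trial amplitude and uniform phase relative to stimulus onset —
exactly the structure of induced (non-phase-locked) band power. Marginally
at each timepoint, `x(t) | y ~ N(μ(t) + y Σ_ω A_ω cos(ωt + φ_ω), Σ_ω Σ_ω)`,
stationary in covariance.

Assumptions and conventions:

* binary, exactly balanced, equiprobable conditions (labels alternate in the
  simulator); the information ceiling is therefore 1 bit;
* `t = 0` at stimulus onset; time in seconds; frequencies in Hz externally
  and rad/s inside formulas; phases stored wrapped to `[0, 2π)`;
* `μ(t) = 0` by default — the baseline cancels from every information
  quantity, and none of the demonstrations uses a nonzero baseline except
  example 2, which stores the condition-*common* oscillation there;
* Gaussian residuals only; every `Σ_ω` must be strictly positive definite
  (no pseudo-inverse fallback — a singular covariance is a modelling error);
* induced condition effects are parameterised as a per-condition scale on
  the residual's Cholesky factor, `ε → s_{ω,y} ε`.

## Information content

With shared covariance, every standard decoding metric is a monotone
function of the squared Mahalanobis separation between the class means,
`d²(t) = δ(t)'Σ⁻¹δ(t)` with `δ(t)` the class-mean difference. Writing each
band's complex amplitude vector `v_i = a_i e^{iφ_i}` and `Q = Σ⁻¹`, the
product-to-sum identity gives the narrowband expansion

```
d²(t) = c + r cos(2ωt + ξ),   c = 2·Re(v̄'Qv),   r e^{iξ} = 2·v'Qv ,
```

with `r ≤ c` by Cauchy–Schwarz (so `d² ≥ 0` everywhere). For the broadband
signal the same expansion over all signed band pairs produces a constant
plus sinusoids at `2ω_i` and `|ω_i ± ω_j|` — support bounded by twice the
model bandwidth `2Ω`. For the complex features `(Re w, Im w)` the
cos²+sin² identity removes time entirely: `d² = 2c`, constant, and
`f(2c) ≥ f(c + r)` with equality iff the modulation is full (`r = c`).

Link functions (module `infotheory`):

* `link_mi` — mutual information in bits, computed as
  `1 − E[H_b(P(Y=1|x))]` along the discriminant projection with a 300-node
  Gauss–Hermite rule (absolute error < 2e-9, validated in-test against
  adaptive quadrature); monotone increasing and concave.
* `link_accuracy` — Bayes accuracy `Φ(√d²/2)`.
* `link_distance` — expected absolute standardized discriminant projection
  `m(2Φ(m) − 1) + 2φ(m)`, `m = √d²/2`.

Because the link is nonlinear, the *metric* timecourse is not strictly
bandlimited: it inherits faint harmonics above `2Ω` (measured < 0.2% of peak
power across random models). All spectral-support statements therefore use
the 1%-of-peak support rule, and all spectral measurements are made over an
integer number of cycles so periodic components fall on exact FFT bins.

**Monte-Carlo oracle.** `mc_mi_estimate` samples the exact class
conditionals (including induced covariance differences, for which no closed
form exists) and averages the posterior label entropy; the reported SE is
the standard error of the i.i.d. per-sample entropy terms. The analytic
formulas are required to agree with this oracle within sampling error; the
induced-effects bounds (time-invariance of induced-only information,
subadditivity of combined effects) are probed the same way.

## Aliasing

The information component of a band at ω lives at 2ω, so alias-free
instantaneous decoding requires `Fs ≥ 4Ω`; the boundary rate passes.
`alias_frequency` folds a frequency into `[0, Fs/2]` by reflection about
Nyquist multiples; folding *to* exactly Nyquist maps to Nyquist. Empirical
folding checks locate the argmax-power non-DC FFT bin of the analytic
information timecourse sampled over an integer number of cycles.

## STFT features

Sliding-window one-sided DFT per trial and channel. Choices the data do not
dictate, fixed as follows:

* **Window**: Hamming by default (Hann and boxcar available); 100 ms for
  the MEG-like sampling regime, 50 ms in the fast simulation scenarios.
  Band spacing is `1000/window_ms` Hz from 0 to Nyquist.
* **Hop**: 1 sample by default so decoding is per-timepoint; configurable.
* **Edges**: symmetric reflection padding so one window is centred on every
  output sample and the feature time axis equals the epoch's; a
  "valid-only" mode restricts to fully interior windows.
* **Normalisation**: amplitude-interpretable — a unit sinusoid at a band
  centre yields unit magnitude (DC and Nyquist bins scaled accordingly).
* **Phase**: referenced to the window centre, so the real part of band ω
  estimates the model's narrowband signal at the output timepoint and the
  imaginary part its quadrature.

The 0 Hz and Nyquist bands have identically zero imaginary parts, so
narrowband and complex decoding coincide there (tested). A Parseval
identity (windowed power recoverable from the one-sided bins) holds exactly
and is tested; note a tapered window's own transform leaks a constant input
into the first band — only with a boxcar is DC confined to the 0 Hz bin.

## Decoding protocol

Linear maximum-margin classifier (hinge loss, fixed `C = 1`, no tuning),
stratified k-fold CV (3 folds by default), features standardized per
training fold, fold structure shared across timepoints so timecourses are
comparable, all splits seeded. Reported accuracy is the mean of per-fold
accuracies. The aggregate classifier is a nested CV: per-band complex
decoders produce decision values (signed hyperplane distances — richer than
hard labels), out-of-fold within the outer-training set and full-fit for the
outer-test set; a 100-tree random forest stacks them; the outer 2-fold loop
repeats 10 times on bootstrap-resampled trials and averages. Stratification
is over the binary labels.

`accuracy_psd` is the periodogram of the mean-removed accuracy timecourse.
`cluster_permutation_test` uses a paired t statistic per timepoint,
two-sided cluster-forming threshold at α = 0.05 by default, cluster mass =
summed t within sign-consistent suprathreshold runs, a sign-flipping null
for the maximum |mass|, and `p = (1 + #{perm ≥ obs})/(n_perm + 1)` — so the
smallest attainable p is `1/(n_perm+1)` and the test is exact-conservative.
Its family-wise error is verified by simulation (500 null runs within the
binomial 99% CI of nominal α).

## Scenarios: what the generator emulates, and the chosen conditions

The simulator emulates epoched visual-MEG-like data: 100 samples/s, 0.5 s
epochs, binary labels, a handful of channels. It does **not** emulate
sensor-count realism (hundreds of channels), 1/f background spectra,
non-Gaussian or nonstationary noise, inter-subject variability, or
artefacts; passing tests therefore establish the theory and the estimators'
behaviour under the model's assumptions, not performance on raw recordings.

Conditions fixed once, with rationale:

* **example 1** — 2 channels, 10 Hz, amplitude `1/√2` per channel, unit
  band noise ⇒ `c = r = 2`: peak Bayes accuracy `Φ(1) ≈ 0.84` (typical of
  strong pairwise MEG decoding) and troughs at exact chance.
* **example 2** — 10 + 15 Hz in both conditions, base amplitude 1, 20%
  condition contrast (the informative amplitude is half the difference,
  0.1); channel 2 lags the bands by (π/4, 3π/8), as when oscillations
  propagate across sensors. These lags make the information timecourse show
  three distinct peaks per 0.2 s fundamental period while keeping all four
  harmonics {5, 20, 25, 30} Hz present; with zero lags two extra minor
  peaks sit exactly at the 10% prominence rule, and a π/2 lag would null
  the 30 Hz line.
* **aliasing** — example-1 information sampled at 160/40/30 Hz.
* **chirp** — two channels sharing a half-sine instantaneous-frequency
  profile 5→50 Hz (zero-slope junction into a dwell at the 50 Hz cap;
  sweep onsets staggered at 0 and 0.15 s) under an amplitude envelope with
  `env² = Hann(epoch)`. The envelope choice is load-bearing: the squared
  contrast — hence the information timecourse — is then amplitude-modulated
  by exactly one FFT bin, so the information spectrum genuinely terminates
  within one bin of 100 Hz. Hard step gates put sinc sidebands at 104–108 Hz
  above the 1% support rule and are not bandlimited below the stated 50 Hz
  cap; any 0.5 s signal necessarily carries ±2 Hz (one-bin) spectral width.
* **activations** — non-oscillatory Gaussian activations (σ = 30 ms) at
  0.15 s / 0.35 s on separate channels; analysed with 50 ms and 200 ms
  windows. The 50 ms window resolves two information peaks; the 200 ms
  window smears them (reduced prominence / merger), illustrating the window
  length trade-off.

Waveform scenarios state their noise per feature level: unit broadband
variance for the instantaneous map and unit complex band variance for the
band-resolved map; the two maps are illustrative and not required to share
one noise budget.

Peak detection throughout: local maxima with prominence ≥ 10% of the global
maximum; spectral support: bins above 1% of the peak non-DC power.

## Numerical choices and degenerate inputs

* SPD validation via smallest eigenvalue (> 0) at model build; the summed
  covariance must also be SPD for broadband quantities.
* Separations within `−1e−9` of zero (float cancellation at exact zeros of
  the timecourse) are clipped to 0; genuinely negative input is an error.
* `link_mi(0) = 0` exactly; outputs clipped to `[0, 1]`.
* Harmonic accumulation keys frequencies rounded to 1e-9 Hz; terms below
  `1e-12` of the dominant coefficient are dropped; `ξ` is set to 0 when
  `r = 0`.
* Odd trial counts are rejected (the design is exactly balanced); labels
  outside `{+1, −1}` are rejected at container construction and read time.
* LinearSVC uses `max_iter = 20000`, `random_state = 0`; zero-variance
  features pass harmlessly through the standardizer.

## Problem sizes used by the test suite

Simulation checks use sizes chosen to make their statistics decisive at
desk scale: 10⁴ trials for mean-convergence, 10⁵ samples per Monte-Carlo
probe (SE ≈ 1e-3 bits), 1000 trials × 50 timepoints for accuracy-surface
recovery, 20 seeds for the complex-vs-narrowband comparison, 500 null
simulations × 500 permutations for cluster calibration, 50–100 random
models for property sweeps.

## Known limitations

* Two conditions only; no multi-class information measures.
* Gaussian class conditionals; no k-NN/KSG estimators for unknown
  densities.
* No wavelet/multitaper features (the STFT fixed-resolution trade-off is
  the deliberate choice here).
* The induced-effects information has no closed form; the package provides
  Monte-Carlo probes (time-invariance, subadditivity) rather than an
  analytic bound.
* Reading vendor MEG formats is out of scope; the HDF5 container is the
  interchange format.
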