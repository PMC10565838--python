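"""Representational-aliasing arithmetic.

A sinusoidal evoked component at frequency ``w`` produces information content
(decoding-accuracy structure) at ``2w``, so the information spectrum of a
model with bandwidth ``Omega`` extends to ``2 Omega``.  Sampled accuracy
timecourses therefore alias unless the sampling rate satisfies
``Fs >= 4 Omega`` — twice the usual Nyquist requirement on the signal itself.
Components above the Nyquist frequency fold back by reflection about its
multiples, producing spurious peaks at predictable locations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evoked_model import EvokedSpectrumModel

__all__ = [
    "AliasReport",
    "info_bandwidth",
    "alias_frequency",
    "min_sample_rate",
    "check_sampling",
    "dominant_frequency",
    "power_spectrum",
]


@dataclass
class AliasReport:
    """Folding outcome for one band's information-spectrum component."""

    band_hz: float
    info_freq_hz: float
    sample_rate_hz: float
    nyquist_hz: float
    observed_freq_hz: float
    is_aliased: bool


def info_bandwidth(model: EvokedSpectrumModel) -> float:
    """Highest frequency of the information spectrum: twice the model
    bandwidth ``Omega`` (highest band with nonzero evoked amplitude)."""
    return 2.0 * model.max_freq_hz


def alias_frequency(freq_hz: float, sample_rate_hz: float) -> float:
    """Fold a frequency into ``[0, Fs/2]`` by reflection about Nyquist
    multiples; the identity whenever ``freq_hz <= Fs/2``."""
    if sample_rate_hz <= 0:
        raise ValueError("sample rate must be positive")
    if freq_hz < 0:
        raise ValueError("frequency must be non-negative")
    g = float(freq_hz) % float(sample_rate_hz)
    if g > sample_rate_hz / 2.0:
        g = sample_rate_hz - g
    return g


def min_sample_rate(model: EvokedSpectrumModel) -> float:
    """Minimum alias-free sampling rate for instantaneous decoding: 4*Omega."""
    return 2.0 * info_bandwidth(model)


def check_sampling(
    model: EvokedSpectrumModel, sample_rate_hz: float
) -> list[AliasReport]:
    """Per-band alias reports at the given sampling rate.

    A band is flagged when its information component ``2w`` exceeds the
    Nyquist frequency; the boundary ``Fs = 4 Omega`` passes.
    """
    if sample_rate_hz <= 0:
        raise ValueError("sample rate must be positive")
    nyq = sample_rate_hz / 2.0
    reports = []
    for f in model.freqs_hz:
        info_f = 2.0 * float(f)
        obs = alias_frequency(info_f, sample_rate_hz)
        reports.append(
            AliasReport(
                band_hz=float(f),
                info_freq_hz=info_f,
                sample_rate_hz=float(sample_rate_hz),
                nyquist_hz=nyq,
                observed_freq_hz=obs,
                is_aliased=bool(info_f > nyq + 1e-9),
            )
        )
    return reports


def power_spectrum(values: np.ndarray, sample_rate_hz: float):
    """One-sided FFT power of a mean-removed timecourse.

    Assumes the samples span an integer number of cycles of any periodic
    content, so periodic components fall on exact bins.  Returns
    ``(freqs_hz, power)`` with the DC bin retained (power 0 after mean
    removal).
    """
    x = np.asarray(values, dtype=float)
    x = x - x.mean()
    spec = np.fft.rfft(x)
    power = np.abs(spec) ** 2 / len(x)
    freqs = np.fft.rfftfreq(len(x), d=1.0 / sample_rate_hz)
    return freqs, power


def dominant_frequency(values: np.ndarray, sample_rate_hz: float) -> float:
    """Dominant nonzero frequency of a sampled timecourse (argmax FFT power
    excluding DC)."""
    freqs, power = power_spectrum(values, sample_rate_hz)
    if len(freqs) < 2:
        raise ValueError("timecourse too short to estimate a frequency")
    k = 1 + int(np.argmax(power[1:]))
    return float(freqs[k])
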