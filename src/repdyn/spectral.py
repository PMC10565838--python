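"""Sliding-window STFT features for epoched trials.

Each trial/channel is expanded into complex Fourier coefficients per band and
window position.  Coefficients are amplitude-normalised (a unit sinusoid at a
band centre has unit magnitude) and phase-referenced to the window centre, so
the real part of band ``w`` estimates the model's narrowband signal
``z(t) ~ A cos(w t + phi)`` at the output timepoint and the imaginary part its
quadrature (gradient) component.  By construction the imaginary part is
identically zero in the 0 Hz band and the Nyquist band.

Band spacing is set by the window length alone (``1000 / window_ms`` Hz),
independent of the sampling rate.  With reflection padding and a hop of one
sample the output time axis coincides with the epoch's, so decoding can run
timepoint-by-timepoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import get_window

from .evoked_model import TrialDataset

__all__ = [
    "SpectralFeatures",
    "MissingBandError",
    "stft_epochs",
    "band_real_features",
    "band_complex_features",
    "write_features",
    "read_features",
]

_WINDOWS = {"hamming": "hamming", "hann": "hann", "boxcar": "boxcar"}


class MissingBandError(KeyError):
    """Requested band is not among the computed STFT bands."""


@dataclass
class SpectralFeatures:
    """Complex STFT coefficients, trials x channels x bands x time."""

    coeffs: np.ndarray
    band_hz: np.ndarray
    window_ms: float
    window_shape: str
    hop_samples: int
    sample_rate_hz: float
    time_s: np.ndarray

    @property
    def n_trials(self) -> int:
        return self.coeffs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[1]

    def band_index(self, band_hz: float) -> int:
        hits = np.flatnonzero(np.isclose(self.band_hz, band_hz, atol=1e-6))
        if not hits.size:
            raise MissingBandError(
                f"band {band_hz:g} Hz not among computed bands {self.band_hz}"
            )
        return int(hits[0])


def stft_epochs(
    dataset: TrialDataset,
    window_ms: float = 100.0,
    hop_samples: int = 1,
    window_shape: str = "hamming",
    padding: str = "reflect",
) -> SpectralFeatures:
    """Sliding-window one-sided DFT of every trial and channel.

    Parameters
    ----------
    window_ms :
        Window length in milliseconds; sets the band resolution
        ``1000 / window_ms`` Hz.
    hop_samples :
        Step between window positions. 1 gives per-timepoint features.
    window_shape :
        Taper name: ``hamming`` (default), ``hann`` or ``boxcar``.
    padding :
        ``"reflect"`` (default) symmetrically extends the epoch so one window
        is centred on every ``hop``-th sample and the output time axis spans
        the epoch; ``"valid"`` keeps only fully interior windows.
    """
    if window_ms <= 0:
        raise ValueError("window_ms must be positive")
    if hop_samples < 1:
        raise ValueError("hop_samples must be a positive integer")
    if window_shape not in _WINDOWS:
        raise ValueError(
            f"unknown window shape {window_shape!r}; choose from {sorted(_WINDOWS)}"
        )

    fs = dataset.sample_rate_hz
    n_t = dataset.n_timepoints
    length = int(round(window_ms / 1000.0 * fs))
    if length < 2:
        raise ValueError("window shorter than two samples")
    if length > n_t:
        raise ValueError(
            f"window of {length} samples is longer than the epoch ({n_t} samples)"
        )

    win = get_window(_WINDOWS[window_shape], length)
    half = length // 2

    if padding == "reflect":
        padded = np.pad(
            dataset.data, ((0, 0), (0, 0), (half, length - 1 - half)), mode="reflect"
        )
        positions = np.arange(0, n_t, hop_samples)
        centres = positions
    elif padding == "valid":
        padded = dataset.data
        positions = np.arange(0, n_t - length + 1, hop_samples)
        centres = positions + half
    else:
        raise ValueError("padding must be 'reflect' or 'valid'")

    windows = sliding_window_view(padded, length, axis=2)[:, :, positions, :]
    coeffs = np.fft.rfft(windows * win, axis=3)  # (N, P, T', K)

    k = np.arange(coeffs.shape[3])
    scale = np.full(k.shape, 2.0 / win.sum())
    scale[0] = 1.0 / win.sum()
    if length % 2 == 0:
        scale[-1] = 1.0 / win.sum()
    # reference phase to the window centre so Re(w) tracks the narrowband
    # signal at the output timepoint
    phase_ref = np.exp(1j * 2.0 * np.pi * k * half / length)
    coeffs = coeffs * (scale * phase_ref)

    return SpectralFeatures(
        coeffs=np.transpose(coeffs, (0, 1, 3, 2)),
        band_hz=k * fs / length,
        window_ms=float(window_ms),
        window_shape=window_shape,
        hop_samples=int(hop_samples),
        sample_rate_hz=fs,
        time_s=dataset.time_s[centres],
    )


def band_real_features(features: SpectralFeatures, band_hz: float) -> np.ndarray:
    """Real coefficients of one band: ``(trials, channels, time)``.

    These are the features of narrowband signal decoding — equivalent to
    decoding band-pass-filtered data.
    """
    return features.coeffs[:, :, features.band_index(band_hz), :].real.copy()


def band_complex_features(features: SpectralFeatures, band_hz: float) -> np.ndarray:
    """Real and imaginary coefficients stacked: ``(trials, 2*channels, time)``.

    The first half equals :func:`band_real_features`; the second half carries
    the quadrature (gradient) information used by complex spectrum decoding.
    """
    b = features.band_index(band_hz)
    w = features.coeffs[:, :, b, :]
    return np.concatenate([w.real, w.imag], axis=1)


def write_features(features: SpectralFeatures, path) -> None:
    """Persist features in an HDF5 container (complex stored as two floats)."""
    with h5py.File(path, "w") as h5:
        h5.create_dataset("coeffs_real", data=features.coeffs.real)
        h5.create_dataset("coeffs_imag", data=features.coeffs.imag)
        h5.create_dataset("band_hz", data=features.band_hz)
        h5.create_dataset("time_s", data=features.time_s)
        h5.attrs["window_ms"] = features.window_ms
        h5.attrs["window_shape"] = features.window_shape
        h5.attrs["hop_samples"] = features.hop_samples
        h5.attrs["sample_rate_hz"] = features.sample_rate_hz


def read_features(path) -> SpectralFeatures:
    with h5py.File(path, "r") as h5:
        return SpectralFeatures(
            coeffs=h5["coeffs_real"][()] + 1j * h5["coeffs_imag"][()],
            band_hz=h5["band_hz"][()],
            time_s=h5["time_s"][()],
            window_ms=float(h5.attrs["window_ms"]),
            window_shape=str(h5.attrs["window_shape"]),
            hop_samples=int(h5.attrs["hop_samples"]),
            sample_rate_hz=float(h5.attrs["sample_rate_hz"]),
        )
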