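"""Two-condition generative model of epoched multichannel neural data.

The model describes stimulus-evoked activity recorded on ``P`` channels over a
short epoch following stimulus onset.  On each trial the data are a
condition-independent baseline plus a sum of narrowband Fourier components; the
component at angular frequency ``w`` carries a phase-locked (evoked) part whose
sign follows the binary condition label ``y in {+1, -1}``, and a stationary
Gaussian residual with band-specific spatial covariance::

    x(t) = mu(t) + y * sum_w A_w cos(w t + phi_w) + noise(t)

In the complex spectral view each band's contribution is ``Re(w_t)`` with
``w_t = y A_w exp(i(w t + phi_w)) + eps_w exp(i w t)`` and
``eps_w = N(0, Sigma_w) + i N(0, Sigma_w)`` drawn once per trial, so the
residual has random but fixed within-trial amplitude and uniform phase —
exactly the structure of induced (non-phase-locked) band power.  Optional
per-condition scaling of ``eps_w`` models condition-dependent induced effects.

Frequencies are specified in Hz externally and converted to rad/s inside the
formulas; time is in seconds with t = 0 at stimulus onset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import yaml

TWO_PI = 2.0 * np.pi

__all__ = [
    "EvokedSpectrumModel",
    "TrialDataset",
    "ModelValidationError",
    "DatasetFormatError",
    "build_model",
    "evoked_waveform",
    "simulate_trials",
    "write_dataset",
    "read_dataset",
]


class ModelValidationError(ValueError):
    """Raised when a model specification violates its invariants."""


class DatasetFormatError(ValueError):
    """Raised when an epoched-data container is malformed."""


def _as_spd(cov: np.ndarray, band_hz: float) -> np.ndarray:
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ModelValidationError(
            f"noise covariance for band {band_hz} Hz is not square: shape {cov.shape}"
        )
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ModelValidationError(
            f"noise covariance for band {band_hz} Hz is not symmetric"
        )
    min_eig = float(np.linalg.eigvalsh(cov).min())
    if min_eig <= 0.0:
        raise ModelValidationError(
            f"noise covariance for band {band_hz} Hz is not positive definite "
            f"(min eigenvalue {min_eig:.3e})"
        )
    return cov


@dataclass
class EvokedSpectrumModel:
    """Full parameterisation of the two-condition evoked-spectrum model.

    Parameters
    ----------
    n_channels :
        Number of recording channels ``P``.
    sample_rate_hz :
        Sampling rate ``Fs`` of the epoch grid.
    epoch_length_s :
        Epoch duration in seconds; the grid has ``round(Fs * length)`` samples.
    freqs_hz :
        Band centre frequencies (non-negative, each at or below Nyquist); the
        highest entry with nonzero amplitude is the model bandwidth ``Omega``.
    amplitudes :
        ``(n_bands, P)`` non-negative evoked amplitudes (diagonal of ``A_w``).
    phases :
        ``(n_bands, P)`` phase offsets, stored wrapped to ``[0, 2*pi)``.
    noise_cov :
        ``(n_bands, P, P)`` symmetric positive-definite band covariances.
    baseline_mean :
        ``(P, n_timepoints)`` condition-independent mean ``mu(t)``; defaults
        to zero (it cancels from every information quantity).
    induced :
        Optional mapping ``band_hz -> (scale_pos, scale_neg)`` multiplying the
        residual amplitude per condition, modelling condition-dependent
        induced band power.
    """

    n_channels: int
    sample_rate_hz: float
    epoch_length_s: float
    freqs_hz: np.ndarray
    amplitudes: np.ndarray
    phases: np.ndarray
    noise_cov: np.ndarray
    baseline_mean: np.ndarray | None = None
    induced: dict[float, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        self.n_channels = int(self.n_channels)
        self.sample_rate_hz = float(self.sample_rate_hz)
        self.epoch_length_s = float(self.epoch_length_s)
        if self.n_channels <= 0:
            raise ModelValidationError("n_channels must be positive")
        if self.sample_rate_hz <= 0:
            raise ModelValidationError("sample_rate_hz must be positive")
        if self.epoch_length_s <= 0:
            raise ModelValidationError("epoch_length_s must be positive")

        self.freqs_hz = np.atleast_1d(np.asarray(self.freqs_hz, dtype=float))
        nb, p = len(self.freqs_hz), self.n_channels
        self.amplitudes = np.broadcast_to(
            np.asarray(self.amplitudes, dtype=float), (nb, p)
        ).copy()
        self.phases = np.mod(
            np.broadcast_to(np.asarray(self.phases, dtype=float), (nb, p)), TWO_PI
        )
        self.noise_cov = np.asarray(self.noise_cov, dtype=float)
        if self.noise_cov.shape != (nb, p, p):
            raise ModelValidationError(
                f"noise_cov must have shape {(nb, p, p)}, got {self.noise_cov.shape}"
            )

        if np.any(self.freqs_hz < 0):
            raise ModelValidationError("frequencies must be non-negative")
        nyq = self.sample_rate_hz / 2.0
        above = self.freqs_hz[self.freqs_hz > nyq + 1e-12]
        if above.size:
            raise ModelValidationError(
                f"frequency {above[0]:g} Hz exceeds the Nyquist frequency {nyq:g} Hz"
            )
        if np.any(self.amplitudes < 0):
            raise ModelValidationError("amplitudes must be non-negative")
        for f, cov in zip(self.freqs_hz, self.noise_cov):
            _as_spd(cov, f)

        if self.baseline_mean is None:
            self.baseline_mean = np.zeros((p, self.n_timepoints))
        else:
            self.baseline_mean = np.asarray(self.baseline_mean, dtype=float)
            if self.baseline_mean.shape != (p, self.n_timepoints):
                raise ModelValidationError(
                    "baseline_mean must have shape "
                    f"{(p, self.n_timepoints)}, got {self.baseline_mean.shape}"
                )
        if self.induced is not None:
            self.induced = {
                float(f): (float(s[0]), float(s[1])) for f, s in self.induced.items()
            }
            for f, (sp, sm) in self.induced.items():
                if self.band_index(f) is None:
                    raise ModelValidationError(
                        f"induced scaling given for unknown band {f:g} Hz"
                    )
                if sp <= 0 or sm <= 0:
                    raise ModelValidationError("induced scalings must be positive")

    # -- derived geometry -------------------------------------------------
    @property
    def n_timepoints(self) -> int:
        return int(round(self.epoch_length_s * self.sample_rate_hz))

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_timepoints) / self.sample_rate_hz

    @property
    def nyquist_hz(self) -> float:
        return self.sample_rate_hz / 2.0

    @property
    def max_freq_hz(self) -> float:
        """Highest band frequency with any nonzero evoked amplitude (Omega)."""
        nz = [f for f, a in zip(self.freqs_hz, self.amplitudes) if np.any(a > 0)]
        if not nz:
            raise ModelValidationError("model has no band with nonzero amplitude")
        return float(max(nz))

    def band_index(self, band_hz: float) -> int | None:
        hits = np.flatnonzero(np.isclose(self.freqs_hz, band_hz, atol=1e-9))
        return int(hits[0]) if hits.size else None

    def induced_scales(self, band_hz: float) -> tuple[float, float]:
        """Residual amplitude scaling for (y=+1, y=-1) in the given band."""
        if self.induced is None:
            return (1.0, 1.0)
        for f, s in self.induced.items():
            if np.isclose(f, band_hz, atol=1e-9):
                return s
        return (1.0, 1.0)

    def to_config(self) -> dict:
        """Round-trippable plain-python parameter mapping (see build_model)."""
        comps = []
        for i, f in enumerate(self.freqs_hz):
            comp = {
                "freq_hz": float(f),
                "amplitudes": self.amplitudes[i].tolist(),
                "phases": self.phases[i].tolist(),
                "noise_cov": self.noise_cov[i].tolist(),
            }
            if self.induced is not None:
                sp, sm = self.induced_scales(f)
                if (sp, sm) != (1.0, 1.0):
                    comp["induced_scale"] = [sp, sm]
            comps.append(comp)
        cfg = {
            "n_channels": self.n_channels,
            "sample_rate_hz": self.sample_rate_hz,
            "epoch_length_s": self.epoch_length_s,
            "components": comps,
        }
        if np.any(self.baseline_mean):
            cfg["baseline_mean"] = self.baseline_mean.tolist()
        return cfg


@dataclass
class TrialDataset:
    """Epoched trials x channels x time data with binary condition labels."""

    data: np.ndarray
    labels: np.ndarray
    sample_rate_hz: float
    time_s: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels)
        self.time_s = np.asarray(self.time_s, dtype=float)
        if self.data.ndim != 3:
            raise DatasetFormatError(
                f"data must be trials x channels x time, got shape {self.data.shape}"
            )
        if self.labels.shape != (self.data.shape[0],):
            raise DatasetFormatError("labels length does not match trial count")
        if self.time_s.shape != (self.data.shape[2],):
            raise DatasetFormatError("time_s length does not match time dimension")
        if not np.all(np.isin(self.labels, (1, -1))):
            raise DatasetFormatError("labels must contain only +1 and -1")
        self.labels = self.labels.astype(np.int8)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[2]


# ---------------------------------------------------------------------------
# construction

def _load_mapping(config) -> dict:
    if isinstance(config, (str, Path)):
        path = Path(config)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            return json.loads(text)
        return yaml.safe_load(text)
    return dict(config)


def build_model(config) -> EvokedSpectrumModel:
    """Build a validated :class:`EvokedSpectrumModel` from a parameter mapping.

    ``config`` may be a dict or a path to a YAML/JSON file with keys
    ``n_channels``, ``sample_rate_hz``, ``epoch_length_s``, a ``components``
    list (each with ``freq_hz`` and optional ``amplitudes``, ``phases``,
    ``noise_cov``, ``induced_scale``) and optional ``default_noise_variance``
    (identity scaling used where a component omits its covariance) and
    ``baseline_mean``.
    """
    cfg = _load_mapping(config)
    try:
        p = int(cfg["n_channels"])
        fs = float(cfg["sample_rate_hz"])
        length = float(cfg["epoch_length_s"])
        comps = cfg["components"]
    except KeyError as exc:
        raise ModelValidationError(f"config is missing required key {exc}") from None
    if not comps:
        raise ModelValidationError("config must list at least one component")

    default_var = float(cfg.get("default_noise_variance", 1.0))
    freqs, amps, phases, covs = [], [], [], []
    induced: dict[float, tuple[float, float]] = {}
    for comp in comps:
        f = float(comp["freq_hz"])
        freqs.append(f)
        amps.append(np.broadcast_to(np.asarray(comp.get("amplitudes", 0.0), float), p))
        phases.append(np.broadcast_to(np.asarray(comp.get("phases", 0.0), float), p))
        cov = comp.get("noise_cov")
        covs.append(default_var * np.eye(p) if cov is None else np.asarray(cov, float))
        if "induced_scale" in comp:
            sp, sm = comp["induced_scale"]
            induced[f] = (float(sp), float(sm))

    return EvokedSpectrumModel(
        n_channels=p,
        sample_rate_hz=fs,
        epoch_length_s=length,
        freqs_hz=np.asarray(freqs),
        amplitudes=np.stack(amps),
        phases=np.stack(phases),
        noise_cov=np.stack(covs),
        baseline_mean=cfg.get("baseline_mean"),
        induced=induced or None,
    )


# ---------------------------------------------------------------------------
# simulation

def evoked_waveform(model: EvokedSpectrumModel, label: int) -> np.ndarray:
    """Noise-free class mean ``mu(t) + y * sum_w A_w cos(w t + phi_w)``.

    Returns a ``(channels, time)`` array on the model's time grid.
    """
    if label not in (1, -1):
        raise ValueError("label must be +1 or -1")
    t = model.time_s[None, :]
    out = model.baseline_mean.copy()
    for f, a, phi in zip(model.freqs_hz, model.amplitudes, model.phases):
        out += label * a[:, None] * np.cos(TWO_PI * f * t + phi[:, None])
    return out


def class_mean_difference(model: EvokedSpectrumModel) -> np.ndarray:
    """Difference of the two class means, ``2 sum_w A_w cos(w t + phi_w)``."""
    return evoked_waveform(model, 1) - evoked_waveform(model, -1)


def evoked_waveform_frame(model: EvokedSpectrumModel):
    """Both conditions' evoked waveforms as a tidy table (for CSV/plots)."""
    import pandas as pd

    rows = []
    for label in (1, -1):
        wave = evoked_waveform(model, label)
        for ch in range(model.n_channels):
            rows.append(pd.DataFrame({
                "time_s": model.time_s,
                "value": wave[ch],
                "channel": ch,
                "condition": label,
            }))
    return pd.concat(rows, ignore_index=True)


def simulate_trials(
    model: EvokedSpectrumModel, n_trials: int, seed: int
) -> TrialDataset:
    """Draw a balanced set of trials from the generative model.

    Labels alternate ``+1, -1, ...`` (exactly balanced, equiprobable-prior
    design).  Per band the residual is a single complex Gaussian draw
    ``eps = N(0, Sigma) + i N(0, Sigma)`` per trial, rotated around the epoch
    as ``Re(eps * exp(i w t))`` — stationary narrowband noise with random
    phase and fixed within-trial amplitude.  Induced condition effects scale
    ``eps`` by the per-condition factor.
    """
    n_trials = int(n_trials)
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    if n_trials % 2:
        raise ValueError("n_trials must be even (balanced design)")

    rng = np.random.default_rng(seed)
    labels = np.tile([1, -1], n_trials // 2).astype(np.int8)
    t = model.time_s
    p = model.n_channels

    data = np.empty((n_trials, p, len(t)))
    for lab in (1, -1):
        data[labels == lab] = evoked_waveform(model, lab)[None]

    for f, cov in zip(model.freqs_hz, model.noise_cov):
        chol = np.linalg.cholesky(cov)
        eps_r = rng.standard_normal((n_trials, p)) @ chol.T
        eps_i = rng.standard_normal((n_trials, p)) @ chol.T
        sp, sm = model.induced_scales(f)
        scale = np.where(labels == 1, sp, sm)[:, None]
        eps_r *= scale
        eps_i *= scale
        ang = TWO_PI * f * t
        data += eps_r[:, :, None] * np.cos(ang) - eps_i[:, :, None] * np.sin(ang)

    meta = {"model": model.to_config(), "seed": int(seed), "n_trials": n_trials}
    return TrialDataset(
        data=data,
        labels=labels,
        sample_rate_hz=model.sample_rate_hz,
        time_s=t,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# persistence: HDF5 container + JSON metadata sidecar

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_dataset(dataset: TrialDataset, path) -> None:
    """Write a dataset to an HDF5 container with a JSON metadata sidecar."""
    path = Path(path)
    with h5py.File(path, "w") as h5:
        h5.create_dataset("data", data=dataset.data.astype(np.float64))
        h5.create_dataset("labels", data=dataset.labels.astype(np.int8))
        h5.create_dataset("time_s", data=dataset.time_s.astype(np.float64))
        h5.attrs["sample_rate_hz"] = float(dataset.sample_rate_hz)
    _sidecar_path(path).write_text(json.dumps(dataset.meta, indent=2, default=float))


def read_dataset(path) -> TrialDataset:
    """Read a dataset written by :func:`write_dataset` (lossless round trip)."""
    path = Path(path)
    with h5py.File(path, "r") as h5:
        for name in ("data", "labels", "time_s"):
            if name not in h5:
                raise DatasetFormatError(f"container is missing dataset '{name}'")
        if "sample_rate_hz" not in h5.attrs:
            raise DatasetFormatError("container is missing attribute 'sample_rate_hz'")
        data = h5["data"][()]
        labels = h5["labels"][()]
        time_s = h5["time_s"][()]
        fs = float(h5.attrs["sample_rate_hz"])
    sidecar = _sidecar_path(path)
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return TrialDataset(
        data=data, labels=labels, sample_rate_hz=fs, time_s=time_s, meta=meta
    )
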