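import numpy as np
import pytest

from repdyn import EvokedSpectrumModel, example1_model, example2_model


def random_model(
    rng: np.random.Generator,
    n_channels: int = 3,
    n_bands: int = 2,
    freq_choices=None,
    sample_rate_hz: float = 1000.0,
    epoch_length_s: float = 0.5,
    amp_scale: float = 0.8,
) -> EvokedSpectrumModel:
    """Random model with SPD band covariances and moderate separations.

    Frequencies are drawn as integer multiples of 2 Hz so that every
    information harmonic completes an integer number of cycles over the
    0.5 s epoch (exact FFT bins).
    """
    if freq_choices is None:
        freq_choices = 2.0 * np.arange(1, 25)
    freqs = rng.choice(freq_choices, size=n_bands, replace=False)
    amps = rng.uniform(0.1, amp_scale, size=(n_bands, n_channels))
    phases = rng.uniform(0, 2 * np.pi, size=(n_bands, n_channels))
    covs = []
    for _ in range(n_bands):
        a = rng.standard_normal((n_channels, n_channels))
        covs.append(a @ a.T + n_channels * np.eye(n_channels))
    return EvokedSpectrumModel(
        n_channels=n_channels,
        sample_rate_hz=sample_rate_hz,
        epoch_length_s=epoch_length_s,
        freqs_hz=np.sort(freqs),
        amplitudes=amps,
        phases=phases,
        noise_cov=np.stack(covs),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def model1():
    """Canonical single 10 Hz component model (c = r = 2)."""
    return example1_model()


@pytest.fixture
def model2():
    """Canonical 10 + 15 Hz model with 20% condition contrast."""
    return example2_model()
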