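"""Analytic information content and its Monte-Carlo oracle."""

import numpy as np
import pytest

from repdyn import (
    broadband_info_timecourse,
    broadband_separation,
    complex_info_timecourse,
    complex_separation,
    dominant_frequency,
    induced_info_probe,
    link_accuracy,
    link_distance,
    link_mi,
    mc_mi_estimate,
    narrowband_info_timecourse,
    separation_params,
)
from repdyn.evoked_model import EvokedSpectrumModel, class_mean_difference
from tests.conftest import random_model

TWO_PI = 2 * np.pi


def direct_separation(model, time_s, band=None):
    """Brute-force squared Mahalanobis separation, straight from the model
    definition (independent of the product-to-sum expansion)."""
    if band is None:
        delta = class_mean_difference(model)
        if not np.array_equal(time_s, model.time_s):
            delta = np.zeros((model.n_channels, len(time_s)))
            for f, a, phi in zip(model.freqs_hz, model.amplitudes, model.phases):
                delta += 2 * a[:, None] * np.cos(TWO_PI * f * time_s + phi[:, None])
        cov = model.noise_cov.sum(axis=0)
    else:
        idx = model.band_index(band)
        f, a, phi = model.freqs_hz[idx], model.amplitudes[idx], model.phases[idx]
        delta = 2 * a[:, None] * np.cos(TWO_PI * f * time_s + phi[:, None])
        cov = model.noise_cov[idx]
    q = np.linalg.inv(cov)
    return np.einsum("ct,cd,dt->t", delta, q, delta)


class TestSeparationParams:
    def test_null_band(self, model1):
        model1.amplitudes[:] = 0.0
        p = separation_params(model1, 10.0)
        assert p.c == 0.0 and p.r == 0.0

    def test_single_channel_hand_expansion(self):
        # one channel, amplitude a, phase 0, unit variance:
        # d2(t) = 4 a^2 cos^2(wt) = 2a^2 + 2a^2 cos(2wt)
        a = 0.6
        model = EvokedSpectrumModel(
            n_channels=1, sample_rate_hz=100, epoch_length_s=0.5,
            freqs_hz=[10.0], amplitudes=[[a]], phases=[[0.0]],
            noise_cov=np.eye(1)[None],
        )
        p = separation_params(model, 10.0)
        assert p.c == pytest.approx(2 * a * a, abs=1e-12)
        assert p.r == pytest.approx(2 * a * a, abs=1e-12)

    def test_matches_brute_force(self, rng):
        t = np.linspace(0, 0.5, 1000)
        for _ in range(5):
            model = random_model(rng, n_channels=3, n_bands=1)
            band = float(model.freqs_hz[0])
            p = separation_params(model, band)
            np.testing.assert_allclose(
                p.evaluate(t), direct_separation(model, t, band), atol=1e-10
            )

    def test_unknown_band_rejected(self, model1):
        with pytest.raises(ValueError):
            separation_params(model1, 11.0)

    def test_modulation_never_exceeds_mean(self, rng):
        # r <= c so the squared separation is non-negative at every t
        for _ in range(20):
            model = random_model(rng, n_channels=4, n_bands=1)
            p = separation_params(model, float(model.freqs_hz[0]))
            assert p.r <= p.c + 1e-12


class TestBroadbandSeparation:
    def test_single_band_degenerates_to_narrowband(self, model1):
        bb = broadband_separation(model1)
        nb = separation_params(model1, 10.0)
        assert bb.c == pytest.approx(nb.c)
        t = model1.time_s
        np.testing.assert_allclose(bb.evaluate(t), nb.evaluate(t), atol=1e-12)

    def test_harmonic_set_10_15(self, model2):
        harmonics = broadband_separation(model2).harmonic_freqs_hz
        np.testing.assert_allclose(harmonics, [5.0, 20.0, 25.0, 30.0])

    def test_matches_brute_force(self, rng):
        t = np.linspace(0, 0.5, 1000)
        for _ in range(5):
            model = random_model(rng, n_channels=3, n_bands=2)
            bb = broadband_separation(model)
            np.testing.assert_allclose(
                bb.evaluate(t), direct_separation(model, t), atol=1e-10
            )

    def test_highest_harmonic_is_twice_bandwidth(self, rng):
        for _ in range(10):
            model = random_model(rng, n_channels=2, n_bands=3)
            bb = broadband_separation(model)
            assert bb.harmonic_freqs_hz.max() == pytest.approx(
                2 * model.max_freq_hz
            )


class TestLinks:
    def test_anchors(self):
        assert link_mi(0.0) == 0.0
        assert link_mi(1e6) == pytest.approx(1.0, abs=1e-6)
        assert link_accuracy(0.0) == 0.5
        assert link_accuracy(1e6) == pytest.approx(1.0, abs=1e-9)

    def test_negative_rejected(self):
        for fn in (link_mi, link_accuracy, link_distance):
            with pytest.raises(ValueError):
                fn(-0.5)

    def test_gauss_hermite_matches_adaptive_quadrature(self):
        from repdyn.infotheory import _mi_scalar

        for sep in [1e-4, 0.03, 0.5, 1.0, 4.0, 10.0, 40.0, 200.0]:
            assert link_mi(sep) == pytest.approx(_mi_scalar(sep), abs=1e-8)

    def test_mi_against_frozen_monte_carlo(self):
        # 10^6-sample plug-in estimate at separation 4 (seed 12345):
        # 0.48593 +/- 0.00033
        assert abs(link_mi(4.0) - 0.48593) < 3 * 0.00033

    def test_accuracy_against_bayes_simulation(self, rng):
        # empirical Bayes-rule accuracy at separation 1 on 10^6 draws
        n = 1_000_000
        x = rng.normal(0.5, 1.0, size=n)  # class +1 projections, d = 1
        emp = (x > 0).mean()
        se = np.sqrt(emp * (1 - emp) / n)
        assert abs(link_accuracy(1.0) - emp) < 3 * se

    def test_monotone_and_concave(self):
        grid = np.linspace(0.0, 25.0, 200)
        mi = link_mi(grid)
        acc = link_accuracy(grid)
        dist = link_distance(grid)
        assert np.all(np.diff(mi) > 0)
        assert np.all(np.diff(acc) > 0)
        assert np.all(np.diff(dist) > 0)
        assert np.all(np.diff(mi, 2) < 1e-12)  # concavity of the MI link


class TestTimecourses:
    def test_narrowband_composition(self, rng):
        model = random_model(rng, n_channels=3, n_bands=1)
        band = float(model.freqs_hz[0])
        tc = narrowband_info_timecourse(model, band)
        expect = link_mi(direct_separation(model, model.time_s, band))
        np.testing.assert_allclose(tc.value, expect, atol=1e-8)

    def test_narrowband_dominant_frequency_is_doubled(self, model1):
        tc = narrowband_info_timecourse(model1, 10.0)
        assert dominant_frequency(tc.value, model1.sample_rate_hz) == 20.0

    def test_narrowband_spectrum_single_line(self, rng):
        # the squared separation has a single nonzero-frequency line at 2w
        from repdyn import power_spectrum

        for _ in range(10):
            model = random_model(rng, n_channels=3, n_bands=1)
            band = float(model.freqs_hz[0])
            p = separation_params(model, band)
            t = model.time_s
            f, pw = power_spectrum(p.evaluate(t), model.sample_rate_hz)
            nz = f[pw > 1e-9 * pw.max()]
            np.testing.assert_allclose(nz[nz > 0], [2 * band])

    def test_zero_amplitude_flat_zero(self, model1):
        model1.amplitudes[:] = 0.0
        tc = narrowband_info_timecourse(model1, 10.0)
        np.testing.assert_array_equal(tc.value, 0.0)

    def test_broadband_single_band_equals_narrowband(self, model1):
        bb = broadband_info_timecourse(model1)
        nb = narrowband_info_timecourse(model1, 10.0)
        np.testing.assert_allclose(bb.value, nb.value, atol=1e-12)

    def test_broadband_support_bounded_by_twice_bandwidth(self, rng):
        # supported spectrum (1% of peak rule) never extends beyond 2*Omega
        from repdyn import power_spectrum
        from repdyn.scenarios import support_edge_hz

        for _ in range(50):
            model = random_model(rng, n_channels=2, n_bands=2)
            tc = broadband_info_timecourse(model)
            f, pw = power_spectrum(tc.value, model.sample_rate_hz)
            assert support_edge_hz(f, pw) <= 2 * model.max_freq_hz + 1e-9

    def test_complex_constant_and_dominates_narrowband(self, rng):
        for _ in range(20):
            model = random_model(rng, n_channels=3, n_bands=1)
            band = float(model.freqs_hz[0])
            cx = complex_info_timecourse(model, band)
            nb = narrowband_info_timecourse(model, band)
            assert np.var(cx.value) < 1e-20
            assert cx.value[0] >= nb.value.max() - 1e-12

    def test_complex_equality_when_fully_modulated(self, model1):
        # c = r for the canonical model, so link(2c) = link(c + r)
        p = separation_params(model1, 10.0)
        assert p.c == pytest.approx(p.r)
        cx = complex_info_timecourse(model1, 10.0)
        nb = narrowband_info_timecourse(model1, 10.0, time_s=np.array([0.0]))
        assert cx.value[0] == pytest.approx(nb.value[0], abs=1e-12)

    def test_metric_dispatch(self, model1):
        acc = narrowband_info_timecourse(
            model1, 10.0, metric="classification_accuracy"
        )
        assert np.all(acc.value >= 0.5) and np.all(acc.value <= 1.0)
        with pytest.raises(ValueError):
            narrowband_info_timecourse(model1, 10.0, metric="f1")


class TestMonteCarloOracle:
    def test_zero_amplitude_estimates_zero(self, model1):
        model1.amplitudes[:] = 0.0
        est = mc_mi_estimate(model1, 0.1, "broadband", 20_000, seed=0)
        assert abs(est.value) <= 3 * max(est.se, 1e-12)

    def test_narrowband_trough_is_zero(self, model1):
        # c = r: the trough of c + r cos(2wt + xi) is exactly zero
        est = mc_mi_estimate(
            model1, 0.025, "narrowband", 20_000, seed=1, band_hz=10.0
        )
        assert abs(est.value) <= 3 * max(est.se, 1e-12)

    def test_complex_scope_time_invariant(self, model1):
        e1 = mc_mi_estimate(model1, 0.013, "complex", 50_000, seed=2, band_hz=10.0)
        e2 = mc_mi_estimate(model1, 0.437, "complex", 50_000, seed=3, band_hz=10.0)
        assert abs(e1.value - e2.value) <= 3 * np.hypot(e1.se, e2.se)

    def test_matches_analytic_all_scopes(self, rng):
        model = random_model(rng, n_channels=2, n_bands=2)
        band = float(model.freqs_hz[-1])
        t = float(rng.uniform(0, 0.5))
        checks = [
            ("broadband", None, link_mi(direct_separation(model, np.array([t]))[0])),
            ("narrowband", band,
             link_mi(direct_separation(model, np.array([t]), band)[0])),
            ("complex", band, link_mi(complex_separation(model, band))),
        ]
        for scope, b, expect in checks:
            est = mc_mi_estimate(model, t, scope, 100_000, seed=7, band_hz=b)
            assert abs(est.value - expect) <= 3 * est.se, scope

    def test_small_sample_rejected(self, model1):
        with pytest.raises(ValueError):
            mc_mi_estimate(model1, 0.0, "broadband", 100, seed=0)

    def test_unknown_scope_rejected(self, model1):
        with pytest.raises(ValueError):
            mc_mi_estimate(model1, 0.0, "wavelet", 20_000, seed=0)


class TestInducedProbes:
    def make_induced(self, scales, amplitudes=0.0):
        model = EvokedSpectrumModel(
            n_channels=2, sample_rate_hz=100, epoch_length_s=0.5,
            freqs_hz=[10.0], amplitudes=np.full((1, 2), amplitudes),
            phases=np.zeros((1, 2)), noise_cov=np.eye(2)[None],
            induced={10.0: scales},
        )
        return model

    def test_no_contrast_gives_zero(self):
        model = self.make_induced((1.0, 1.0), amplitudes=0.0)
        est = induced_info_probe(model, 0.2, "narrowband", 20_000, seed=0,
                                 band_hz=10.0)
        assert abs(est.value) <= 3 * max(est.se, 1e-12)

    def test_induced_only_time_invariant(self):
        # two timepoints half an information-period apart
        model = self.make_induced((1.8, 1.0), amplitudes=0.0)
        e1 = induced_info_probe(model, 0.10, "narrowband", 50_000, seed=1,
                                band_hz=10.0)
        e2 = induced_info_probe(model, 0.125, "narrowband", 50_000, seed=2,
                                band_hz=10.0)
        assert e1.value > 5 * e1.se  # the contrast is detectable
        assert abs(e1.value - e2.value) <= 3 * np.hypot(e1.se, e2.se)

    def test_subadditive_against_isolated_effects(self):
        # evoked + induced information does not exceed the sum of the two
        # effects assessed independently, at several probe timepoints
        both = self.make_induced((1.8, 1.0), amplitudes=0.5)
        evoked_only = self.make_induced((1.0, 1.0), amplitudes=0.5)
        induced_only = self.make_induced((1.8, 1.0), amplitudes=0.0)
        for i, t in enumerate([0.0, 0.012, 0.10, 0.31]):
            eb = induced_info_probe(both, t, "narrowband", 50_000,
                                    seed=10 + i, band_hz=10.0)
            ee = induced_info_probe(evoked_only, t, "narrowband", 50_000,
                                    seed=20 + i, band_hz=10.0)
            ei = induced_info_probe(induced_only, t, "narrowband", 50_000,
                                    seed=30 + i, band_hz=10.0)
            bound = ee.value + ei.value
            se = np.sqrt(eb.se**2 + ee.se**2 + ei.se**2)
            assert eb.value <= bound + 3 * se
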