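"""Temporal and spectral descriptors: analytic cases and invariances."""

import numpy as np
import pytest

from ehgkit.features_linear import (
    FeatureError,
    SpectralEstimate,
    dominant_frequency,
    estimate_psd,
    hl_ratio,
    mean_frequency,
    normalized_energies,
    peak_to_peak,
    spectral_features,
    spectral_moment_ratio,
    spectrum_deciles,
    teager_energy,
)

FS = 20.0


def sine(freq, n=2400, amp=1.0, fs=FS, phase=0.0):
    return amp * np.sin(2 * np.pi * freq * np.arange(n) / fs + phase)


def line_spectrum(freqs_powers, df=0.01, fmax=10.0):
    """A synthetic PSD with discrete lines (one bin per line)."""
    f = np.arange(0.0, fmax, df)
    p = np.zeros_like(f)
    for f0, pw in freqs_powers:
        p[int(round(f0 / df))] = pw / df
    return SpectralEstimate(freqs=f, psd=p)


class TestPeakToPeak:
    @pytest.mark.parametrize(
        "x, expected",
        [
            (np.full(50, 0.3), 0.0),
            (np.array([-1.2, 0.4, 3.1]), 4.3),
        ],
    )
    def test_cases(self, x, expected):
        assert peak_to_peak(x) == pytest.approx(expected)

    def test_unit_sine(self):
        assert peak_to_peak(sine(0.5)) == pytest.approx(2.0, abs=1e-3)

    def test_empty_errors(self):
        with pytest.raises(FeatureError):
            peak_to_peak([])


class TestTeager:
    def test_sine_identity(self):
        # psi[n] = A^2 sin^2(w) exactly, for every interior sample
        a, f = 0.7, 0.31
        w = 2 * np.pi * f / FS
        assert teager_energy(sine(f, amp=a)) == pytest.approx(
            a**2 * np.sin(w) ** 2, rel=1e-9
        )

    def test_constant_is_zero(self):
        assert teager_energy(np.full(100, 2.5)) == pytest.approx(0.0)

    def test_ramp_is_one(self):
        assert teager_energy(np.arange(500, dtype=float)) == pytest.approx(1.0)

    def test_too_short_errors(self):
        with pytest.raises(FeatureError):
            teager_energy([1.0, 2.0])


class TestEstimatePsd:
    def test_white_noise_parseval(self, rng):
        x = rng.standard_normal(2400)
        spec = estimate_psd(x, FS)
        power = np.sum(spec.psd) * (spec.freqs[1] - spec.freqs[0])
        assert power == pytest.approx(np.var(x), rel=0.05)

    def test_sine_peak_location(self):
        spec = estimate_psd(sine(0.5), FS)
        assert spec.freqs[np.argmax(spec.psd)] == pytest.approx(0.5, abs=0.02)

    def test_two_tone_power_ratio(self, rng):
        x = sine(0.3) + sine(0.7, phase=1.0)
        spec = estimate_psd(x, FS)
        p03 = spec.band_power(0.25, 0.35)
        p07 = spec.band_power(0.65, 0.75)
        assert p03 / p07 == pytest.approx(1.0, abs=0.1)

    def test_wrong_length_errors(self):
        with pytest.raises(ValueError):
            estimate_psd(np.zeros(100), FS)


class TestMeanFrequency:
    def test_single_line(self):
        spec = line_spectrum([(0.5, 1.0)])
        assert mean_frequency(spec) == pytest.approx(0.5)

    def test_flat_band_midpoint(self):
        f = np.arange(0, 10, 0.01)
        spec = SpectralEstimate(f, np.ones_like(f))
        assert mean_frequency(spec, (0.1, 1.0)) == pytest.approx(0.55, abs=0.02)

    def test_two_equal_lines(self):
        spec = line_spectrum([(0.3, 1.0), (0.7, 1.0)])
        assert mean_frequency(spec) == pytest.approx(0.5, abs=0.02)

    def test_zero_power_errors(self):
        f = np.arange(0, 10, 0.01)
        spec = SpectralEstimate(f, np.zeros_like(f))
        with pytest.raises(FeatureError):
            mean_frequency(spec)


class TestDominantFrequency:
    def test_single_line_both_bands(self):
        spec = line_spectrum([(0.45, 1.0)])
        assert dominant_frequency(spec, (0.2, 1.0)) == pytest.approx(0.45, abs=0.01)
        assert dominant_frequency(spec, (0.34, 1.0)) == pytest.approx(0.45, abs=0.01)

    def test_band_dependent_maximum(self):
        spec = line_spectrum([(0.25, 1.0), (0.5, 0.5)])
        assert dominant_frequency(spec, (0.2, 1.0)) == pytest.approx(0.25, abs=0.01)
        assert dominant_frequency(spec, (0.34, 1.0)) == pytest.approx(0.5, abs=0.01)

    def test_ar2_resonance(self, rng):
        # AR(2) with poles at radius 0.97, angle 2*pi*0.4/20: spectral peak
        # near 0.4 Hz; long signal for a stable estimate
        w = 2 * np.pi * 0.4 / FS
        a1, a2 = 2 * 0.97 * np.cos(w), -(0.97**2)
        e = rng.standard_normal(120000)
        x = np.zeros_like(e)
        for n in range(2, e.size):
            x[n] = a1 * x[n - 1] + a2 * x[n - 2] + e[n]
        spec = estimate_psd(x, FS, expected_length=None)
        df = spec.freqs[1] - spec.freqs[0]
        assert dominant_frequency(spec, (0.2, 1.0)) == pytest.approx(
            0.4, abs=2 * df + 1e-9
        )


class TestDeciles:
    def test_flat_band(self):
        f = np.arange(0, 10, 0.001)
        spec = SpectralEstimate(f, np.ones_like(f))
        d = spectrum_deciles(spec)
        expected = 0.34 + np.arange(1, 10) * 0.066
        assert np.allclose(d, expected, atol=0.002)

    def test_single_line(self):
        spec = line_spectrum([(0.6, 1.0)])
        assert np.allclose(spectrum_deciles(spec), 0.6)

    def test_step_mass(self):
        spec = line_spectrum([(0.4, 1.0), (0.8, 1.0)])
        d = spectrum_deciles(spec)
        assert np.allclose(d[:5], 0.4) and np.allclose(d[5:], 0.8)

    def test_monotone_and_median_equivalence_fuzz(self, rng):
        # d1 <= ... <= d9 and d5 splits in-band power in half, for random PSDs
        f = np.arange(0, 10, 0.01)
        for _ in range(25):
            spec = SpectralEstimate(f, rng.uniform(0, 1, f.size))
            d = spectrum_deciles(spec)
            assert np.all(np.diff(d) >= 0)
            mask = (f >= 0.34) & (f < 1.0)
            pf, pp = f[mask], spec.psd[mask]
            below = pp[pf <= d[4]].sum() / pp.sum()
            binw = pp[pf == d[4]].sum() / pp.sum()
            assert below >= 0.5 - 1e-9 and below - binw <= 0.5 + 1e-9


class TestNormalizedEnergies:
    def test_single_line_middle_band(self):
        spec = line_spectrum([(0.5, 1.0)])
        ne = normalized_energies(spec)
        assert ne[0] == pytest.approx(0.0)
        assert ne[1] == pytest.approx(1.0, abs=1e-9)
        assert ne[2] == pytest.approx(0.0)

    def test_flat_spectrum_bandwidth_ratios(self):
        f = np.arange(0, 10, 0.001)
        spec = SpectralEstimate(f, np.ones_like(f))
        ne = normalized_energies(spec)
        assert ne[0] == pytest.approx(0.14 / 3.9, rel=0.02)
        assert ne[1] == pytest.approx(0.26 / 3.9, rel=0.02)
        assert ne[2] == pytest.approx(0.4 / 3.9, rel=0.02)

    def test_fractions_sum_below_one(self, rng):
        f = np.arange(0, 10, 0.01)
        for _ in range(10):
            spec = SpectralEstimate(f, rng.uniform(0, 1, f.size))
            assert sum(normalized_energies(spec)) <= 1.0 + 1e-9


class TestHlRatio:
    def test_equal_lines(self):
        spec = line_spectrum([(0.25, 1.0), (0.5, 1.0)])
        assert hl_ratio(spec) == pytest.approx(1.0, rel=0.1)

    def test_flat_spectrum(self):
        f = np.arange(0, 10, 0.001)
        spec = SpectralEstimate(f, np.ones_like(f))
        assert hl_ratio(spec) == pytest.approx(0.66 / 0.14, rel=0.1)

    def test_zero_denominator_errors(self):
        spec = line_spectrum([(0.5, 1.0)])  # no power at all in 0.2-0.34
        with pytest.raises(FeatureError):
            hl_ratio(spec)


class TestSpectralMomentRatio:
    def test_line_at_one_hz(self):
        spec = line_spectrum([(1.0, 3.0)], fmax=10.0)
        # frequency grid: include 1.0 Hz inside the band via closed upper edge
        assert spectral_moment_ratio(spec, (0.1, 1.01)) == pytest.approx(1.0)

    def test_line_at_half_hz(self):
        spec = line_spectrum([(0.5, 2.0)])
        assert spectral_moment_ratio(spec) == pytest.approx(64.0)

    def test_monotone_under_shift(self):
        lo = spectral_moment_ratio(line_spectrum([(0.4, 1.0)]))
        hi = spectral_moment_ratio(line_spectrum([(0.6, 1.0)]))
        assert hi < lo


class TestScalingInvariance:
    def test_gain_affects_only_amplitude_features(self, rng):
        """Spectral shape features are gain-invariant; App scales as gain and
        Teager as gain^2."""
        x = rng.standard_normal(2400)
        f1 = spectral_features(x, FS)
        f2 = spectral_features(2.0 * x, FS)
        for name, v in f1.items():
            if name == "teager":
                assert f2[name] == pytest.approx(4.0 * v, rel=1e-9)
            else:
                assert f2[name] == pytest.approx(v, rel=1e-9)
        assert peak_to_peak(2.0 * x) == pytest.approx(2.0 * peak_to_peak(x))
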