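"""Non-linear descriptors: brute-force oracle equivalence, analytic limits
and band-sensitivity properties."""

import numpy as np
import pytest

from ehgkit.features_nonlinear import (
    EntropyConfig,
    FeatureError,
    fuzzy_entropy,
    katz_fd,
    lempel_ziv,
    lz76_complexity,
    poincare,
    sample_entropy,
    spectral_entropy,
    time_reversibility,
)
from ehgkit.preprocess import BANDS, bandpass
from oracles import fuzen_bruteforce, lz76_bruteforce, sampen_bruteforce

FS = 20.0


class TestSampleEntropy:
    def test_periodic_alternation_is_zero(self):
        # every length-2 match extends to length 3, so A = B and -ln(1) = 0
        x = np.tile([0.0, 1.0], 200)
        assert sample_entropy(x) == pytest.approx(0.0)

    def test_matches_bruteforce_oracle(self, rng):
        cfg = EntropyConfig()
        for _ in range(10):
            x = rng.standard_normal(300)
            expected = sampen_bruteforce(x, cfg.m, cfg.r_factor * np.std(x))
            assert sample_entropy(x, cfg) == pytest.approx(expected, rel=1e-10)

    def test_smoothing_reduces_entropy(self, rng):
        # low-pass filtering makes the series more regular in every trial
        from scipy.signal import sosfiltfilt, butter

        sos = butter(4, 0.05, output="sos")
        for _ in range(20):
            x = rng.standard_normal(400)
            assert sample_entropy(sosfiltfilt(sos, x)) < sample_entropy(x)

    def test_constant_signal_errors(self):
        with pytest.raises(FeatureError):
            sample_entropy(np.ones(200))


class TestFuzzyEntropy:
    def test_matches_bruteforce_oracle(self, rng):
        cfg = EntropyConfig()
        for _ in range(10):
            x = rng.standard_normal(500)
            expected = fuzen_bruteforce(x, cfg.m, cfg.r_factor * np.std(x), 2.0)
            assert fuzzy_entropy(x, cfg) == pytest.approx(expected, rel=1e-8)

    def test_offset_invariance(self, rng):
        x = rng.standard_normal(300)
        assert fuzzy_entropy(x + 5.0) == pytest.approx(fuzzy_entropy(x), rel=1e-12)

    def test_constant_signal_is_zero(self):
        assert fuzzy_entropy(np.full(200, 3.3)) == 0.0


class TestSpectralEntropy:
    def test_pure_tone_near_zero(self):
        x = np.sin(2 * np.pi * 0.5 * np.arange(2400) / FS)
        assert spectral_entropy(x, FS, (0.1, 4.0)) < 0.25

    def test_white_noise_near_one(self, rng):
        x = rng.standard_normal(2400)
        assert spectral_entropy(x, FS, (0.1, 4.0)) >= 0.95

    def test_bounded_fuzz(self, rng):
        for _ in range(10):
            x = rng.standard_normal(600) * rng.uniform(0.1, 10)
            v = spectral_entropy(x, FS, (0.1, 4.0))
            assert 0.0 <= v <= 1.0


class TestLempelZiv:
    def test_textbook_parse_count(self):
        # classic 16-symbol example; exhaustive parse has 6 phrases
        assert lz76_complexity("0001101001000101") == 6
        assert lz76_bruteforce("0001101001000101") == 6

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(20):
            n_states = int(rng.choice([2, 6]))
            s = rng.integers(0, n_states, size=int(rng.integers(50, 500)))
            assert lz76_complexity(s) == lz76_bruteforce(s)

    def test_periodic_normalized_complexity_vanishes(self):
        # alternating symbols: phrase count stays O(1) so C -> 0 with N
        values = []
        for n in (100, 600, 2400):
            x = np.tile([0.0, 1e-3], n // 2) + np.linspace(0, 0, n)
            values.append(lempel_ziv(x, 2))
        assert values[0] > values[1] > values[2]
        assert values[-1] < 0.1

    def test_iid_complexity_near_one(self, rng):
        x = rng.standard_normal(2400)
        assert lempel_ziv(x, 2) == pytest.approx(1.0, abs=0.15)
        assert lempel_ziv(x, 6) == pytest.approx(1.0, abs=0.15)

    def test_constant_errors(self):
        with pytest.raises(FeatureError):
            lempel_ziv(np.ones(100), 2)


class TestTimeReversibility:
    def test_ramp_cubed_step(self):
        c = 0.7
        x = np.arange(200) * c
        assert time_reversibility(x) == pytest.approx(c**3, rel=1e-12)

    def test_sine_full_periods_zero(self):
        # 2001 samples -> the 2000 lag-1 differences cover 20 whole periods
        x = np.sin(2 * np.pi * np.arange(2001) / 100)
        assert time_reversibility(x) == pytest.approx(0.0, abs=1e-9)

    def test_sign_flip_antisymmetry(self, rng):
        x = rng.standard_normal(500) ** 3
        assert time_reversibility(-x) == pytest.approx(-time_reversibility(x))


class TestKatzFd:
    def test_straight_line_is_one(self):
        for slope in (0.0, 0.5, -3.0):
            x = slope * np.arange(100) + 1.0
            if slope == 0.0:
                with pytest.raises(FeatureError):
                    katz_fd(x)  # constant: zero extent
            else:
                assert katz_fd(x) == pytest.approx(1.0, rel=1e-12)

    def test_two_points(self):
        assert katz_fd([0.0, 1.0]) == 1.0

    def test_noise_rougher_than_walk(self, rng):
        for _ in range(20):
            x = rng.standard_normal(400)
            assert katz_fd(x) > katz_fd(np.cumsum(x))


class TestPoincare:
    def test_ramp_sd1_zero(self):
        pc = poincare(np.arange(100, dtype=float))
        assert pc.sd1 == pytest.approx(0.0)
        assert pc.sd_ratio == pytest.approx(0.0)

    def test_iid_ratio_near_one(self, rng):
        pc = poincare(rng.standard_normal(2400))
        assert pc.sd_ratio == pytest.approx(1.0, abs=0.1)

    def test_sdrr_identity_fuzz(self, rng):
        for _ in range(20):
            pc = poincare(rng.standard_normal(100))
            assert pc.sdrr**2 == pytest.approx((pc.sd1**2 + pc.sd2**2) / 2)


class TestBandComplementarity:
    def test_fwl_burst_raises_fwl_not_fwh1_features(self, rng):
        """A 0.25 Hz component inflates low-band amplitude but leaves the
        0.34-1 Hz band essentially untouched (no band-ignoring bug)."""
        noise = 0.05 * rng.standard_normal(4800)
        burst = np.sin(2 * np.pi * 0.25 * np.arange(4800) / FS)
        base_fwl = np.ptp(bandpass(noise, FS, BANDS["fwl"]))
        base_fwh1 = np.ptp(bandpass(noise, FS, BANDS["fwh1"]))
        with_fwl = np.ptp(bandpass(noise + burst, FS, BANDS["fwl"]))
        with_fwh1 = np.ptp(bandpass(noise + burst, FS, BANDS["fwh1"]))
        assert with_fwl > 5 * base_fwl
        assert with_fwh1 < 2 * base_fwh1
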