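import numpy as np
import pytest
from scipy import stats as sstats

from febci.evaluation_stats import (anova_power, anova_sample_size,
                                    band_power, chance_level,
                                    classify_effect_size, correlation_map,
                                    one_way_anova, spectrum, time_frequency)


class TestChanceLevel:
    @pytest.mark.parametrize("n,expected", [(240, 29.58), (60, 35.0),
                                            (4320, 26.09)])
    def test_published_four_class_values(self, n, expected):
        assert chance_level(n, 4, 0.05) == pytest.approx(expected, abs=0.005)

    def test_decreasing_in_trials_toward_asymptote(self):
        values = [chance_level(n, 4) for n in (60, 240, 1000, 10 ** 6)]
        assert all(a > b for a, b in zip(values, values[1:]))
        assert values[-1] < 25.2

    def test_invalid_query_rejected(self):
        with pytest.raises(ValueError):
            chance_level(0, 4)
        with pytest.raises(ValueError):
            chance_level(60, 4, alpha=1.5)


class TestOneWayAnova:
    def test_identical_groups_zero_f(self):
        res = one_way_anova([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert res.F == 0.0 and res.cohens_f == 0.0

    def test_matches_sums_of_squares_oracle(self):
        """Direct SS decomposition oracle on a worked example."""
        groups = [np.array([1.0, 2, 3]), np.array([2.0, 3, 4]),
                  np.array([6.0, 7, 8])]
        res = one_way_anova(groups)
        # independent oracle: scipy's F and p, and SS arithmetic for eta2
        F_sp, p_sp = sstats.f_oneway(*groups)
        assert res.F == pytest.approx(F_sp, abs=1e-10)
        assert res.p == pytest.approx(p_sp, abs=1e-10)
        grand = np.concatenate(groups).mean()
        ssb = sum(3 * (g.mean() - grand) ** 2 for g in groups)
        sst = ((np.concatenate(groups) - grand) ** 2).sum()
        eta2 = ssb / sst
        assert res.eta_squared == pytest.approx(eta2, abs=1e-10)
        assert res.cohens_f == pytest.approx(np.sqrt(eta2 / (1 - eta2)),
                                             abs=1e-10)

    def test_effect_size_benchmarks(self):
        assert classify_effect_size(0.45) == "large"
        assert classify_effect_size(0.30) == "medium"
        assert classify_effect_size(0.12) == "small"

    def test_constant_shift_invariance(self, rng):
        groups = [rng.standard_normal(8) for _ in range(3)]
        shifted = [g + 100.0 for g in groups]
        assert one_way_anova(groups).F == pytest.approx(
            one_way_anova(shifted).F, rel=1e-9)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova([[1, 1], [1, 1]])


class TestAnovaSampleSize:
    def test_monotone_in_effect_size(self):
        n_small = anova_sample_size(0.4, 0.05, 0.8, 4)
        n_large = anova_sample_size(0.9, 0.05, 0.8, 4)
        assert n_small >= n_large

    @pytest.mark.parametrize("f", [0.4, 0.9])
    def test_matches_noncentral_f_power_oracle(self, f):
        """The returned N is the smallest with power >= 0.8 under an
        independent statsmodels noncentral-F power computation."""
        from statsmodels.stats.power import FTestAnovaPower

        n = anova_sample_size(f, 0.05, 0.8, 4)
        solver = FTestAnovaPower()
        assert solver.power(f, n, 0.05, k_groups=4) >= 0.8
        assert solver.power(f, n - 1, 0.05, k_groups=4) < 0.8

    def test_power_function_consistency(self):
        n = anova_sample_size(0.4, 0.05, 0.8, 4)
        assert anova_power(0.4, n, 4) >= 0.8
        assert anova_power(0.4, n - 1, 4) < 0.8

    def test_invalid_query(self):
        with pytest.raises(ValueError):
            anova_sample_size(0.0)


class TestCorrelationMap:
    def test_identical_waveforms_unit_correlation(self, rng):
        w = rng.standard_normal((4, 100))
        out = correlation_map({"FB": w, "RB": w.copy()})
        np.testing.assert_allclose(out[("FB", "RB")], 1.0, atol=1e-12)

    def test_sign_flip_anticorrelated(self, rng):
        w = rng.standard_normal((4, 100))
        out = correlation_map({"FB": w, "RB": -w})
        np.testing.assert_allclose(out[("FB", "RB")], -1.0, atol=1e-12)

    def test_matches_covariance_oracle(self, rng):
        a, b = rng.standard_normal((2, 4, 64))
        out = correlation_map({"LS": a, "RS": b})
        for c in range(4):
            oracle = np.cov(a[c], b[c])[0, 1] / (a[c].std(ddof=1)
                                                 * b[c].std(ddof=1))
            assert out[("LS", "RS")][c] == pytest.approx(oracle, abs=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            correlation_map({"FB": rng.standard_normal((4, 10)),
                             "RB": rng.standard_normal((4, 12))})


class TestSpectralDiagnostics:
    def test_periodogram_peak_at_sine_frequency(self):
        fs, t = 250.0, np.arange(1000) / 250.0
        f, p = spectrum(np.sin(2 * np.pi * 10 * t), fs)
        assert f[np.argmax(p)] == pytest.approx(10, abs=0.3)

    def test_parseval(self, rng):
        """Periodogram total power equals time-domain mean square."""
        x = rng.standard_normal(1024)
        _, p = spectrum(x, 250.0)
        assert p.sum() == pytest.approx(np.mean(x ** 2), rel=1e-9)

    def test_band_power_splits_total(self, rng):
        x = rng.standard_normal(1000)
        total = band_power(x, 250, 0, 126)
        assert band_power(x, 250, 0, 30) + band_power(x, 250, 30, 126) \
            == pytest.approx(total, rel=1e-9)

    def test_spectrogram_frame_count(self):
        fs = 250.0
        x = np.sin(2 * np.pi * 10 * np.arange(1000) / fs)
        f, t, S = time_frequency(x, fs, window_s=0.5, overlap_frac=0.9)
        nper, hop = 125, 125 - 112
        expected = (1000 - nper) // hop + 1
        assert S.shape == (nper // 2 + 1, expected)

    def test_window_too_long_rejected(self):
        with pytest.raises(ValueError):
            time_frequency(np.zeros(100), 250.0, window_s=1.0)
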