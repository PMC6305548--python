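import numpy as np
import pytest

from febci.namemd import (NAMEMDConfig, add_noise_channels,
                          hammersley_directions, mean_frequency, memd,
                          namemd_decompose)


class TestHammersleyDirections:
    @pytest.mark.parametrize("K,dim", [(4, 2), (16, 3), (64, 4), (64, 6)])
    def test_unit_norm(self, K, dim):
        d = hammersley_directions(K, dim)
        np.testing.assert_allclose(np.linalg.norm(d.vectors, axis=1), 1.0,
                                   atol=1e-12)

    def test_circle_points_distinct(self):
        d = hammersley_directions(4, 2)
        assert len({tuple(np.round(v, 9)) for v in d.vectors}) == 4

    def test_rejects_dim_below_2(self):
        with pytest.raises(ValueError):
            hammersley_directions(8, 1)

    def test_more_uniform_than_random(self, rng):
        """Monte-Carlo oracle: the minimum pairwise angle of the K=64
        dim=4 quasi-uniform set beats a same-size uniform-random set in
        >= 90% of trials."""

        def min_angle(V):
            g = np.clip(V @ V.T, -1, 1)
            np.fill_diagonal(g, -1)
            return np.arccos(g.max())  # smallest angle between any pair

        ours = min_angle(hammersley_directions(64, 4).vectors)
        wins = 0
        n_trials = 50
        for _ in range(n_trials):
            R = rng.standard_normal((64, 4))
            R /= np.linalg.norm(R, axis=1, keepdims=True)
            wins += ours > min_angle(R)
        assert wins >= 0.9 * n_trials


class TestAddNoiseChannels:
    def test_zero_noise_channels_identity(self, rng):
        y = rng.standard_normal((4, 256))
        out = add_noise_channels(y, NAMEMDConfig(n_noise_channels=0))
        np.testing.assert_array_equal(out, y)

    def test_channel_count(self, rng):
        y = rng.standard_normal((4, 256))
        out = add_noise_channels(y, NAMEMDConfig(n_noise_channels=2))
        assert out.shape == (6, 256)

    def test_noise_variance_matches_config(self, rng):
        """Sample-variance oracle: appended noise has the configured
        variance within 5% at T = 10,000."""
        y = rng.standard_normal((4, 10_000)) * 3.0
        cfg = NAMEMDConfig(n_noise_channels=2, noise_variance_ratio=0.02,
                           seed=5)
        out = add_noise_channels(y, cfg)
        target = 0.02 * y.var(axis=1).mean()
        for c in (4, 5):
            assert out[c].var() == pytest.approx(target, rel=0.05)

    def test_seeded_reproducibility(self, rng):
        y = rng.standard_normal((4, 256))
        cfg = NAMEMDConfig(seed=11)
        np.testing.assert_array_equal(add_noise_channels(y, cfg),
                                      add_noise_channels(y, cfg))


class TestDecomposition:
    def test_reconstruction_identity(self, rng):
        """Completeness: IMFs + residual reproduce the input to 1e-6
        relative max error for sines, mixtures and noise."""
        fs = 250.0
        t = np.arange(1000) / fs
        inputs = [
            np.vstack([np.sin(2 * np.pi * 5 * t)] * 4),
            np.vstack([np.sin(2 * np.pi * 2 * t) + np.sin(2 * np.pi * 20 * t),
                       np.cos(2 * np.pi * 9 * t),
                       rng.standard_normal(1000),
                       np.linspace(-1, 1, 1000)]),
            rng.standard_normal((4, 1000)),
        ]
        for y in inputs:
            s = namemd_decompose(y, NAMEMDConfig(seed=1), fs_hz=fs)
            err = np.abs(s.reconstruct_full() - y).max()
            assert err < 1e-6 * np.abs(y).max()

    def test_constant_input_reconstructs(self):
        y = np.full((4, 200), 2.5)
        s = namemd_decompose(y, NAMEMDConfig(seed=0), fs_hz=250.0)
        np.testing.assert_allclose(s.reconstruct_full(), y, atol=1e-9)

    def test_two_tone_separation(self):
        """FFT-argmax oracle: a 2 Hz + 20 Hz mixture puts 20 Hz in the
        first IMF and 2 Hz in a later one."""
        fs = 250.0
        t = np.arange(1000) / fs
        x = np.sin(2 * np.pi * 2 * t) + np.sin(2 * np.pi * 20 * t)
        imfs, _ = memd(np.vstack([x, x]), NAMEMDConfig(seed=0))

        def peak_hz(sig):
            spec = np.abs(np.fft.rfft(sig))
            return np.fft.rfftfreq(sig.size, 1 / fs)[np.argmax(spec)]

        assert peak_hz(imfs[0, 0]) == pytest.approx(20, abs=1.0)
        later = [peak_hz(imfs[j, 0]) for j in range(1, imfs.shape[0])]
        assert any(abs(p - 2) < 1.0 for p in later)

    def test_imf_alignment_across_channels(self, rng):
        """All channels share one IMF count (joint multivariate sifting)."""
        y = rng.standard_normal((4, 512))
        s = namemd_decompose(y, NAMEMDConfig(seed=2), fs_hz=250.0)
        assert s.imfs.shape[1] == 4
        assert s.residual.shape == (4, 512)

    def test_seeded_determinism(self, rng):
        y = rng.standard_normal((4, 400))
        a = namemd_decompose(y, NAMEMDConfig(seed=3), fs_hz=250.0)
        b = namemd_decompose(y, NAMEMDConfig(seed=3), fs_hz=250.0)
        assert a.n_imfs == b.n_imfs
        np.testing.assert_array_equal(a.imfs, b.imfs)

    def test_too_few_channels_rejected(self):
        with pytest.raises(ValueError):
            memd(np.zeros((1, 100)), NAMEMDConfig(n_noise_channels=0))

    def test_quasi_dyadic_filter_bank(self):
        """On white noise the mean frequencies of successive IMFs fall by
        roughly a factor of two (median ratio in [1.6, 2.6])."""
        rng = np.random.default_rng(77)
        ratios = []
        for trial in range(8):
            y = rng.standard_normal((4, 512))
            s = namemd_decompose(y, NAMEMDConfig(n_directions=32,
                                                 seed=trial), fs_hz=1.0)
            mf = [np.mean([mean_frequency(s.imfs[j, c], 1.0)
                           for c in range(4)]) for j in range(s.n_imfs)]
            ratios += [a / b for a, b in zip(mf[:-1], mf[1:]) if b > 0]
        assert 1.6 <= np.median(ratios) <= 2.6
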