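import numpy as np
import pytest

from febci.evaluation_stats import band_power
from febci.recording import CLASSES
from febci.signal_model import (ALPHA_BAND, DEFAULT_SIGNATURES, ClassSignature,
                                SyntheticConfig, generate_dataset,
                                generate_trial)


class TestClassSignature:
    def test_rejects_nonpositive_gains(self):
        with pytest.raises(ValueError):
            ClassSignature("FB", (1, 1, 0, 1), (1, 1, 1, 1))

    def test_rejects_wrong_channel_count(self):
        with pytest.raises(ValueError):
            ClassSignature("FB", (1, 1, 1), (1, 1, 1, 1))

    def test_default_table_covers_all_classes(self):
        assert set(DEFAULT_SIGNATURES) == set(CLASSES)


class TestGenerateTrial:
    def test_shape_and_event(self, timing, gen_config):
        rec = generate_trial("FB", timing=timing, config=gen_config, seed=3)
        assert rec.samples.shape == (4, int(timing.trial_s * gen_config.fs_hz))
        assert rec.events == [(int(timing.prep_s * gen_config.fs_hz),
                               "task:FB")]

    def test_unknown_class_rejected(self):
        with pytest.raises(KeyError):
            generate_trial("XX")

    def test_determinism(self, timing, gen_config):
        a = generate_trial("LS", timing=timing, config=gen_config, seed=7)
        b = generate_trial("LS", timing=timing, config=gen_config, seed=7)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_zero_emg_leaves_background_high_band(self, timing):
        """With emg_amp_uV = 0 the >30 Hz task power equals the
        background-only level (no EMG term is added)."""
        cfg0 = SyntheticConfig(emg_amp_uV=0.0)
        pows = {"task": [], "rest": []}
        for seed in range(8):
            rec = generate_trial("RB", timing=timing, config=cfg0, seed=seed)
            fs = cfg0.fs_hz
            i0, i1 = int(2 * fs), int(6 * fs)
            pows["task"].append(band_power(rec.samples[0, i0:i1], fs, 30, 500))
            pows["rest"].append(band_power(rec.samples[0, i1:], fs, 30, 500))
        ratio = np.mean(pows["task"]) / np.mean(pows["rest"])
        assert 0.5 < ratio < 2.0  # same 1/f background either side

    def test_emg_doubles_high_band_task_power(self, timing, gen_config):
        """Default EMG raises >30 Hz task-window power at least 2x over
        the rest window."""
        ratios = []
        for seed in range(5):
            rec = generate_trial("RB", timing=timing, config=gen_config,
                                 seed=seed)
            fs = gen_config.fs_hz
            i0, i1 = int(2 * fs), int(6 * fs)
            task = np.mean([band_power(rec.samples[c, i0:i1], fs, 30, 500)
                            for c in range(4)])
            rest = np.mean([band_power(rec.samples[c, i1:], fs, 30, 500)
                            for c in range(4)])
            ratios.append(task / rest)
        assert min(ratios) >= 2.0

    def test_alpha_gain_ratio_maps_to_squared_power_ratio(self, timing,
                                                          gen_config):
        """A C4/C3 alpha amplitude gain ratio of 1.5 yields a task-window
        8-16 Hz power ratio of 1.5**2 within 15% (periodogram oracle,
        averaged over seeds)."""
        sig = ClassSignature("FB", alpha_gain=(1, 1, 1, 1.5),
                             theta_gain=(1, 1, 1, 1))
        r = []
        for seed in range(30):
            rec = generate_trial("FB", sig, timing, gen_config, seed=seed)
            fs = gen_config.fs_hz
            i0, i1 = int(2 * fs), int(6 * fs)
            p4 = band_power(rec.samples[3, i0:i1], fs, *ALPHA_BAND)
            p3 = band_power(rec.samples[2, i0:i1], fs, *ALPHA_BAND)
            r.append(p4 / p3)
        assert np.mean(r) == pytest.approx(1.5 ** 2, rel=0.15)


class TestGenerateDataset:
    def test_balanced_sessions(self, timing, gen_config):
        ds = generate_dataset(10, timing=timing, config=gen_config, seed=0)
        assert len(ds) == 60
        assert ds.epochs.shape == (60, 4, int(4 * gen_config.fs_hz))
        counts = {c: ds.labels.count(c) for c in CLASSES}
        assert set(counts.values()) == {15}

    def test_single_class_request(self, timing, gen_config):
        ds = generate_dataset(per_class_counts={"FB": 5, "RB": 0, "LS": 0,
                                                "RS": 0},
                              timing=timing, config=gen_config, seed=0)
        assert ds.labels == ["FB"] * 5

    def test_zero_trials_rejected(self, timing, gen_config):
        with pytest.raises(ValueError):
            generate_dataset(per_class_counts={"FB": 0}, timing=timing,
                             config=gen_config, seed=0)

    def test_determinism(self, timing, gen_config):
        a = generate_dataset(2, timing=timing, config=gen_config, seed=9)
        b = generate_dataset(2, timing=timing, config=gen_config, seed=9)
        np.testing.assert_array_equal(a.epochs, b.epochs)

    def test_band_power_class_contrast(self, timing, gen_config):
        """Averaged over seeds, the LS/RS alpha power ratio on C4 matches
        the squared gain ratio within 15%."""
        g_ls = DEFAULT_SIGNATURES["LS"].alpha_gain[3]
        g_rs = DEFAULT_SIGNATURES["RS"].alpha_gain[3]
        p_ls, p_rs = [], []
        for seed in range(25):
            ls = generate_trial("LS", timing=timing, config=gen_config,
                                seed=seed)
            rs = generate_trial("RS", timing=timing, config=gen_config,
                                seed=1000 + seed)
            fs = gen_config.fs_hz
            i0, i1 = int(2 * fs), int(6 * fs)
            p_ls.append(band_power(ls.samples[3, i0:i1], fs, *ALPHA_BAND))
            p_rs.append(band_power(rs.samples[3, i0:i1], fs, *ALPHA_BAND))
        ratio = np.mean(p_ls) / np.mean(p_rs)
        assert ratio == pytest.approx((g_ls / g_rs) ** 2, rel=0.15)
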