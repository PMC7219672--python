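import numpy as np
import pytest

from fracfall.preprocess import sum_vector
from fracfall.synthetic import (
    SimConfig,
    fgn_autocovariance,
    gen_adl_window,
    gen_arfima_series,
    gen_fall_window,
    gen_fgn,
    gen_labelled_dataset,
)


class TestFGn:
    def test_white_noise_case_uncorrelated(self):
        x = gen_fgn(0.5, 4096, seed=1)
        r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert abs(r1) <= 3.0 / np.sqrt(len(x))

    def test_persistent_case_matches_closed_form_acf(self):
        """fGn lag-1 autocovariance is 2^(2H−1) − 1 exactly.

        The known-zero-mean estimator is used: subtracting the sample mean
        biases the ACF of long-memory series downward."""
        h = 0.9
        r1s = []
        for seed in range(5):
            x = gen_fgn(h, 4096, seed=seed)
            r1s.append(np.mean(x[:-1] * x[1:]))
        assert np.mean(r1s) == pytest.approx(2.0 ** (2 * h - 1) - 1, abs=0.05)

    def test_autocovariance_function_values(self):
        rho = fgn_autocovariance(0.7, np.arange(6))
        assert rho[0] == pytest.approx(1.0)
        # Monte-Carlo check at small lags
        xs = np.stack([gen_fgn(0.7, 2048, seed=s) for s in range(20)])
        for k in range(1, 4):
            emp = np.mean([np.mean(x[:-k] * x[k:]) for x in xs])
            assert emp == pytest.approx(rho[k], abs=0.05)

    def test_seed_determinism(self):
        np.testing.assert_array_equal(gen_fgn(0.7, 256, 9), gen_fgn(0.7, 256, 9))

    def test_invalid_hurst_rejected(self):
        with pytest.raises(ValueError):
            gen_fgn(1.2, 64, 0)


class TestARFIMASeries:
    def test_memoryless_case_is_iid(self):
        x = gen_arfima_series(0, 0.0, 0, n=4096, seed=2)
        acf1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert abs(acf1) <= 3.0 / np.sqrt(len(x))

    def test_seed_determinism(self):
        a = gen_arfima_series(1, 0.3, 1, ar=[0.5], ma=[0.3], n=512, seed=4)
        b = gen_arfima_series(1, 0.3, 1, ar=[0.5], ma=[0.3], n=512, seed=4)
        np.testing.assert_array_equal(a, b)

    def test_nonstationary_ar_rejected(self):
        with pytest.raises(ValueError, match="stationary"):
            gen_arfima_series(1, 0.0, 0, ar=[1.05], n=128, seed=0)

    def test_coefficient_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="counts"):
            gen_arfima_series(2, 0.0, 0, ar=[0.5], n=128, seed=0)


class TestAccelerometerWindows:
    def test_fall_window_has_impact_spike(self, sim_cfg):
        rng = sim_cfg.rng()
        for _ in range(20):
            seg, label = gen_fall_window(sim_cfg, rng)
            assert label == "fall"
            sv = sum_vector(seg)
            assert len(sv) == 128
            assert sv.max() >= np.median(sv) + 2.0

    def test_quiet_fall_without_spike_or_noise_is_constant(self):
        cfg = SimConfig(
            seed=0, noise_sd_g=0.0, drift_sd_g=0.0,
            spike_amplitude_g=(0.0, 0.0), freefall_depth_g=(0.0, 0.0),
        )
        seg, _ = gen_fall_window(cfg)
        np.testing.assert_allclose(sum_vector(seg), 1.0, atol=1e-12)

    def test_adl_window_energy_is_low_frequency(self, sim_cfg):
        """ADL episodic motion concentrates non-DC sum-vector spectral
        energy below 8 Hz (episodes centre on 0.5-3 Hz)."""
        rng = sim_cfg.rng()
        fracs = []
        for _ in range(30):
            seg, label = gen_adl_window(sim_cfg, rng)
            assert label == "adl"
            sv = sum_vector(seg)
            spec = np.abs(np.fft.rfft(sv - sv.mean())) ** 2
            freqs = np.fft.rfftfreq(len(sv), d=1.0 / seg.fs)
            fracs.append(spec[freqs < 8.0].sum() / spec.sum())
        assert np.mean(fracs) > 0.5

    def test_zero_episode_config_is_noise_only(self):
        cfg = SimConfig(seed=3, episode_count=(0, 0), drift_sd_g=0.0)
        seg, _ = gen_adl_window(cfg)
        sv = sum_vector(seg)
        assert np.std(sv) < 3 * cfg.noise_sd_g

    def test_window_determinism(self, sim_cfg):
        a, _ = gen_fall_window(sim_cfg)
        b, _ = gen_fall_window(sim_cfg)
        np.testing.assert_array_equal(a.az, b.az)

    def test_quantization_snaps_to_grid(self):
        cfg = SimConfig(seed=5, quantize_bits=12)
        seg, _ = gen_fall_window(cfg)
        step = 16.0 / 2**12
        np.testing.assert_allclose(
            seg.az, np.round(seg.az / step) * step, atol=1e-12
        )


class TestLabelledDataset:
    def test_counts_and_shuffle(self):
        segs, labels = gen_labelled_dataset(50, 30, SimConfig(seed=13))
        assert len(segs) == 80
        assert labels.count("fall") == 50 and labels.count("adl") == 30
        assert labels[:50].count("fall") < 50  # shuffled

    def test_single_class_request(self):
        segs, labels = gen_labelled_dataset(0, 10, SimConfig(seed=1))
        assert labels == ["adl"] * 10

    def test_dataset_determinism(self):
        a, la = gen_labelled_dataset(5, 5, SimConfig(seed=2))
        b, lb = gen_labelled_dataset(5, 5, SimConfig(seed=2))
        assert la == lb
        np.testing.assert_array_equal(a[0].az, b[0].az)
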