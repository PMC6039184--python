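import numpy as np
import pytest

from adaptcode import (GatingState, metamer_probability, noisy_transmission,
                       run_experiment, speed_accuracy, spike_raster)


class TestRunExperiment:
    def test_identity_encoder_is_lossless(self, mean_config):
        trace = run_experiment(mean_config, "identity", 3, np.random.default_rng(1))
        df = trace.df
        np.testing.assert_array_equal(df["x"], df["y"])
        np.testing.assert_array_equal(df["p_low"], df["p_low_ideal"])
        assert np.all(df["inference_error"] == 0.0)
        assert np.all(df["reconstruction_error"] == 0.0)

    def test_trace_shape_and_bounds(self, mean_config, bank_inference_n3):
        trace = run_experiment(mean_config, bank_inference_n3, 2,
                               np.random.default_rng(2))
        df = trace.df
        assert len(df) == 2 * trace.period == 400
        assert df["p_low"].between(0, 1).all()
        assert (df["inference_error"] >= 0).all()
        assert (df["entropy_rate"] >= 0).all()
        assert set(df["theta"].unique()) == {-1.0, 1.0}

    def test_fixed_seed_reproducibility(self, mean_config, bank_inference_n3):
        a = run_experiment(mean_config, bank_inference_n3, 2, np.random.default_rng(3))
        b = run_experiment(mean_config, bank_inference_n3, 2, np.random.default_rng(3))
        assert a.df.equals(b.df)

    def test_gating_records_misalignment_and_nulls(self, mean_config):
        gate = GatingState(window=10, threshold_fraction=0.5)
        trace = run_experiment(mean_config, gate, 5, np.random.default_rng(4))
        df = trace.df
        assert df["misalignment"].notna().all()
        assert 0.0 < df["null"].mean() < 1.0
        assert df.loc[df["null"] == 1.0, "y"].isna().all()

    def test_cycle_average_folds_cycles(self, mean_config):
        trace = run_experiment(mean_config, "identity", 4, np.random.default_rng(5))
        avg = trace.cycle_average()
        assert len(avg) == trace.period
        np.testing.assert_allclose(
            avg["theta"].to_numpy(),
            np.concatenate([np.full(100, -1.0), np.full(100, 1.0)]))


class TestSpeedAccuracy:
    def test_instant_jump_gives_unit_speed(self):
        p = np.concatenate([np.full(100, 0.9), np.full(100, 0.1)])
        sa = speed_accuracy(p)
        assert sa["speed_down"] == 1.0
        assert sa["speed_up"] == 1.0

    def test_constant_trace_accuracy(self):
        p = np.concatenate([np.full(100, 0.8), np.full(100, 0.3)])
        sa = speed_accuracy(p)
        assert sa["accuracy_low"] == pytest.approx(0.8)
        assert sa["accuracy_high"] == pytest.approx(0.7)

    def test_slow_ramp_detected(self):
        ramp = np.linspace(0.0, 1.0, 100)
        p = np.concatenate([ramp, 1.0 - ramp])
        sa = speed_accuracy(p)
        assert sa["speed_down"] < 0.2
        assert sa["speed_up"] < 0.2

    def test_never_stabilizing_floor(self):
        # oscillates outside the band around its final-window average
        p_half = np.tile([0.0, 1.0], 50)
        sa = speed_accuracy(np.concatenate([p_half, p_half]))
        assert sa["speed_down"] == pytest.approx(1.0 / 100)


class TestSpikeRaster:
    def test_requires_four_levels(self, mean_config, bank_inference_n3):
        trace = run_experiment(mean_config, bank_inference_n3, 1,
                               np.random.default_rng(6))
        with pytest.raises(ValueError):
            spike_raster(bank_inference_n3, trace)

    def test_spike_counts_follow_entropy_code(self, mean_config, bank_inference_n4):
        trace = run_experiment(mean_config, bank_inference_n4, 2,
                               np.random.default_rng(7))
        patterns, counts, rate = spike_raster(bank_inference_n4, trace)
        assert set(np.unique(counts)) <= {0.0, 1.0, 2.0}
        assert len(rate) == trace.period
        # aligned phases are dominated by the most probable level -> 0 spikes
        assert np.mean(counts) < 1.0

    def test_uniform_usage_average(self):
        # (0 + 1 + 1 + 2) / 4 = 1 spike per 2-bit symbol under uniform usage
        from adaptcode.metrics import SPIKE_COUNTS
        assert SPIKE_COUNTS.mean() == pytest.approx(1.0)


class TestMetamers:
    def test_probability_peaks_when_aligned(self, mean_config, bank_inference_n3, rng):
        grid, probs = metamer_probability(mean_config, bank_inference_n3, rng,
                                          n_pairs=5000, n_grid=11)
        assert probs[0] > probs[-1]          # aligned beats misaligned
        assert np.all((0 <= probs) & (probs <= 1))

    def test_single_level_always_metamer(self, mean_config):
        from adaptcode import build_bank
        bank = build_bank(mean_config, "reconstruction", 1,
                          np.random.default_rng(9), n_bins=5, n_train=2000)
        _, probs = metamer_probability(mean_config, bank,
                                       np.random.default_rng(10),
                                       n_pairs=100, n_grid=5)
        assert np.all(probs == 1.0)

    def test_seed_stability_within_binomial_error(self, mean_config, bank_inference_n3):
        n_pairs = 10_000
        _, a = metamer_probability(mean_config, bank_inference_n3,
                                   np.random.default_rng(11),
                                   n_pairs=n_pairs, n_grid=3)
        _, b = metamer_probability(mean_config, bank_inference_n3,
                                   np.random.default_rng(12),
                                   n_pairs=n_pairs, n_grid=3)
        sd = np.sqrt(0.25 / n_pairs)
        assert np.all(np.abs(a - b) < 6 * sd)  # 3 SDs on each estimate


class TestNoisyTransmission:
    def test_zero_noise_matches_noiseless(self, mean_config, bank_inference_n3):
        a = run_experiment(mean_config, bank_inference_n3, 2,
                           np.random.default_rng(13))
        b = noisy_transmission(mean_config, bank_inference_n3, 0.0, 2,
                               np.random.default_rng(13))
        assert a.df.equals(b.df)

    def test_huge_noise_destroys_information(self, mean_config, bank_inference_n3):
        trace = noisy_transmission(mean_config, bank_inference_n3, 100.0, 5,
                                   np.random.default_rng(14))
        sa = speed_accuracy(trace.cycle_average()["p_low"].to_numpy())
        assert sa["accuracy_low"] < 0.75
        assert sa["accuracy_high"] < 0.75

    def test_negative_variance_rejected(self, mean_config, bank_inference_n3):
        with pytest.raises(ValueError):
            noisy_transmission(mean_config, bank_inference_n3, -0.1, 1,
                               np.random.default_rng(15))


class TestDynamicCodingCost:
    def test_entropy_rate_spikes_after_switches(self, mean_config, bank_inference_n3):
        """Inference-optimized discretization: the cycle-averaged entropy
        rate shows a transient spike in the 10 steps after each switch and
        then returns near baseline."""
        trace = run_experiment(mean_config, bank_inference_n3, 50,
                               np.random.default_rng(21))
        er = trace.cycle_average()["entropy_rate"].to_numpy()
        base = np.concatenate([er[50:100], er[150:200]]).mean()
        peak = max(er[0:10].max(), er[100:110].max())
        assert peak > base * 1.5
        # recovery: the last-half average sits well below the peak
        assert base < 0.7 * peak

    def test_mean_mode_entropy_transients_symmetric(self, mean_config,
                                                    bank_inference_n3):
        """Upward and downward mean switches produce mirror-image coding
        cost transients."""
        trace = run_experiment(mean_config, bank_inference_n3, 100,
                               np.random.default_rng(22))
        er = trace.cycle_average()["entropy_rate"].to_numpy()
        down, up = er[0:30], er[100:130]
        np.testing.assert_allclose(down.mean(), up.mean(), rtol=0.15)

    def test_variance_mode_entropy_transients_asymmetric(self, var_config):
        """Variance switches are asymmetric: the high-variance state keeps
        the entropy rate elevated, so the post-upward-switch cost exceeds
        the post-downward-switch cost."""
        from adaptcode import build_bank
        bank = build_bank(var_config, "inference", 3, np.random.default_rng(23))
        trace = run_experiment(var_config, bank, 100, np.random.default_rng(24))
        er = trace.cycle_average()["entropy_rate"].to_numpy()
        assert er[100:130].mean() > 1.2 * er[0:30].mean()
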