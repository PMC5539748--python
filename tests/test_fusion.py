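import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ppgfuse import (
    RunConfig,
    WeightTrace,
    clean_scenario,
    design_lowpass_fir,
    detect_on_mixed,
    filter_channel,
    generate_beat_times,
    generate_channel,
    generate_record,
    mix_average,
    mix_weighted,
    run_weight_dynamics,
    scenario_preset,
    update_weight,
)
from ppgfuse.fusion import smooth_trace

FS = 200.0


def _trace(weights, config):
    return WeightTrace(
        weights=np.asarray(weights, float),
        alpha=config.alpha,
        bounds=(config.weight_min, config.weight_max),
    )


class TestMixAverage:
    def test_identical_channels_are_fixed_point(self, rng):
        ch = rng.normal(size=300)
        mixed = mix_average(np.tile(ch, (4, 1)))
        np.testing.assert_allclose(mixed.values, ch, atol=1e-15)

    def test_single_sample_arithmetic(self):
        mixed = mix_average(np.array([[0.0], [0.0], [0.0], [4.0]]))
        assert mixed.values[0] == pytest.approx(1.0)

    def test_matches_brute_force_summation(self, rng):
        channels = rng.normal(size=(4, 500))
        oracle = np.array(
            [sum(channels[i][n] for i in range(4)) / 4.0 for n in range(500)]
        )
        np.testing.assert_allclose(mix_average(channels).values, oracle, atol=1e-12)

    def test_ragged_channels_rejected(self):
        with pytest.raises(ValueError):
            mix_average([np.zeros(10), np.zeros(10), np.zeros(10), np.zeros(9)])


class TestUpdateWeight:
    @pytest.mark.parametrize(
        "prev,event,expected",
        [
            (10.0, "valid_peak", 12.0),
            (20.0, "valid_peak", 20.0),  # clamp at upper bound
            (2.0, "invalid_peak", 2.0),  # clamp at lower bound
            (10.0, "invalid_peak", 8.0),
            (10.0, "missed_window", 8.0),
            (10.0, "none", 10.0),
        ],
    )
    def test_three_cases_with_clamping(self, prev, event, expected, config):
        assert update_weight(prev, event, config) == expected

    def test_unknown_event_rejected(self, config):
        with pytest.raises(ValueError, match="unknown"):
            update_weight(10.0, "bogus", config)


class TestMixWeighted:
    def test_equal_weights_equal_average_exactly(self, config, rng):
        channels = rng.normal(size=(4, 400))
        for w in (2.0, 7.0, 20.0):
            trace = _trace(np.full((4, 400), w), config)
            np.testing.assert_allclose(
                mix_weighted(channels, trace).values,
                mix_average(channels).values,
                rtol=0,
                atol=1e-12,
            )

    def test_single_sample_direct_evaluation(self, config):
        trace = _trace([[20.0], [2.0], [2.0], [2.0]], config)
        mixed = mix_weighted(np.array([[1.0], [0.0], [0.0], [0.0]]), trace)
        assert mixed.values[0] == pytest.approx(20.0 / 26.0, rel=1e-12)

    @given(seed=st.integers(0, 2**16))
    def test_matches_brute_force_summation(self, config, seed):
        r = np.random.default_rng(seed)
        channels = r.normal(size=(4, 50))
        weights = r.uniform(config.weight_min, config.weight_max, size=(4, 50))
        trace = _trace(weights, config)
        oracle = np.array(
            [
                sum(weights[i, n] * channels[i, n] for i in range(4))
                / sum(weights[i, n] for i in range(4))
                for n in range(50)
            ]
        )
        np.testing.assert_allclose(mix_weighted(channels, trace).values, oracle, atol=1e-12)

    @given(seed=st.integers(0, 2**16))
    def test_convexity_and_permutation_equivariance(self, config, seed):
        r = np.random.default_rng(seed)
        channels = r.normal(size=(4, 80))
        weights = r.uniform(config.weight_min, config.weight_max, size=(4, 80))
        trace = _trace(weights, config)
        mixed = mix_weighted(channels, trace).values
        assert np.all(mixed >= channels.min(axis=0) - 1e-12)
        assert np.all(mixed <= channels.max(axis=0) + 1e-12)
        perm = r.permutation(4)
        permuted = mix_weighted(channels[perm], _trace(weights[perm], config)).values
        np.testing.assert_allclose(permuted, mixed, atol=1e-12)


class TestWeightDynamics:
    def test_flat_channels_keep_minimum_weight(self, config):
        channels = np.ones((4, int(20 * FS)))
        trace = run_weight_dynamics(channels, FS, config)
        np.testing.assert_array_equal(trace.weights, config.weight_min)

    def test_weights_bounded_integral_and_alpha_stepped(self, config):
        rec = generate_record(scenario_preset("rapid_horizontal", seed=11, duration_s=20.0))
        coeffs = design_lowpass_fir(config.filter_order, config.cutoff_hz, rec.fs)
        filtered = np.vstack([filter_channel(ch, coeffs) for ch in rec.samples])
        trace = run_weight_dynamics(filtered, rec.fs, config)
        w = trace.weights
        assert w.min() >= config.weight_min and w.max() <= config.weight_max
        np.testing.assert_array_equal(w, np.round(w))  # integral with alpha=2
        steps = np.abs(np.diff(w, axis=1))
        assert set(np.unique(steps)) <= {0.0, config.alpha}

    def test_clean_channel_ratchets_to_maximum(self, config):
        rec = generate_record(clean_scenario(hr_bpm=60.0, seed=3))
        coeffs = design_lowpass_fir(config.filter_order, config.cutoff_hz, rec.fs)
        filtered = np.vstack([filter_channel(ch, coeffs) for ch in rec.samples])
        trace = run_weight_dynamics(filtered, rec.fs, config)
        # >= 9 valid beats lift a weight from 2 to 20 at alpha = 2; one clean
        # minute at 60 bpm has ~58 of them, so the weight saturates and holds
        for i in range(4):
            w = trace.weights[i]
            hit = np.nonzero(w == config.weight_max)[0]
            assert hit.size > 0
            assert np.all(w[hit[0] :] == config.weight_max)

    def test_clean_channel_outweighs_pure_noise_channels(self, config):
        scenario = clean_scenario(hr_bpm=75.0, seed=21, duration_s=30.0)
        beats = generate_beat_times(30.0, 75.0, 0.0, FS, seed=21)
        clean = generate_channel(beats, scenario, 0)
        rng = np.random.default_rng(99)
        channels = np.vstack([clean] + [rng.normal(0, 0.5, clean.size) for _ in range(3)])
        coeffs = design_lowpass_fir(config.filter_order, config.cutoff_hz, FS)
        filtered = np.vstack([filter_channel(ch, coeffs) for ch in channels])
        trace = run_weight_dynamics(filtered, FS, config)
        means = trace.weights.mean(axis=1)
        assert means[0] > means[1:].max()


class TestSmoothTrace:
    def test_constant_trace_unchanged(self, config):
        trace = _trace(np.full((4, 200), 6.0), config)
        np.testing.assert_allclose(smooth_trace(trace, FS, 0.3).weights, 6.0, atol=1e-12)

    def test_bounds_preserved_and_steps_spread(self, config):
        w = np.full((4, 400), 2.0)
        w[:, 200:] = 20.0
        smoothed = smooth_trace(_trace(w, config), FS, 0.3).weights
        assert smoothed.min() >= 2.0 and smoothed.max() <= 20.0
        assert np.abs(np.diff(smoothed, axis=1)).max() < 1.0  # no 18-unit jumps


class TestPipeline:
    def test_clean_record_recovers_rate_with_both_methods(self, config):
        rec = generate_record(clean_scenario(hr_bpm=60.0, seed=7))
        for method in ("average", "weighted"):
            _, peaks, pr = detect_on_mixed(rec, method, config)
            assert pr.size > 40
            assert np.all(np.abs(pr[2:] - 60.0) <= 1.0)

    def test_channel_method_bypasses_mixing(self, config):
        rec = generate_record(clean_scenario(hr_bpm=60.0, seed=7))
        coeffs = design_lowpass_fir(config.filter_order, config.cutoff_hz, rec.fs)
        mixed, peaks, _ = detect_on_mixed(rec, "channel:3", config)
        np.testing.assert_allclose(
            mixed.values, filter_channel(rec.samples[2], coeffs), atol=1e-12
        )
        assert len(peaks) > 0

    @pytest.mark.parametrize("method", ["channel:0", "channel:9", "median"])
    def test_bad_method_rejected(self, method, config):
        rec = generate_record(clean_scenario(hr_bpm=60.0, seed=1, duration_s=5.0))
        with pytest.raises(ValueError):
            detect_on_mixed(rec, method, config)
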