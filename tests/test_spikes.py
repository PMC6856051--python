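"""Spike-train generation, jitter, Gaussian-filtered distance, task bundles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ionliquid.errors import ConfigError, SearchError
from ionliquid.spikes import (
    SpikePattern,
    SpikeTrain,
    jitter_spike_train,
    make_distance_matched_pairs,
    make_pattern_task,
    pattern_distance,
    poisson_spike_train,
    spike_train_distance,
)


def quadrature_distance(u, v, sigma, n_grid=40001, pad=8.0):
    """Independent oracle: dense-grid L2 distance of the filtered functions."""
    lo = -pad * sigma
    hi = u.duration + pad * sigma
    t = np.linspace(lo, hi, n_grid)

    def f(train):
        if train.n_spikes == 0:
            return np.zeros_like(t)
        z = (t[:, None] - train.times[None, :]) / sigma
        return np.exp(-0.5 * z**2).sum(axis=1) / (sigma * np.sqrt(2 * np.pi))

    diff2 = (f(u) - f(v)) ** 2
    return float(np.sqrt(np.trapezoid(diff2, t)))


class TestPoisson:
    def test_zero_rate_gives_empty_train(self):
        assert poisson_spike_train(0.0, 200.0, seed=1).n_spikes == 0

    def test_mean_count_matches_rate_times_duration(self):
        counts = [poisson_spike_train(20.0, 200.0, seed=s).n_spikes for s in range(10000)]
        expected = 20.0 * 0.2  # = 4 spikes
        sigma = np.sqrt(expected / 10000)
        assert np.mean(counts) == pytest.approx(expected, abs=3 * sigma)

    def test_same_seed_reproduces_train(self):
        a = poisson_spike_train(20.0, 200.0, seed=7)
        b = poisson_spike_train(20.0, 200.0, seed=7)
        np.testing.assert_array_equal(a.times, b.times)

    def test_negative_rate_rejected(self):
        with pytest.raises(ConfigError):
            poisson_spike_train(-1.0, 200.0)


class TestJitter:
    def test_zero_sigma_is_identity(self):
        u = poisson_spike_train(20.0, 200.0, seed=3)
        v = jitter_spike_train(u, 0.0, seed=4)
        np.testing.assert_array_equal(u.times, v.times)

    @given(st.floats(0.0, 50.0), st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=40, derandomize=True)
    def test_output_sorted_and_in_range_for_any_sigma(self, sigma, seed):
        u = poisson_spike_train(30.0, 200.0, seed=seed)
        v = jitter_spike_train(u, sigma, seed=seed + 1)
        assert v.n_spikes == u.n_spikes
        assert np.all(np.diff(v.times) >= 0)
        if v.n_spikes:
            assert v.times.min() >= 0 and v.times.max() <= 200.0

    def test_displacement_std_matches_sigma_for_interior_spikes(self):
        # one spike far from both boundaries: no clipping, displacement ~ N(0, sigma)
        u = SpikeTrain(times=np.array([500.0]), duration=1000.0)
        disp = np.array([
            jitter_spike_train(u, 10.0, seed=s).times[0] - 500.0 for s in range(10000)
        ])
        assert disp.std() == pytest.approx(10.0, rel=0.05)
        assert disp.mean() == pytest.approx(0.0, abs=0.5)


class TestDistance:
    def test_self_distance_is_zero(self):
        u = poisson_spike_train(20.0, 500.0, seed=0)
        assert spike_train_distance(u, u) == pytest.approx(0.0, abs=1e-12)

    def test_symmetry(self):
        u = poisson_spike_train(20.0, 500.0, seed=1)
        v = poisson_spike_train(20.0, 500.0, seed=2)
        assert spike_train_distance(u, v) == pytest.approx(spike_train_distance(v, u))

    def test_two_single_spike_trains_match_closed_form_and_quadrature(self):
        sigma = 5.0
        delta = 7.0
        u = SpikeTrain(times=np.array([100.0]), duration=300.0)
        v = SpikeTrain(times=np.array([100.0 + delta]), duration=300.0)
        got = spike_train_distance(u, v, sigma)
        norm = 1.0 / (2 * sigma * np.sqrt(np.pi))
        closed = np.sqrt(2 * norm - 2 * norm * np.exp(-(delta**2) / (4 * sigma**2)))
        assert got == pytest.approx(closed, abs=1e-12)
        assert got == pytest.approx(quadrature_distance(u, v, sigma), abs=1e-6)

    @pytest.mark.parametrize("seed", range(6))
    def test_random_trains_agree_with_quadrature_oracle(self, seed):
        u = poisson_spike_train(25.0, 300.0, seed=seed)
        v = poisson_spike_train(25.0, 300.0, seed=seed + 100)
        got = spike_train_distance(u, v, 5.0)
        assert got == pytest.approx(quadrature_distance(u, v, 5.0), abs=1e-6)

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=30, derandomize=True)
    def test_pseudo_metric_triangle_inequality(self, seed):
        rng = np.random.default_rng(seed)
        trains = [poisson_spike_train(rng.uniform(5, 40), 200.0, rng) for _ in range(3)]
        d01 = spike_train_distance(trains[0], trains[1])
        d12 = spike_train_distance(trains[1], trains[2])
        d02 = spike_train_distance(trains[0], trains[2])
        assert d02 <= d01 + d12 + 1e-9

    def test_normalized_distance_bounded_by_one(self):
        for seed in range(10):
            u = poisson_spike_train(20.0, 200.0, seed=seed)
            v = poisson_spike_train(20.0, 200.0, seed=seed + 50)
            d = spike_train_distance(u, v, normalized=True)
            assert 0.0 <= d <= 1.0

    def test_mismatched_durations_rejected(self):
        u = SpikeTrain(times=np.array([1.0]), duration=10.0)
        v = SpikeTrain(times=np.array([1.0]), duration=20.0)
        with pytest.raises(ConfigError):
            spike_train_distance(u, v)

    def test_multi_channel_distance_is_l2_over_channels(self):
        a = SpikePattern(trains=(SpikeTrain(times=np.array([10.0]), duration=100.0),
                                 SpikeTrain(times=np.array([50.0]), duration=100.0)))
        b = SpikePattern(trains=(SpikeTrain(times=np.array([20.0]), duration=100.0),
                                 SpikeTrain(times=np.array([80.0]), duration=100.0)))
        per = [spike_train_distance(u, v) for u, v in zip(a.trains, b.trains)]
        assert pattern_distance(a, b) == pytest.approx(np.sqrt(sum(d**2 for d in per)))


class TestPatternTask:
    def test_default_task_shapes(self):
        task = make_pattern_task(seed=0)
        assert task.n_patterns == 80
        assert all(p.n_channels == 4 for p in task.patterns)
        assert all(p.duration == 200.0 for p in task.patterns)
        assert task.label_functions.shape == (20, 80)
        assert set(np.unique(task.label_functions)) <= {0, 1}

    def test_same_seed_reproduces_bundle(self):
        a = make_pattern_task(n_patterns=5, n_functions=3, seed=11)
        b = make_pattern_task(n_patterns=5, n_functions=3, seed=11)
        np.testing.assert_array_equal(a.label_functions, b.label_functions)
        for pa, pb in zip(a.patterns, b.patterns):
            for ta, tb in zip(pa.trains, pb.trains):
                np.testing.assert_array_equal(ta.times, tb.times)

    def test_sampled_instances_reference_their_base_patterns(self):
        task = make_pattern_task(n_patterns=5, n_functions=1, seed=2)
        instances, idx = task.sample_instances(30, 0.0, np.random.default_rng(0))
        for inst, i in zip(instances, idx):
            for ch_inst, ch_base in zip(inst.trains, task.patterns[i].trains):
                np.testing.assert_array_equal(ch_inst.times, ch_base.times)


class TestMatchedPairs:
    def test_zero_target_returns_identical_pair(self):
        u, v = make_distance_matched_pairs(0.0, 0.0, seed=5)
        np.testing.assert_array_equal(u.times, v.times)

    @pytest.mark.parametrize("target", [0.1, 0.3])
    def test_accepted_pairs_satisfy_tolerance_by_construction(self, target):
        rng = np.random.default_rng(1)
        for _ in range(20):
            u, v = make_distance_matched_pairs(target, 0.02, seed=rng)
            d = spike_train_distance(u, v, normalized=True)
            assert abs(d - target) <= 0.02

    def test_accepted_distance_distribution_centers_on_target(self):
        rng = np.random.default_rng(2)
        ds = []
        for _ in range(100):
            u, v = make_distance_matched_pairs(0.3, 0.02, seed=rng)
            ds.append(spike_train_distance(u, v, normalized=True))
        assert np.mean(ds) == pytest.approx(0.3, abs=0.02)

    def test_unreachable_target_exhausts_budget_with_diagnostics(self):
        with pytest.raises(SearchError, match="attempts"):
            make_distance_matched_pairs(0.9, 0.001, rate_hz=5.0, duration_ms=100.0,
                                        seed=0, max_attempts=3)
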