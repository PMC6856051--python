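"""Firing dynamics: pre-activation, k-WTA, intrinsic plasticity, full loop."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ionliquid.dynamics import (
    DynamicsConfig,
    LiquidState,
    StatePath,
    axonal_feedback,
    kwta,
    pattern_to_injections,
    preactivation,
    run_simulation,
    update_thresholds,
)
from ionliquid.errors import ConfigError
from ionliquid.grid import BinMapping, DiffusionParams, VoltageGrid
from ionliquid.spikes import SpikePattern, SpikeTrain, poisson_spike_train
from ionliquid.topology import Topology, TopologyConfig, generate_random_topology


def tiny_topology(grid=8, lattice=2, dendrites=1):
    """Neurons with all terminals on their own lattice bins."""
    cfg = TopologyConfig(grid_width=grid, grid_height=grid, lattice=lattice,
                         n_dendrites=dendrites,
                         dendrite_length=(0.0, 0.0), axon_length=(0.0, 0.0))
    return generate_random_topology(cfg, seed=0)


class TestPreactivation:
    def test_single_dendrite_reads_bin_minus_threshold(self):
        topo = tiny_topology()
        grid = VoltageGrid.zeros(8, 8)
        x, y = topo.dendrite_terminals[0, 0]
        grid.voltage[y, x] = 0.5
        state = LiquidState.initial(topo.n_neurons)
        state.nu[0] = 0.1
        p = preactivation(grid, topo, state)
        assert p[0] == pytest.approx(0.5 * topo.dendrite_weights[0, 0] - 0.1)

    def test_zero_grid_zero_threshold_gives_zero(self):
        topo = tiny_topology()
        p = preactivation(VoltageGrid.zeros(8, 8), topo, LiquidState.initial(4))
        np.testing.assert_array_equal(p, 0.0)

    def test_two_dendrites_weighted_sum(self):
        topo = tiny_topology(dendrites=2)
        grid = VoltageGrid.zeros(8, 8)
        x0, y0 = topo.dendrite_terminals[0, 0]
        grid.voltage[y0, x0] = 1.0  # second dendrite shares the bin here, V=1 on both
        p = preactivation(grid, topo, LiquidState.initial(4))
        assert p[0] == pytest.approx(1.0)  # w = (0.5, 0.5) on (1, 1)


class TestKwta:
    def test_k_equals_n_fires_everyone(self):
        np.testing.assert_array_equal(kwta(np.array([0.3, -1.0, 2.0]), 3), [1, 1, 1])

    def test_single_winner_is_argmax(self):
        np.testing.assert_array_equal(kwta(np.array([3.0, 1.0, 2.0]), 1), [1, 0, 0])

    def test_ties_break_toward_lowest_index(self):
        np.testing.assert_array_equal(kwta(np.zeros(5), 2), [1, 1, 0, 0, 0])

    @pytest.mark.parametrize("k", [0, 4])
    def test_k_out_of_range_rejected(self, k):
        with pytest.raises(ConfigError):
            kwta(np.zeros(3), k)

    @given(st.integers(0, 2**31 - 1), st.integers(1, 30))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_exactly_k_winners_and_no_loser_beats_a_winner(self, seed, n):
        rng = np.random.default_rng(seed)
        p = rng.normal(size=n)
        k = int(rng.integers(1, n + 1))
        x = kwta(p, k)
        assert x.sum() == k
        if k < n:
            assert p[x == 1].min() >= p[x == 0].max()


class TestThresholdUpdate:
    def test_active_neuron_threshold_rises_by_eta_times_one_minus_sparsity(self):
        nu = update_thresholds(np.zeros(2), np.array([1, 0]), eta=0.2, k=1, n=20)
        assert nu[0] == pytest.approx(0.2 * (1 - 0.05))
        assert nu[1] == pytest.approx(-0.2 * 0.05)

    def test_threshold_sum_invariant_with_exact_k_winners(self, rng):
        nu = rng.normal(size=50)
        x = np.zeros(50)
        x[rng.choice(50, 5, replace=False)] = 1
        nu2 = update_thresholds(nu, x, eta=0.2, k=5, n=50)
        assert nu2.sum() == pytest.approx(nu.sum(), abs=1e-12)


class TestAxonalFeedback:
    def test_no_spikes_leaves_grid_unchanged(self, small_topology):
        g = VoltageGrid.zeros(16, 16)
        out = axonal_feedback(g, small_topology, np.zeros(16), 1.0)
        np.testing.assert_array_equal(out.voltage, 0.0)

    def test_single_spike_deposits_amplitude_at_axon_bin(self, small_topology):
        x = np.zeros(16)
        x[3] = 1
        out = axonal_feedback(VoltageGrid.zeros(16, 16), small_topology, x, 1.0)
        ax, ay = small_topology.axon_terminals[3]
        assert out.voltage[ay, ax] == 1.0
        assert out.total() == 1.0

    def test_shared_axon_bins_accumulate(self):
        topo = tiny_topology()
        topo.axon_terminals[:] = [4, 4]
        out = axonal_feedback(VoltageGrid.zeros(8, 8), topo, np.array([1, 1, 0, 0]), 0.5)
        assert out.voltage[4, 4] == pytest.approx(1.0)


class TestRunSimulation:
    def test_exactly_k_active_every_step(self, small_topology, rng):
        dyn = DynamicsConfig(k=3)
        inputs = [np.column_stack([rng.integers(0, 16, 4), rng.integers(0, 16, 4),
                                   rng.uniform(0, 5, 4)]) for _ in range(40)]
        path = run_simulation(VoltageGrid.zeros(16, 16), small_topology, dyn, inputs)
        np.testing.assert_array_equal(path.activity.sum(axis=1), 3)

    def test_silent_symmetric_liquid_cycles_through_neurons(self):
        # hand trace, 2x2 neurons, k=1, no input, no feedback: all p tie at
        # step 1 so neuron 0 wins; its raised threshold hands step 2 to
        # neuron 1 (tie among 1,2,3), then step 3 to neuron 2.
        topo = tiny_topology()
        dyn = DynamicsConfig(k=1, eta=0.2, spike_amplitude=0.0)
        empty = [np.empty((0, 3))] * 3
        path = run_simulation(VoltageGrid.zeros(8, 8), topo, dyn, empty)
        np.testing.assert_array_equal(np.argmax(path.activity, axis=1), [0, 1, 2])

    def test_identical_runs_reproduce_identical_paths(self, small_topology, rng):
        dyn = DynamicsConfig(k=2)
        inputs = [np.column_stack([rng.integers(0, 16, 2), rng.integers(0, 16, 2),
                                   rng.uniform(0, 5, 2)]) for _ in range(20)]
        a = run_simulation(VoltageGrid.zeros(16, 16), small_topology, dyn, inputs)
        b = run_simulation(VoltageGrid.zeros(16, 16), small_topology, dyn, inputs)
        np.testing.assert_array_equal(a.activity, b.activity)

    def test_threshold_sum_conserved_over_whole_run(self, small_topology, rng):
        dyn = DynamicsConfig(k=2)
        inputs = [np.column_stack([rng.integers(0, 16, 3), rng.integers(0, 16, 3),
                                   rng.uniform(0, 10, 3)]) for _ in range(200)]
        path = run_simulation(VoltageGrid.zeros(16, 16), small_topology, dyn, inputs,
                              record_trajectories=True)
        sums = path.nu.sum(axis=1)
        np.testing.assert_allclose(sums, 0.0, atol=1e-9)

    def test_firing_rates_converge_to_target_sparsity(self):
        # intrinsic plasticity drives every neuron's rate toward k/N under
        # stationary random input
        cfg = TopologyConfig(grid_width=20, grid_height=20, lattice=5)
        topo = generate_random_topology(cfg, seed=2)
        dyn = DynamicsConfig(k=1)
        mapping = BinMapping(targets=np.array([[5, 5], [14, 5], [5, 14], [14, 14]]),
                             grid_width=20, grid_height=20, gain=20.0)
        pattern = SpikePattern(trains=tuple(
            poisson_spike_train(20.0, 60000.0, s) for s in range(4)))
        inputs = pattern_to_injections(pattern, mapping, 3000, 20.0)
        path = run_simulation(VoltageGrid.zeros(20, 20), topo, dyn, inputs)
        rates = path.rates()
        target = dyn.k / topo.n_neurons
        assert np.all(np.abs(rates - target) <= 0.5 * target)


class TestInjectionBinning:
    def test_plain_binning_preserves_total_charge(self, two_channel_mapping):
        train = SpikeTrain(times=np.array([1.0, 55.0, 99.0]), duration=100.0)
        pat = SpikePattern(trains=(train, SpikeTrain(times=np.array([]), duration=100.0)))
        steps = pattern_to_injections(pat, two_channel_mapping, 5, 20.0)
        total = sum(ev[:, 2].sum() for ev in steps if ev.size)
        assert total == pytest.approx(3 * two_channel_mapping.gain)

    def test_antialiased_binning_preserves_charge_and_splits_smoothly(self, two_channel_mapping):
        train = SpikeTrain(times=np.array([30.0]), duration=100.0)  # 1.5 steps
        pat = SpikePattern(trains=(train, SpikeTrain(times=np.array([]), duration=100.0)))
        steps = pattern_to_injections(pat, two_channel_mapping, 5, 20.0, antialias=True)
        assert steps[1][0, 2] == pytest.approx(0.5 * two_channel_mapping.gain)
        assert steps[2][0, 2] == pytest.approx(0.5 * two_channel_mapping.gain)
        total = sum(ev[:, 2].sum() for ev in steps if ev.size)
        assert total == pytest.approx(two_channel_mapping.gain)

    def test_settle_steps_append_silent_steps(self, two_channel_mapping):
        pat = SpikePattern(trains=(SpikeTrain(times=np.array([10.0]), duration=100.0),
                                   SpikeTrain(times=np.array([]), duration=100.0)))
        steps = pattern_to_injections(pat, two_channel_mapping, 5, 20.0, settle_steps=3)
        assert len(steps) == 8
        assert all(ev.size == 0 for ev in steps[5:])


class TestStatePathIO:
    def test_csv_round_trip(self, tmp_path, rng):
        path = StatePath(activity=rng.integers(0, 2, size=(7, 5)).astype(np.uint8))
        f = tmp_path / "sp.csv"
        path.save_csv(f, sidecar={"seed": 1})
        loaded = StatePath.load_csv(f)
        np.testing.assert_array_equal(loaded.activity, path.activity)
        assert (tmp_path / "sp.csv.json").exists()
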