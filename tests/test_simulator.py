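"""Integrator, Poisson drive, delayed delivery, and run-level contracts."""

import numpy as np
import pytest

from spikecompete.netgen import (
    EXCITATORY,
    NetworkConfig,
    NetworkTopology,
    build_network,
    make_fixture,
)
from spikecompete.plasticity import STDPConfig, nearest_neighbor_sd
from spikecompete.simulator import (
    PoissonDriveConfig,
    poisson_input_mask,
    run_simulation,
    step_neuron,
)


class TestStepNeuron:
    def test_resting_fixed_point_is_preserved(self):
        # v* = -70, u* = b v* solves 0.04 v^2 + 5 v + 140 - u = 0
        v, u, fired = step_neuron(-70.0, -14.0, EXCITATORY, 0.0)
        assert not fired
        assert v == pytest.approx(-70.0, abs=1e-6)
        assert u == pytest.approx(-14.0, abs=1e-6)

    def test_threshold_reset(self):
        v, u, fired = step_neuron(30.0, -5.0, EXCITATORY, 0.0)
        assert fired
        assert v == -65.0
        assert u == pytest.approx(-5.0 + 8.0)

    def test_suprathreshold_drive_fires_within_100_ms(self):
        v, u = -70.0, -14.0
        fired_any = False
        for _ in range(100):
            v, u, fired = step_neuron(v, u, EXCITATORY, 20.0)
            fired_any = fired_any or fired
        assert fired_any

    def test_invalid_dt_rejected(self):
        with pytest.raises(ValueError):
            step_neuron(-70.0, -14.0, EXCITATORY, 0.0, dt=0.3)


class TestPoissonDrive:
    def test_zero_rate_never_spikes(self, rng):
        assert not poisson_input_mask(0.0, 1000, 10, rng).any()

    def test_empirical_rate_matches(self, rng):
        n = 1_000_000
        mask = poisson_input_mask(10.0, 1000, 1000, rng)
        p = 10.0 / 1000.0
        se = np.sqrt(p * (1 - p) / n)
        assert abs(mask.mean() - p) < 3 * se

    def test_streams_uncorrelated_across_neurons(self, rng):
        mask = poisson_input_mask(40.0, 100_000, 2, rng).astype(float)
        r = np.corrcoef(mask[:, 0], mask[:, 1])[0, 1]
        assert abs(r) < 0.01

    def test_rates_at_or_above_1khz_rejected(self):
        with pytest.raises(ValueError):
            PoissonDriveConfig(rate=1000.0).validate()
        with pytest.raises(ValueError):
            PoissonDriveConfig(rate=-1.0).validate()


def _forced_input(duration_ms, n, spikes):
    """Input mask with 20-mV pulses at the given (t, neuron) pairs."""
    mask = np.zeros((duration_ms, n), dtype=bool)
    for t, j in spikes:
        mask[t, j] = True
    return mask


class TestDelayedDelivery:
    @pytest.mark.parametrize("delay", [1, 5])
    def test_delivery_lag_tracks_the_conduction_delay(self, delay):
        # a single 20-mV delivery is suprathreshold from rest, so the
        # target's response time shifts one-for-one with the delay
        topo = NetworkTopology(
            n_neurons=2, n_excitatory=2,
            pre=[0], post=[1], weight=[20.0], delay=[delay], plastic=[True],
        )
        spikes = [(t, 0) for t in range(100, 900, 100)]
        res = run_simulation(
            topo, 0.0, duration_s=1, input_spikes=_forced_input(1000, 2, spikes)
        )
        t0 = res.raster.spike_times(0)
        t1 = res.raster.spike_times(1)
        assert len(t0) > 0 and len(t1) == len(t0)
        lags = t1 - t0
        # delivery at t0 + delay, then a few ms of integration to threshold
        assert lags.min() >= delay + 2
        assert lags.max() <= delay + 8

    def test_simultaneous_arrivals_sum_linearly(self):
        # two afferents with weight 10 each: one alone cannot drive the
        # target from rest, both together (20 mV in one bin) can
        def net(weights):
            return NetworkTopology(
                n_neurons=3,
                n_excitatory=3,
                pre=[0, 1],
                post=[2, 2],
                weight=weights,
                delay=[1, 1],
                plastic=[True, True],
            )

        both = [(t, j) for t in range(50, 950, 40) for j in (0, 1)]
        one = [(t, 0) for t in range(50, 950, 40)]
        res_both = run_simulation(
            net([10.0, 10.0]), 0.0, duration_s=1, input_spikes=_forced_input(1000, 3, both)
        )
        res_one = run_simulation(
            net([10.0, 10.0]), 0.0, duration_s=1, input_spikes=_forced_input(1000, 3, one)
        )
        assert len(res_both.raster.spike_times(2)) > 0
        assert len(res_one.raster.spike_times(2)) == 0

    def test_inhibitory_arrival_subtracts(self):
        # neuron 2 (inhibitory) vetoes the excitatory pulse when its
        # -5-mV arrival coincides with a +20-mV excitatory arrival
        topo = NetworkTopology(
            n_neurons=3,
            n_excitatory=2,
            pre=[0, 2],
            post=[1, 1],
            weight=[20.0, -5.0],
            delay=[1, 1],
            plastic=[True, False],
        )
        # make both sources fire: feed them strong input at the same times
        spikes = [(t, j) for t in range(100, 900, 50) for j in (0, 2)]
        res = run_simulation(topo, 0.0, duration_s=1, input_spikes=_forced_input(1000, 3, spikes))
        with_inh = len(res.raster.spike_times(1))
        topo_noinh = NetworkTopology(
            n_neurons=3, n_excitatory=2, pre=[0], post=[1], weight=[20.0], delay=[1],
            plastic=[True],
        )
        res2 = run_simulation(
            topo_noinh, 0.0, duration_s=1, input_spikes=_forced_input(1000, 3, spikes)
        )
        without_inh = len(res2.raster.spike_times(1))
        assert without_inh > with_inh


class TestRunContracts:
    def test_zero_drive_network_stays_silent(self):
        topo = build_network(NetworkConfig(rng_seed=0))
        res = run_simulation(topo, 0.0, duration_s=10)
        assert res.raster.n_spikes == 0

    def test_identical_seeds_give_identical_runs(self):
        topo = build_network(NetworkConfig(rng_seed=4))
        a = run_simulation(topo, 10.0, stdp=STDPConfig(), duration_s=3, seed=99)
        b = run_simulation(topo, 10.0, stdp=STDPConfig(), duration_s=3, seed=99)
        assert np.array_equal(a.raster.times, b.raster.times)
        assert np.array_equal(a.raster.ids, b.raster.ids)
        assert np.array_equal(a.weights, b.weights)

    def test_weights_constant_without_stdp(self):
        topo = build_network(NetworkConfig(rng_seed=4))
        res = run_simulation(topo, 10.0, stdp=None, duration_s=3, seed=5)
        assert np.array_equal(res.weights, topo.weight)
        assert res.raster.n_spikes > 0

    def test_no_neuron_fires_twice_in_one_millisecond(self):
        topo = build_network(NetworkConfig(rng_seed=4))
        res = run_simulation(topo, 40.0, stdp=STDPConfig(), duration_s=3, seed=5)
        key = res.raster.times.astype(np.int64) * 1000 + res.raster.ids
        assert len(np.unique(key)) == len(key)

    def test_firing_rate_stays_finite_at_10hz_drive(self):
        topo = build_network(NetworkConfig(rng_seed=4))
        res = run_simulation(topo, 10.0, stdp=STDPConfig(), duration_s=10, seed=5)
        assert np.all(res.exc_spikes_per_s / 800 < 100.0)
        assert res.exc_spikes_per_s[-1] > 0

    def test_raster_window_restricts_recording(self):
        topo = build_network(NetworkConfig(rng_seed=4))
        res = run_simulation(
            topo, 10.0, duration_s=3, seed=5, raster_windows=[(1.0, 2.0)]
        )
        assert res.raster.n_spikes > 0
        assert res.raster.times.min() >= 1000
        assert res.raster.times.max() < 2000

    def test_invalid_duration_rejected(self):
        topo = make_fixture("chain3")
        with pytest.raises(ValueError):
            run_simulation(topo, 10.0, duration_s=0)


class TestSTDPIntegration:
    """The kernel's event bookkeeping against the event-replay reference."""

    def _two_neuron_net(self, delay):
        return NetworkTopology(
            n_neurons=2,
            n_excitatory=2,
            pre=[0],
            post=[1],
            weight=[6.0],
            delay=[delay],
            plastic=[True],
        )

    @pytest.mark.parametrize("delay", [1, 3, 7])
    def test_weight_change_matches_event_replay(self, delay):
        """Arrival times are somatic times + delay; sd replay reproduces
        the committed weight exactly (single commit, no decay carryover)."""
        topo = self._two_neuron_net(delay)
        # fire 0 and 1 at staggered times via strong external pulses
        spikes = [(t, 0) for t in range(100, 900, 100)]
        spikes += [(t, 1) for t in range(137, 900, 100)]
        cfg = STDPConfig()
        res = run_simulation(
            topo, 0.0, stdp=cfg, duration_s=1, input_spikes=_forced_input(1000, 2, spikes)
        )
        arrivals = res.raster.spike_times(0).astype(float) + delay
        posts = res.raster.spike_times(1).astype(float)
        sd = nearest_neighbor_sd(arrivals, posts, cfg, coincident="potentiate")
        expected = float(np.clip(6.0 + cfg.drift_add + sd, 0, cfg.w_max))
        assert res.weights[0] == pytest.approx(expected, abs=1e-12)

    def test_event_conservation_via_terminal_raster(self):
        """Every somatic spike yields exactly outdegree terminal events."""
        from spikecompete.signal import presynaptic_terminal_raster

        topo = build_network(NetworkConfig(n_neurons=60, rng_seed=9))
        res = run_simulation(topo, 30.0, duration_s=2, seed=11)
        n_exc = topo.n_excitatory
        total_terminal = 0
        for j in range(n_exc):
            events, _ = presynaptic_terminal_raster(res.raster, topo, j)
            total_terminal += len(events)
        # sum over E->E synapses of the presynaptic spike counts
        expected = sum(
            len(res.raster.spike_times(p)) for p in topo.pre[topo.plastic]
        )
        assert total_terminal == expected
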