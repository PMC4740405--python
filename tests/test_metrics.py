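"""Degrees, strengths, edge-end correlations, labels, delay statistics."""

import numpy as np
import pandas as pd
import pytest

from spikecompete.metrics import (
    DegenerateStrengthsError,
    assembly_switches,
    degrees,
    delay_profile,
    identify_winners,
    joint_distribution,
    strength_correlation,
    strength_table,
    strengths,
    weight_by_delay,
)
from spikecompete.netgen import NetworkConfig, NetworkTopology, build_network


def brute_force_edge_correlation(topology, weights, which, w_max=10.0):
    """Double-loop oracle for the edge-end strength correlation."""
    n = topology.n_excitatory
    s_in = np.zeros(n)
    s_out = np.zeros(n)
    edges = []
    for p, q, w, pl in zip(topology.pre, topology.post, weights, topology.plastic):
        if not pl:
            continue
        s_in[q] += w / w_max
        s_out[p] += w / w_max
        if w > 0:
            edges.append((p, q))
    s = s_in if which == "in" else s_out
    tails = np.array([s[p] for p, _ in edges])
    heads = np.array([s[q] for _, q in edges])
    return float(
        ((tails - tails.mean()) * (heads - heads.mean())).mean()
        / (tails.std() * heads.std())
    )


class TestDegreesAndStrengths:
    def test_star5_hub(self, star5):
        k_in, k_out = degrees(star5)
        assert k_in[0] == 4 and k_out[0] == 0

    def test_zero_weights_do_not_count(self, star5):
        k_in, k_out = degrees(star5, np.zeros(star5.n_synapses))
        assert not k_in.any() and not k_out.any()

    def test_mean_indegree_matches_binomial_expectation(self):
        topo = build_network(NetworkConfig(rng_seed=21))
        k_in, _ = degrees(topo)
        expected = 799 * 0.1
        sd_of_mean = np.sqrt(799 * 0.1 * 0.9 / 800)
        assert abs(k_in.mean() - expected) < 4 * sd_of_mean

    def test_chain3_strengths(self, chain3):
        s_in, s_out = strengths(chain3, w_max=10.0)
        assert s_in[1] == pytest.approx(1.0)  # 10 / 10
        assert s_out[1] == pytest.approx(0.5)  # 5 / 10

    def test_uniform_weights_make_strength_proportional_to_degree(self):
        topo = build_network(NetworkConfig(n_neurons=200, rng_seed=3))
        k_in, k_out = degrees(topo)
        s_in, s_out = strengths(topo, w_max=10.0)
        np.testing.assert_allclose(s_in, 0.6 * k_in)
        np.testing.assert_allclose(s_out, 0.6 * k_out)

    def test_loop4_hand_sums(self, loop4):
        s_in, s_out = strengths(loop4, w_max=10.0)
        # 0 -> 1 (9), 1 -> 2 (6), 2 -> 3 (3), 3 -> 0 (1)
        assert s_in.tolist() == [0.1, 0.9, 0.6, 0.3]
        assert s_out.tolist() == [0.9, 0.6, 0.3, 0.1]

    def test_strength_bounded_by_degree(self):
        topo = build_network(NetworkConfig(n_neurons=300, rng_seed=8))
        k_in, k_out = degrees(topo)
        s_in, s_out = strengths(topo, w_max=10.0)
        assert np.all(s_in <= k_in + 1e-12)
        assert np.all(s_out <= k_out + 1e-12)


class TestStrengthCorrelation:
    def test_identical_strengths_are_degenerate(self, loop4):
        # in a directed cycle with equal weights every neuron has the
        # same s_in and s_out
        w = np.full(4, 5.0)
        with pytest.raises(DegenerateStrengthsError):
            strength_correlation(loop4, w, which="in")

    def test_initial_random_network_is_uncorrelated(self):
        rs = []
        for seed in range(20):
            topo = build_network(NetworkConfig(rng_seed=300 + seed))
            rs.append(strength_correlation(topo, which="in"))
            rs.append(strength_correlation(topo, which="out"))
        assert np.all(np.abs(rs) < 0.05)

    @pytest.mark.parametrize("which", ["in", "out"])
    def test_matches_brute_force_oracle(self, which, rng):
        topo = build_network(
            NetworkConfig(n_neurons=10, excitatory_fraction=0.8, connection_probability=0.6,
                          rng_seed=5)
        )
        w = topo.weight.copy()
        w[topo.plastic] = rng.uniform(0.0, 10.0, int(topo.plastic.sum()))
        w[topo.plastic] *= rng.random(int(topo.plastic.sum())) > 0.2  # prune some
        got = strength_correlation(topo, w, which=which)
        want = brute_force_edge_correlation(topo, w, which)
        assert got == pytest.approx(want, abs=1e-12)
        assert -1.0 <= got <= 1.0

    def test_invariant_under_neuron_relabeling(self, rng):
        topo = build_network(NetworkConfig(n_neurons=50, rng_seed=6))
        w = topo.weight.copy()
        w[topo.plastic] = rng.uniform(0.1, 9.9, int(topo.plastic.sum()))
        r0 = strength_correlation(topo, w, which="in")
        perm = np.concatenate([rng.permutation(topo.n_excitatory),
                               np.arange(topo.n_excitatory, topo.n_neurons)])
        topo2 = NetworkTopology(
            n_neurons=topo.n_neurons,
            n_excitatory=topo.n_excitatory,
            pre=perm[topo.pre],
            post=perm[topo.post],
            weight=w,
            delay=topo.delay,
            plastic=topo.plastic,
        )
        assert strength_correlation(topo2, w, which="in") == pytest.approx(r0, abs=1e-12)

    def test_too_few_synapses_rejected(self, chain3):
        with pytest.raises(DegenerateStrengthsError):
            strength_correlation(chain3, np.array([10.0, 0.0]), which="in")


def _table(s_in, s_out):
    return pd.DataFrame({
        "k_in": np.ones(len(s_in)), "k_out": np.ones(len(s_in)),
        "s_in": s_in, "s_out": s_out,
    })


class TestWinnerIdentification:
    def test_two_neuron_definition(self):
        win = identify_winners(_table([2.0, 1.0], [1.0, 2.0]))
        assert win.tolist() == [True, False]

    def test_all_winners_when_no_neuron_qualifies(self):
        win = identify_winners(_table([3.0, 2.0, 1.0], [1.0, 1.0, 0.5]))
        assert win.all()

    def test_five_neuron_hand_walkthrough(self):
        # descending s_in order: n0 (5, 1) W, n3 (4, 2) W, n1 (3, 9) ->
        # first with s_in < s_out: threshold; n4 (2, 1) and n2 (1, 2)
        # follow it, so they are losers regardless of their own margins
        s_in = [5.0, 3.0, 1.0, 4.0, 2.0]
        s_out = [1.0, 9.0, 2.0, 2.0, 1.0]
        win = identify_winners(_table(s_in, s_out))
        assert win.tolist() == [True, False, False, True, False]

    def test_tie_falls_on_loser_side(self):
        win = identify_winners(_table([2.0, 1.0], [2.0, 0.5]))
        assert win.tolist() == [False, False]

    def test_margin_rule_is_per_neuron(self):
        s_in = [5.0, 3.0, 1.0, 4.0, 2.0]
        s_out = [1.0, 9.0, 2.0, 2.0, 1.0]
        win = identify_winners(_table(s_in, s_out), rule="margin")
        assert win.tolist() == [True, False, False, True, True]

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            identify_winners(_table([1.0], [0.0]), rule="sideways")


class TestAssemblySwitches:
    def test_identical_labelings(self):
        lab = np.array([True, False, True])
        assert assembly_switches(lab, lab) == (0, 0)

    def test_single_flip_percentage(self):
        a = np.zeros(800, dtype=bool)
        a[:100] = True
        b = a.copy()
        b[5] = False
        wl, lw = assembly_switches(a, b)
        assert (wl, lw) == (1, 0)
        assert 100.0 * wl / 800 == pytest.approx(0.125)

    def test_three_flips_match_reported_percentage(self):
        a = np.zeros(800, dtype=bool)
        a[:100] = True
        b = a.copy()
        b[[100, 101, 102]] = True
        wl, lw = assembly_switches(a, b)
        assert (wl, lw) == (0, 3)
        assert round(100.0 * lw / 800, 2) == 0.38

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            assembly_switches(np.array([True]), np.array([True, False]))


class TestDelayStatistics:
    def test_afferent_fraction_counting(self):
        topo = NetworkTopology(
            n_neurons=4, n_excitatory=4,
            pre=[1, 2, 3], post=[0, 0, 0],
            weight=[5.0, 5.0, 5.0], delay=[1, 1, 2],
            plastic=[True, True, True],
        )
        prof = delay_profile(topo, winners=np.array([True, False, False, False]))
        np.testing.assert_allclose(prof.loc["winner"][:3], [2 / 3, 1 / 3, 0.0])

    def test_group_fractions_sum_to_one(self, baseline_10hz_run):
        rec = baseline_10hz_run
        win = identify_winners(rec.strength_table())
        prof = delay_profile(rec.topology, win, rec.final_weights)
        assert prof.loc["winner"].sum() == pytest.approx(1.0)
        assert prof.loc["loser"].sum() == pytest.approx(1.0)

    def test_single_synapse_mean(self):
        topo = NetworkTopology(
            n_neurons=2, n_excitatory=2,
            pre=[0], post=[1], weight=[7.0], delay=[3], plastic=[True],
        )
        wd = weight_by_delay(topo, winners=np.array([False, True]))
        assert wd.loc["winner", 3] == 7.0
        assert np.isnan(wd.loc["winner", 1])


class TestJointDistribution:
    def test_single_neuron_single_bin(self):
        jd = joint_distribution(_table([1.0], [2.0]))
        assert jd.counts.sum() == 1
        assert (jd.counts > 0).sum() == 1

    def test_counts_conserve_population(self, baseline_10hz_run):
        table = baseline_10hz_run.strength_table()
        jd = joint_distribution(table)
        assert jd.n_neurons == 800

    def test_degree_mode(self):
        tab = _table([1.0, 2.0], [2.0, 1.0])
        jd = joint_distribution(tab, mode="degree", bins=5)
        assert jd.counts.sum() == 2
        with pytest.raises(ValueError):
            joint_distribution(tab, mode="sideways")


def test_strength_table_labels_partition_population(baseline_10hz_run):
    table = baseline_10hz_run.strength_table()
    assert set(table["label"].unique()) <= {"winner", "loser"}
    assert len(table) == 800
    assert (table["label"] == "winner").sum() + (table["label"] == "loser").sum() == 800
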