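"""Tournament updates, structural operators and the full evolution loop."""

import math
import random

import pytest

from pathevo.benchmarks import counting_ones_fitness, FitnessFunction
from pathevo.engine import (
    A_WINS,
    B_WINS,
    TIE,
    PEAConfig,
    crossover_two_point,
    mutate_bypass,
    prune,
    run_pea,
    select_winner,
    tournament_update,
)
from pathevo.network import LayeredPathNetwork, init_network

from conftest import build_two_path_net


def one_branch_net(w_loser=0.75):
    """Single-locus branch: loser edge w_loser, winner edge 1 - w_loser."""
    net = LayeredPathNetwork(1)
    win = net.add_node(1, 1)
    lose = net.add_node(1, 0)
    net.add_edge(net.start, win, 1.0 - w_loser)
    net.add_edge(net.start, lose, w_loser)
    return net, (net.start, win), (net.start, lose)


class TestTournamentUpdate:
    def test_worked_example_071_029(self):
        """0.75 loser / 0.25 winner with lambda=0.1 renormalizes to
        0.71 / 0.29 at two decimals."""
        net, (s, win), (_, lose) = one_branch_net()
        tournament_update(net, (s, win), (s, lose), lam=0.1)
        assert round(net.edge_weight(s, lose), 2) == 0.71
        assert round(net.edge_weight(s, win), 2) == 0.29
        assert net.edge_weight(s, lose) == pytest.approx(0.675 / 0.95)

    def test_identical_paths_noop(self, two_path_net):
        (pa, _), (pb, _) = two_path_net.enumerate_paths()
        before = two_path_net.to_text()
        assert tournament_update(two_path_net, pa, pa, 0.1) == set()
        assert two_path_net.to_text() == before

    def test_lambda_small_is_near_identity(self):
        net, e_w, e_l = one_branch_net()
        tournament_update(net, e_w, e_l, lam=1e-12)
        assert net.edge_weight(*e_l) == pytest.approx(0.75, abs=1e-9)

    def test_shared_edges_untouched_vs_punished(self, two_path_net):
        paths = [p for p, _ in two_path_net.enumerate_paths()]
        green = max(paths, key=two_path_net.path_probability)
        pink = min(paths, key=two_path_net.path_probability)
        shared = (green[0], green[1])
        net2 = build_two_path_net()
        tournament_update(two_path_net, green, pink, 0.1,
                          punish_shared=False)
        assert two_path_net.edge_weight(*shared) == 1.0
        tournament_update(net2, green, pink, 0.1, punish_shared=True)
        # sole outflow: renormalizes back to 1 even after punishment
        assert net2.edge_weight(*shared) == pytest.approx(1.0)

    def test_renormalized_nodes_reported(self, two_path_net):
        paths = [p for p, _ in two_path_net.enumerate_paths()]
        touched = tournament_update(two_path_net, paths[0], paths[1], 0.1)
        two_path_net.validate()
        assert touched  # only branch nodes renormalized
        for u in touched:
            assert abs(sum(two_path_net.out_w[u]) - 1.0) < 1e-9


class TestSelectWinner:
    @pytest.mark.parametrize("ra,rb,minimize,expect", [
        (3.0, 2.0, False, A_WINS),
        (3.0, 2.0, True, B_WINS),
        (2.0, 2.0, False, TIE),
        (2.0, 2.0, True, TIE),
        (-1.0, -2.0, False, A_WINS),
    ])
    def test_outcomes(self, ra, rb, minimize, expect):
        assert select_winner(ra, rb, minimize) == expect

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            select_winner(float("nan"), 1.0)


class TestMutateBypass:
    def test_mu_zero_unchanged(self, rng):
        net = init_network(1, 6, rng=rng)
        (path, _), = net.enumerate_paths()
        before = net.to_text()
        applied, skipped, touched = mutate_bypass(net, path, 0.0, 0.01, rng)
        assert (applied, skipped, touched) == (0, 0, set())
        assert net.to_text() == before

    def test_mu_one_bypass_structure(self, rng):
        """Certain mutation with pure bypass events: one new node per layer,
        outflows stay normalized."""
        net = init_network(1, 4, max_nodes_per_layer=4, rng=rng)
        (path, _), = net.enumerate_paths()
        applied, skipped, _ = mutate_bypass(net, path, 1.0, 0.01, rng,
                                            attach_prob=0.0)
        assert applied == 4 and skipped == 0
        assert net.n_nodes == 9
        net.validate()
        # each new weak in-edge sits exactly at omega post-normalization
        for layer in range(1, 5):
            new = [n for n in net.layers[layer] if n not in path]
            assert len(new) == 1

    def test_new_phenotype_is_one_step_from_parent(self, two_path_net):
        rng = random.Random(3)
        paths = [p for p, _ in two_path_net.enumerate_paths()]
        green = max(paths, key=two_path_net.path_probability)
        parent_ph = two_path_net.phenotype_of(green)
        # force one bypass mutation at some layer
        applied = 0
        while applied == 0:
            applied, _, _ = mutate_bypass(two_path_net, green, 0.25, 0.01,
                                          rng, attach_prob=0.0)
        # a bypass upstream of a branch adds one route per downstream
        # alternative (two new paths when it precedes the fork)
        paths_after = [p for p, _ in two_path_net.enumerate_paths()]
        assert len(paths_after) > 2
        old_phs = {two_path_net.phenotype_of(p) for p in paths}
        new_phs = {two_path_net.phenotype_of(p)
                   for p in paths_after} - old_phs
        # every new phenotype is one mutational step from an existing one
        for ph in new_phs:
            assert min(sum(a != b for a, b in zip(ph, old))
                       for old in old_phs) == 1

    def test_attachment_reuses_existing_node(self, rng):
        net = init_network(2, 3, max_nodes_per_layer=2, rng=rng)
        (pa, _), (pb, _) = net.enumerate_paths()
        applied, skipped, _ = mutate_bypass(net, pa, 1.0, 0.01, rng,
                                            attach_prob=1.0)
        assert applied == 3       # every layer at cap -> all attachments
        assert net.n_nodes == 7   # no node creation
        net.validate()
        assert len(net.enumerate_paths()) > 2

    def test_continuous_mutant_near_parent(self):
        rng = random.Random(5)
        net = init_network(1, 30, scheme="continuous", rng=rng)
        (path, _), = net.enumerate_paths()
        parent = net.phenotype_of(path)
        mutate_bypass(net, path, 1.0, 0.01, rng, mutation_sd=0.1,
                      attach_prob=0.0)
        for layer in range(1, 31):
            new = [n for n in net.layers[layer] if n not in path]
            diffs = [abs(net.label[n] - parent[layer - 1]) for n in new]
            assert all(d < 1.0 for d in diffs)
        # Gaussian with sd 0.1: typical deviations are small
        all_new = [abs(net.label[n] - parent[l - 1])
                   for l in range(1, 31) for n in net.layers[l]
                   if n not in path]
        assert sorted(all_new)[len(all_new) // 2] < 0.2


class TestCrossover:
    def test_chi_zero_never_applies(self, rng):
        net = init_network(2, 4, rng=rng)
        (pa, _), (pb, _) = net.enumerate_paths()
        applied, touched = crossover_two_point(net, pa, pb, 0.0, 0.01, rng)
        assert not applied and not touched

    def test_two_new_edges_make_hybrid_paths(self, rng):
        net = init_network(2, 4, rng=rng)
        (pa, _), (pb, _) = net.enumerate_paths()
        n_before = len(net.enumerate_paths())
        applied, touched = crossover_two_point(net, pa, pb, 1.0, 0.01, rng)
        assert applied
        net.validate()
        assert len(net.enumerate_paths()) > n_before

    def test_short_paths_skipped_with_warning(self, rng):
        net = init_network(2, 2, rng=rng)
        (pa, _), (pb, _) = net.enumerate_paths()
        with pytest.warns(UserWarning):
            applied, _ = crossover_two_point(net, pa, pb, 1.0, 0.01, rng)
        assert not applied


class TestPrune:
    def test_fresh_network_untouched(self, rng):
        net = init_network(5, 5, rng=rng)
        assert prune(net, generation=0, tau=1, omega=0.01) == (0, 0)
        net.validate()

    def test_idle_node_removed_other_survives(self):
        net = LayeredPathNetwork(1)
        a = net.add_node(1, 0, generation=0)
        b = net.add_node(1, 1, generation=0)
        net.add_edge(net.start, a, 0.9)
        net.add_edge(net.start, b, 0.1)
        net.last_active[a] = 50
        nodes_removed, _ = prune(net, generation=51, tau=5, omega=1e-6)
        assert nodes_removed == 1
        assert b not in net.layer_of and a in net.layer_of
        assert net.out_w[net.start] == [1.0]
        net.validate()

    def test_sub_threshold_edge_removed_and_chain_culled(self):
        net = LayeredPathNetwork(2)
        a = net.add_node(1, 0)
        b = net.add_node(1, 1)
        a2 = net.add_node(2, 0)
        b2 = net.add_node(2, 1)
        net.add_edge(net.start, a, 0.995)
        net.add_edge(net.start, b, 0.005)
        net.add_edge(a, a2, 1.0)
        net.add_edge(b, b2, 1.0)
        nodes_removed, edges_removed = prune(net, 0, tau=1000, omega=0.01)
        assert edges_removed == 1
        assert nodes_removed == 2          # b unreachable, b2 orphaned
        assert net.out_w[net.start] == [1.0]
        paths = net.enumerate_paths()
        assert len(paths) == 1 and paths[0][1] == 1.0

    def test_never_strips_sole_layer_node(self):
        net = LayeredPathNetwork(1)
        a = net.add_node(1, 0, generation=0)
        net.add_edge(net.start, a, 1.0)
        assert prune(net, generation=10_000, tau=1, omega=0.01) == (0, 0)
        net.validate()


class TestRunPEA:
    def test_counting_ones_reaches_optimum(self):
        """Hill-climbable objective: every seed reaches the maximum."""
        for seed in range(10):
            cfg = PEAConfig(N=1, L=10, lam=0.1, mu=0.1, generations=2000,
                            seed=seed, stop_at_target=True)
            tr = run_pea(cfg, counting_ones_fitness(10))
            assert tr.final_best == 10.0, f"seed {seed}"

    def test_no_variation_constant_trace(self, rng):
        cfg = PEAConfig(N=1, L=6, mu=0.0, chi=0.0, generations=200, seed=1)
        tr = run_pea(cfg, counting_ones_fitness(6))
        assert len(set(tr.best)) == 1
        assert tr.best[0] == tr.reward_a[0]

    def test_constant_fitness_never_changes_weights_without_drift(self):
        """With tie-breaking drift disabled, tied tournaments leave every
        weight untouched."""
        flat = FitnessFunction("flat", "binary", lambda s, g: 1.0)
        cfg = PEAConfig(N=4, L=5, mu=0.0, generations=500, seed=2,
                        tie_break="none")
        tr = run_pea(cfg, flat)
        ws = tr.network.out_w[tr.network.start]
        assert ws == pytest.approx([0.25] * 4)

    def test_constant_fitness_drifts_under_random_tie_break(self):
        """Random tie resolution turns tied tournaments into neutral drift
        of the transition probabilities (no systematic direction)."""
        flat = FitnessFunction("flat", "binary", lambda s, g: 1.0)
        cfg = PEAConfig(N=4, L=5, mu=0.0, generations=500, seed=2,
                        tie_break="random", prune_threshold=1e-12)
        tr = run_pea(cfg, flat)
        ws = tr.network.out_w[tr.network.start]
        assert ws != pytest.approx([0.25] * 4)
        assert sum(ws) == pytest.approx(1.0)

    def test_best_so_far_monotone(self):
        cfg = PEAConfig(N=5, L=12, mu=0.05, generations=1500, seed=3)
        tr = run_pea(cfg, counting_ones_fitness(12))
        assert all(b <= a for b, a in zip(tr.best, tr.best[1:]))

    def test_reproducible_from_seed(self):
        cfg = PEAConfig(N=3, L=8, mu=0.05, chi=0.1, generations=400, seed=9)
        f = counting_ones_fitness(8)
        t1, t2 = run_pea(cfg, f), run_pea(cfg, f)
        assert t1.best == t2.best
        assert t1.network.to_text() == t2.network.to_text()

    def test_outflows_normalized_after_run(self):
        cfg = PEAConfig(N=4, L=10, mu=0.05, chi=0.05, generations=1000,
                        seed=4)
        tr = run_pea(cfg, counting_ones_fitness(10))
        tr.network.validate()

    def test_minimization_sense(self):
        fit = FitnessFunction("ones_min", "binary",
                              lambda s, g: float(sum(s)), minimize=True,
                              optimum=0.0)
        cfg = PEAConfig(N=1, L=8, mu=0.1, generations=2000, seed=5,
                        stop_at_target=True)
        tr = run_pea(cfg, fit)
        assert tr.final_best == 0.0


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        {"lam": 0.0}, {"lam": 1.0}, {"mu": 1.5}, {"omega": 0.0},
        {"tau": 0}, {"N": 0}, {"mutant_label": "invert"},
    ])
    def test_invalid_rejected(self, kw):
        with pytest.raises(ValueError):
            PEAConfig(**kw)

    def test_rho_warns_if_nonzero(self):
        with pytest.warns(UserWarning):
            PEAConfig(rho=0.5)
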