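import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from moranfix.closed_forms import phi_wellmixed_bd
from moranfix.graphs import (
    ErParams,
    Graph,
    complete_graph,
    cycle_graph,
    directed_line,
    generate_er,
    star_graph,
)
from moranfix.markov import (
    build_canonical_matrix,
    fixation_probabilities,
    fixation_with_shortcuts,
    full_matrix_entries,
    replacement_weights,
    simulate_fixation,
    step_distribution,
)

from conftest import sample_connected


def _random_connected(n, p, seed):
    return sample_connected(n, p, 1, seed)[0]


class TestReplacementWeights:
    def test_bd_star_hub_spreads_uniformly(self):
        g = star_graph(5)
        w = replacement_weights(g, "Bd")
        for leaf in range(1, 5):
            assert w[(0, leaf)] == pytest.approx(0.25)
            assert w[(leaf, 0)] == pytest.approx(1.0)

    def test_bd_cycle_all_half(self):
        w = replacement_weights(cycle_graph(4), "Bd")
        assert all(v == pytest.approx(0.5) for v in w.values())

    def test_bd_directed_line(self):
        w = replacement_weights(directed_line(2), "Bd")
        assert w == {(0, 1): pytest.approx(1.0)}

    def test_db_normalizes_over_incoming(self):
        g = star_graph(5)
        w = replacement_weights(g, "dB")
        # hub has 4 in-neighbors, each equally likely at neutrality
        for leaf in range(1, 5):
            assert w[(leaf, 0)] == pytest.approx(0.25)
            assert w[(0, leaf)] == pytest.approx(1.0)

    def test_db_refuses_in_degree_zero(self):
        with pytest.raises(ValueError, match="in-degree zero"):
            replacement_weights(directed_line(3), "dB")


class TestStepDistribution:
    def test_absorbing_states_self_loop(self):
        g = cycle_graph(4)
        for rule in ("Bd", "dB"):
            assert step_distribution(g, 0, 1.5, rule) == {0: 1.0}
            assert step_distribution(g, 0b1111, 1.5, rule) == {0b1111: 1.0}

    @pytest.mark.parametrize("r", [0.5, 1.0, 2.0])
    def test_pair_bd_matches_hand_computation(self, r):
        g = Graph(2, {(0, 1)})
        dist = step_distribution(g, 0b01, r, "Bd")
        assert dist[0b11] == pytest.approx(r / (r + 1))
        assert dist[0b00] == pytest.approx(1 / (r + 1))

    def test_cycle4_db_single_mutant_rates(self):
        # gain: one of the two flanking wild-types dies (2/4) and the mutant
        # wins with probability r/(r+1); loss: the mutant dies (1/4)
        r = 1.5
        dist = step_distribution(cycle_graph(4), 0b0001, r, "dB")
        gain = sum(p for s, p in dist.items() if bin(s).count("1") == 2)
        loss = dist.get(0, 0.0)
        assert gain == pytest.approx(0.5 * r / (r + 1))
        assert loss == pytest.approx(0.25)

    def test_rejects_nonpositive_fitness(self):
        with pytest.raises(ValueError):
            step_distribution(cycle_graph(4), 1, 0.0, "Bd")

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        n=st.integers(2, 6),
        seed=st.integers(0, 2**20),
        config=st.integers(1, 62),
        r=st.floats(0.25, 4.0),
        rule=st.sampled_from(["Bd", "dB"]),
    )
    def test_distribution_sums_to_one(self, n, seed, config, r, rule):
        g = _random_connected(n, 0.6, seed)
        config &= (1 << n) - 1
        if config == 0:
            config = 1
        dist = step_distribution(g, config, r, rule)
        assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)
        assert all(0 <= p <= 1 + 1e-12 for p in dist.values())


class TestCanonicalMatrix:
    def test_pair_blocks(self):
        r = 1.5
        model = build_canonical_matrix(Graph(2, {(0, 1)}), r, "Bd")
        assert model.n_transient == 2
        Q = model.transient_block.toarray()
        assert Q == pytest.approx(np.zeros((2, 2)))
        assert model.absorption_block[0] == pytest.approx(
            [1 / (r + 1), r / (r + 1)]
        )

    def test_transient_count(self):
        model = build_canonical_matrix(cycle_graph(4), 1.25, "dB")
        assert model.n_transient == 14

    def test_full_matrix_entry_count(self):
        assert full_matrix_entries(14) == 2**28

    @pytest.mark.parametrize("rule", ["Bd", "dB"])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rows_sum_to_one(self, rule, seed):
        g = _random_connected(6, 0.5, seed)
        model = build_canonical_matrix(g, 1.75, rule)
        assert np.abs(model.row_sums() - 1.0).max() < 1e-12

    @pytest.mark.parametrize("rule", ["Bd", "dB"])
    def test_matrix_rows_match_step_distribution(self, rule):
        """Dual route: the vectorized assembly must agree state-by-state
        with the scalar per-configuration distribution."""
        g = _random_connected(5, 0.5, seed=9)
        r = 1.25
        model = build_canonical_matrix(g, r, rule)
        full = (1 << 5) - 1
        Q = model.transient_block.toarray()
        R = model.absorption_block
        for config in range(1, full):
            dist = step_distribution(g, config, r, rule)
            row = config - 1
            for target, p in dist.items():
                if target == 0:
                    assert R[row, 0] == pytest.approx(p)
                elif target == full:
                    assert R[row, 1] == pytest.approx(p)
                else:
                    assert Q[row, target - 1] == pytest.approx(p)


class TestFixationProbabilities:
    def test_complete_graph_matches_closed_form(self):
        model = build_canonical_matrix(complete_graph(4), 2.0, "Bd")
        res = fixation_probabilities(model)
        assert res.uniform_avg == pytest.approx(8 / 15, abs=1e-10)

    @pytest.mark.parametrize("rule", ["Bd", "dB"])
    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_neutral_fixation_is_one_over_n(self, rule, seed):
        g = _random_connected(6, 0.5, seed)
        res = fixation_probabilities(build_canonical_matrix(g, 1.0, rule))
        assert res.uniform_avg == pytest.approx(1 / 6, abs=1e-9)

    @pytest.mark.parametrize("rule", ["Bd", "dB"])
    def test_absorption_probabilities_sum_to_one(self, rule):
        g = _random_connected(7, 0.4, seed=11)
        res = fixation_probabilities(build_canonical_matrix(g, 1.5, rule))
        total = res.per_node + res.per_node_extinction
        assert np.abs(total - 1.0).max() < 1e-9

    @pytest.mark.parametrize("n", [4, 6, 8])
    def test_isothermal_theorem_under_bd(self, n):
        """Regular graphs have the well-mixed Bd fixation probability."""
        r = 1.5
        for g in (cycle_graph(n), complete_graph(n)):
            res = fixation_probabilities(build_canonical_matrix(g, r, "Bd"))
            assert res.uniform_avg == pytest.approx(
                phi_wellmixed_bd(r, n), abs=1e-10
            )

    @pytest.mark.parametrize("rule", ["Bd", "dB"])
    def test_phi_nondecreasing_in_r(self, rule, named_graphs):
        grid = [0.5, 0.75, 1.0, 1.25, 1.5, 1.75, 2.0]
        for name in ("cycle4", "star5", "complete4"):
            g = named_graphs[name]
            phis = [
                fixation_probabilities(build_canonical_matrix(g, r, rule)).uniform_avg
                for r in grid
            ]
            assert all(b >= a - 1e-12 for a, b in zip(phis, phis[1:])), name


class TestShortcuts:
    def test_directed_line_is_one_over_n(self):
        res = fixation_with_shortcuts(directed_line(4), 1.5, "Bd")
        assert res.uniform_avg == pytest.approx(0.25)
        assert res.per_node[0] == 1.0 and res.per_node[1:].sum() == 0.0

    def test_disconnected_graph_never_fixes(self):
        g = Graph(4, {(0, 1), (2, 3)})
        for rule in ("Bd", "dB"):
            assert fixation_with_shortcuts(g, 2.0, rule).uniform_avg == 0.0

    def test_multi_source_directed_never_fixes(self):
        # two directed triangles feeding a shared sink: no single lineage
        # can occupy both source components
        edges = {(0, 1), (1, 2), (2, 0), (3, 4), (4, 5), (5, 3), (0, 6), (3, 6)}
        g = Graph(7, edges, directed=True)
        assert fixation_with_shortcuts(g, 2.0, "Bd").uniform_avg == 0.0

    def test_connected_undirected_defers_to_full_solve(self):
        g = star_graph(4)
        direct = fixation_probabilities(build_canonical_matrix(g, 1.25, "Bd"))
        via = fixation_with_shortcuts(g, 1.25, "Bd")
        assert via.per_node == pytest.approx(direct.per_node)

    def test_bd_sink_exclusion_equals_lazy_self_loop(self):
        """Excluding out-degree-zero nodes from the Bd birth lottery must
        give the same absorption probabilities as counting their births
        as null self-transitions (the embedded jump chains coincide)."""
        g = Graph(3, {(0, 1), (1, 0), (0, 2), (1, 2)}, directed=True)  # node 2 sink
        r = 1.5
        res = fixation_with_shortcuts(g, r, "Bd")
        # lazy-chain oracle: dense power iteration with sink included
        n, full = 3, 7
        T = np.zeros((8, 8))
        for s in range(8):
            if s in (0, full):
                T[s, s] = 1.0
                continue
            fit = [r if s >> i & 1 else 1.0 for i in range(n)]
            total = sum(fit)  # all nodes in the lottery
            T[s, s] += fit[2] / total  # sink's birth goes nowhere
            for i in (0, 1):
                nbrs = g.out_neighbors(i)
                for j in nbrs:
                    t = s & ~(1 << j) | ((s >> i & 1) << j)
                    T[s, t] += fit[i] / total / len(nbrs)
        P = np.linalg.matrix_power(T, 4096)
        lazy = np.array([P[1 << i, full] for i in range(n)])
        assert res.per_node == pytest.approx(lazy, abs=1e-9)


class TestSimulation:
    def test_matches_wellmixed_closed_form(self):
        est, se = simulate_fixation(complete_graph(4), 2.0, "Bd", 100_000, rng=1)
        assert abs(est - 8 / 15) < 3 * se

    def test_neutral_matches_one_over_n(self):
        est, se = simulate_fixation(cycle_graph(5), 1.0, "dB", 100_000, rng=2)
        assert abs(est - 0.2) < 3 * se

    def test_matches_exact_solver_on_star(self):
        g = star_graph(5)
        exact = fixation_with_shortcuts(g, 1.5, "dB").uniform_avg
        est, se = simulate_fixation(g, 1.5, "dB", 100_000, rng=3)
        assert abs(est - exact) < 3 * se

    def test_requires_connected_graph(self):
        with pytest.raises(ValueError):
            simulate_fixation(Graph(4, {(0, 1)}), 1.5, "Bd", 10)
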