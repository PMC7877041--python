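import networkx as nx
import numpy as np
import pytest

from betweennet.bipartite_influence import InfluenceGraph
from betweennet.random_walk import (
    ConvergenceError,
    build_transition,
    compute_win,
    propagate,
    transition_from_graph,
    walk,
)

from _oracles import walk_linear_solve


def influence_from(graph: nx.Graph, heat: dict) -> InfluenceGraph:
    genes = tuple(sorted(n for n in graph if isinstance(n, str)))
    occs = tuple(sorted(n for n in graph if isinstance(n, tuple)))
    return InfluenceGraph(
        graph=graph, mutated_genes=genes, occurrences=occs, heat=dict(heat)
    )


def random_bipartite(seed: int, max_nodes: int = 50):
    """A random influence-like bipartite graph with random heats."""
    rng = np.random.default_rng(seed)
    n_genes = int(rng.integers(2, max_nodes // 2))
    n_occ = int(rng.integers(1, max_nodes - n_genes))
    g = nx.Graph()
    genes = [f"g{i:02d}" for i in range(n_genes)]
    occs = [(f"o{j:02d}", "p1") for j in range(n_occ)]
    g.add_nodes_from(genes)
    g.add_nodes_from(occs)
    for gene in genes:
        for occ in occs:
            if rng.random() < 0.15:
                g.add_edge(gene, occ)
    heat = {n: float(rng.random()) if rng.random() < 0.7 else 0.0 for n in g}
    return influence_from(g, heat)


class TestTransition:
    def test_single_edge(self):
        g = nx.Graph([("a", "b")])
        T = transition_from_graph(g, ["a", "b"])
        assert np.allclose(T, [[0, 1], [1, 0]])

    def test_isolated_node_column_is_zero(self):
        g = nx.Graph([("a", "b")])
        g.add_node("c")
        T = transition_from_graph(g, ["a", "b", "c"])
        assert np.allclose(T[:, 2], 0.0)

    def test_star_columns(self):
        g = nx.Graph([("c", "x"), ("c", "y")])
        T = transition_from_graph(g, ["c", "x", "y"])
        assert np.allclose(T[:, 1], [1.0, 0.0, 0.0])  # leaf -> center
        assert np.allclose(T[:, 0], [0.0, 0.5, 0.5])  # center splits

    def test_columns_of_connected_nodes_sum_to_one(self):
        infl = random_bipartite(seed=3)
        T = build_transition(infl)
        deg = dict(infl.graph.degree())
        for j, node in enumerate(infl.node_order):
            expected = 1.0 if deg[node] > 0 else 0.0
            assert np.asarray(T)[:, j].sum() == pytest.approx(expected)


class TestPropagate:
    def test_beta_one_returns_initial_heat(self):
        infl = random_bipartite(seed=1)
        result = walk(infl, beta=1.0)
        order = infl.node_order
        expected = np.diag([infl.heat[u] for u in order])
        assert np.allclose(result.F, expected)
        assert result.iterations == 1
        for u in order:
            assert result.w_in[u] == pytest.approx(infl.heat[u])

    def test_zero_heat_gives_zero_matrix(self):
        g = nx.Graph([("a", ("o", "p"))])
        infl = influence_from(g, {"a": 0.0, ("o", "p"): 0.0})
        result = walk(infl, beta=0.4)
        assert np.allclose(result.F, 0.0)

    def test_two_node_closed_form(self):
        g = nx.Graph([("a", ("b", "p"))])
        infl = influence_from(g, {"a": 1.0, ("b", "p"): 0.0})
        result = walk(infl, beta=0.4)
        T = np.array([[0.0, 1.0], [1.0, 0.0]])
        expected = walk_linear_solve(T, np.array([1.0, 0.0]), beta=0.4)
        assert np.allclose(result.F, expected, atol=1e-6)

    def test_isolated_node_keeps_restart_mass(self):
        g = nx.Graph([("a", ("b", "p"))])
        g.add_node("z")
        infl = influence_from(g, {"a": 0.0, ("b", "p"): 0.0, "z": 0.8})
        result = walk(infl, beta=0.4)
        # all-zero transition column: only the restart term survives
        assert result.w_in["z"] == pytest.approx(0.4 * 0.8, abs=1e-6)
        T = np.asarray(build_transition(infl))
        order = infl.node_order
        heats = np.array([infl.heat[u] for u in order])
        expected = walk_linear_solve(T, heats, beta=0.4)
        idx = order.index("z")
        assert result.w_in["z"] == pytest.approx(expected[idx].sum(), abs=1e-6)

    def test_iterative_matches_linear_solve_on_random_graphs(self):
        for seed in range(10):
            infl = random_bipartite(seed)
            T = build_transition(infl)
            heats = np.array([infl.heat[u] for u in infl.node_order])
            for beta in (0.1, 0.4, 0.9):
                F, _, _ = propagate(T, heats, beta=beta)
                expected = walk_linear_solve(np.asarray(T), heats, beta=beta)
                assert np.allclose(F, expected, atol=1e-6)

    def test_residuals_decrease_monotonically(self):
        infl = random_bipartite(seed=5)
        T = np.asarray(build_transition(infl))
        heats = np.array([infl.heat[u] for u in infl.node_order])
        beta = 0.3
        residuals = []
        F = np.diag(heats)
        F0 = np.diag(heats)
        for _ in range(30):
            F_next = (1 - beta) * T @ F + beta * F0
            residuals.append(np.max(np.abs(F_next - F)))
            F = F_next
        assert all(b <= a + 1e-12 for a, b in zip(residuals, residuals[1:]))

    def test_beta_zero_can_oscillate_and_errors(self):
        g = nx.Graph([("a", ("b", "p"))])
        infl = influence_from(g, {"a": 1.0, ("b", "p"): 0.0})
        T = build_transition(infl)
        with pytest.raises(ConvergenceError) as err:
            propagate(T, np.array([1.0, 0.0]), beta=0.0, max_iter=50)
        assert err.value.residual > 0

    def test_order_permutation_permutes_results(self):
        infl = random_bipartite(seed=9)
        order = infl.node_order
        heats = np.array([infl.heat[u] for u in order])
        F1, _, _ = propagate(build_transition(infl), heats, beta=0.4)
        perm_order = list(reversed(order))
        T2 = transition_from_graph(infl.graph, perm_order)
        heats2 = np.array([infl.heat[u] for u in perm_order])
        F2, _, _ = propagate(T2, heats2, beta=0.4)
        w1 = compute_win(F1, order)
        w2 = compute_win(F2, perm_order)
        for u in order:
            assert w1[u] == pytest.approx(w2[u], abs=1e-9)

    def test_invalid_parameters(self):
        T = np.zeros((2, 2))
        with pytest.raises(ValueError, match="beta"):
            propagate(T, np.ones(2), beta=1.5)
        with pytest.raises(ValueError, match="tol"):
            propagate(T, np.ones(2), tol=0.0)


def test_conservation_of_column_mass_without_isolated_nodes():
    """Column-stochastic T preserves each column's initial heat mass."""
    for seed in range(5):
        infl = random_bipartite(seed + 100)
        connected = [n for n in infl.node_order if infl.graph.degree(n) > 0]
        sub = infl.graph.subgraph(connected)
        genes = tuple(sorted(n for n in sub if isinstance(n, str)))
        occs = tuple(sorted(n for n in sub if isinstance(n, tuple)))
        if not genes or not occs:
            continue
        infl2 = InfluenceGraph(
            graph=sub, mutated_genes=genes, occurrences=occs,
            heat={n: infl.heat[n] for n in sub},
        )
        result = walk(infl2, beta=0.4)
        heats = np.array([infl2.heat[u] for u in infl2.node_order])
        assert np.allclose(result.F.sum(axis=0), heats, atol=1e-6)
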