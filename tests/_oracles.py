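"""Independent brute-force oracles used to check the implementation.

These deliberately avoid the code paths they verify: path enumeration via
networkx generators instead of dependency accumulation, dense linear solves
instead of power iteration, combinatorial sums instead of scipy's
hypergeometric tail, and a literal re-implementation of the greedy ranking
loop.
"""

from __future__ import annotations

from math import comb

import networkx as nx
import numpy as np


def kb_enumeration(graph: nx.Graph, k: int) -> dict:
    """k-betweenness by exhaustive shortest-path enumeration (ordered pairs)."""
    bet = {v: 0.0 for v in graph}
    for s in graph:
        lengths = nx.single_source_shortest_path_length(graph, s)
        for t, d in lengths.items():
            if t == s or d > k:
                continue
            paths = list(nx.all_shortest_paths(graph, s, t))
            for path in paths:
                for v in path[1:-1]:
                    bet[v] += 1.0 / len(paths)
    return bet


def walk_linear_solve(T, heats: np.ndarray, beta: float) -> np.ndarray:
    """Closed form of the restart walk: beta (I - (1-beta) T)^{-1} F0."""
    T = np.asarray(T.todense()) if hasattr(T, "todense") else np.asarray(T)
    n = heats.size
    F0 = np.diag(heats)
    return beta * np.linalg.solve(np.eye(n) - (1.0 - beta) * T, F0)


def hypergeom_upper_tail(M: int, K: int, n: int, k: int) -> float:
    """P(overlap >= k) drawing n from M with K marked, by direct summation."""
    total = comb(M, n)
    return sum(
        comb(K, x) * comb(M - K, n - x)
        for x in range(k, min(K, n) + 1)
        if n - x <= M - K
    ) / total


def greedy_rank_replay(graph: nx.Graph, mutated, w_in, heat, alpha, max_rank):
    """Literal re-execution of the remove-and-rerank loop.

    Scores every remaining gene from scratch at each step (current degrees,
    frozen w_in and frozen max w_in over the original partition) and picks
    the argmax with the (score, degree, MF, name) tie rule.
    """
    g = graph.copy()
    remaining = sorted(mutated)
    max_win = max(w_in[m] for m in mutated)
    order = []
    while remaining and len(order) < max_rank:
        best = None
        best_key = None
        for gene in remaining:
            deg = g.degree(gene)
            max_deg = max(g.degree(x) for x in remaining)
            deg_term = deg / max_deg if max_deg else 0.0
            win_term = w_in[gene] / max_win if max_win else 0.0
            score = alpha * deg_term + (1 - alpha) * win_term
            key = (-score, -deg, -heat.get(gene, 0.0), gene)
            if best_key is None or key < best_key:
                best_key = key
                best = gene
        order.append(best)
        neighbors = list(g.neighbors(best))
        g.remove_node(best)
        g.remove_nodes_from(neighbors)
        remaining.remove(best)
    return order


def degree_greedy_cover(graph: nx.Graph, mutated, heat) -> list:
    """Pure iterative max-degree cover (the alpha = 1 limit)."""
    g = graph.copy()
    remaining = sorted(mutated)
    order = []
    while remaining:
        best = min(remaining, key=lambda x: (-g.degree(x), -heat.get(x, 0.0), x))
        order.append(best)
        neighbors = list(g.neighbors(best))
        g.remove_node(best)
        g.remove_nodes_from(neighbors)
        remaining.remove(best)
    return order
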