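r"""Random walk with restart on the influence graph.

Mutation frequencies seed a heat diffusion: with column-stochastic
transition matrix T (T[i, j] = 1/deg(u_j) for edges, 0 otherwise) and the
diagonal heat matrix F0, the propagation

    F_{t+1} = (1 - beta) T F_t + beta F0,    F_1 = F0

is iterated until the largest entrywise change falls below a tolerance.
For beta > 0 this converges to the closed form beta (I - (1-beta) T)^{-1} F0.
A node's incoming-weight sum w_in is the row sum of the converged F
(diagonal included).

Zero-degree (isolated) nodes get an all-zero T column: their heat decays
to the restart fraction rather than being conserved by an artificial
self-loop, keeping T literal to its definition.  Columns of F whose node
has zero heat are identically zero, so the iteration is carried out only
on the nonzero-heat columns (an exact restriction, not an approximation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .bipartite_influence import InfluenceGraph

logger = logging.getLogger("betweennet")

DEFAULT_BETA = 0.4
DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 1000

#: above this node count the transition matrix is held sparse (same results)
_DENSE_LIMIT = 3000


class ConvergenceError(RuntimeError):
    """Propagation failed to converge within max_iter."""

    def __init__(self, iterations: int, residual: float):
        super().__init__(
            f"propagation did not converge after {iterations} iterations "
            f"(residual {residual:.3g})"
        )
        self.iterations = iterations
        self.residual = residual


@dataclass
class WalkResult:
    """Converged propagation over a fixed node order."""

    node_order: list
    F: np.ndarray
    w_in: dict
    iterations: int
    residual: float


def transition_from_graph(graph, node_order) -> np.ndarray | sparse.csr_matrix:
    """Column-stochastic transition matrix of an undirected graph.

    ``T[i, j] = 1/deg(u_j)`` if (u_i, u_j) is an edge, else 0; the column
    of a zero-degree node is all zeros.
    """
    n = len(node_order)
    index = {u: i for i, u in enumerate(node_order)}
    deg = {u: graph.degree(u) for u in node_order}
    rows, cols, vals = [], [], []
    for u, v in graph.edges():
        i, j = index[u], index[v]
        rows.append(i); cols.append(j); vals.append(1.0 / deg[v])
        rows.append(j); cols.append(i); vals.append(1.0 / deg[u])
    T = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(n, n), dtype=float
    )
    if n <= _DENSE_LIMIT:
        return T.toarray()
    return T


def build_transition(influence: InfluenceGraph) -> np.ndarray | sparse.csr_matrix:
    """Transition matrix of the influence graph in its fixed node order."""
    if not influence.node_order:
        raise ValueError("empty influence graph")
    return transition_from_graph(influence.graph, influence.node_order)


def propagate(
    T,
    heats: np.ndarray,
    beta: float = DEFAULT_BETA,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> tuple[np.ndarray, int, float]:
    """Iterate ``F <- (1-beta) T F + beta F0`` to convergence.

    ``heats`` is the diagonal of F0.  Returns (F, iterations, residual)
    where residual is the final max-abs entry change.

    Raises
    ------
    ConvergenceError
        If the residual is still >= tol after max_iter iterations (possible
        for beta = 0, where the walk on a bipartite graph can oscillate).
    """
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta must be in [0, 1], got {beta}")
    if tol <= 0:
        raise ValueError(f"tol must be > 0, got {tol}")
    heats = np.asarray(heats, dtype=float)
    n = heats.size
    cols = np.flatnonzero(heats)
    # columns of zero-heat nodes are identically zero throughout; restrict
    # the iteration to the nonzero-heat columns (exact, F0 is diagonal)
    col_idx = np.arange(cols.size)
    F0r = np.zeros((n, cols.size))
    F0r[cols, col_idx] = heats[cols]
    restart = beta * heats[cols]
    Fr = F0r.copy()
    iterations = 0
    residual = np.inf
    one_minus = 1.0 - beta
    for iterations in range(1, max_iter + 1):
        F_next = T @ Fr
        if one_minus != 1.0:
            F_next *= one_minus
        F_next[cols, col_idx] += restart
        np.subtract(F_next, Fr, out=Fr)
        np.abs(Fr, out=Fr)
        residual = float(Fr.max()) if cols.size else 0.0
        Fr = F_next
        if residual < tol:
            break
    else:
        raise ConvergenceError(max_iter, residual)
    F = np.zeros((n, n))
    F[:, cols] = Fr
    return F, iterations, residual


def compute_win(F: np.ndarray, node_order) -> dict:
    """Incoming-weight sums: w_in(u) = row sum of converged F (diagonal in)."""
    sums = F.sum(axis=1)
    return {u: float(sums[i]) for i, u in enumerate(node_order)}


def walk(
    influence: InfluenceGraph,
    beta: float = DEFAULT_BETA,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> WalkResult:
    """Run the full restart walk on an influence graph."""
    order = influence.node_order
    T = build_transition(influence)
    heats = np.array([influence.heat[u] for u in order], dtype=float)
    F, iterations, residual = propagate(T, heats, beta=beta, tol=tol, max_iter=max_iter)
    logger.info("random walk converged after %d iterations (residual %.3g)",
                iterations, residual)
    return WalkResult(
        node_order=order, F=F, w_in=compute_win(F, order),
        iterations=iterations, residual=residual,
    )
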