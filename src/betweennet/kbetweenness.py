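r"""Length-bounded (k-)betweenness centrality and per-patient differences.

Classic betweenness counts all shortest paths; here only geodesics of
length <= k edges contribute, on the grounds that very long paths through a
protein network rarely reflect a functional relation.  For node i,

    kB(i) = sum over ordered pairs (s, t), s != i != t, d(s, t) <= k of
            sigma_st(i) / sigma_st

where sigma_st is the number of shortest s-t paths and sigma_st(i) the
number of those through i.  The sum runs over ORDERED pairs -- each
unordered pair {s, t} is counted twice -- and no normalization is applied.
Downstream outlier detection is scale-sensitive only through the fitted
distribution, so any consistent convention works; pass ``ordered=False`` to
halve the values for parity with unordered-pair implementations.

Implementation: Brandes' dependency accumulation with the BFS from each
source truncated at depth k.  Vertices within distance k of the source are
exactly the targets with d(s, t) <= k, and the restriction changes nothing
else, so per-source accumulation restricted to that ball yields the bounded
sum exactly.  Sources are visited in sorted order so floating-point sums
are reproducible.
"""

from __future__ import annotations

import logging
from collections import deque
from typing import Iterable

import networkx as nx
import pandas as pd

from .personalized_networks import PatientNetworks

logger = logging.getLogger("betweennet")


def k_betweenness(
    graph: nx.Graph,
    k: int,
    nodes: Iterable[str] | None = None,
    ordered: bool = True,
) -> dict[str, float]:
    """k-betweenness of every node of ``graph`` (optionally masked to ``nodes``).

    Parameters
    ----------
    graph:
        Simple undirected unweighted graph.
    k:
        Maximum geodesic length (in edges) contributing to the sum; k >= 1.
    nodes:
        Optional node mask; centrality is computed on the induced subgraph.
    ordered:
        Count ordered source/target pairs (default).  ``False`` halves every
        value (unordered-pair convention).

    Returns
    -------
    dict mapping each (masked) node to its centrality; isolated nodes get 0.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if nodes is None:
        node_set = set(graph.nodes)
    else:
        node_set = set(nodes)
        if not node_set:
            raise ValueError("node mask selects no nodes")
    # adjacency restricted to the mask, neighbors sorted for determinism
    adj = {
        u: [v for v in sorted(graph.neighbors(u)) if v in node_set]
        for u in sorted(node_set)
    }
    bet = dict.fromkeys(adj, 0.0)
    for s in adj:
        dist = {s: 0}
        sigma = {s: 1.0}
        preds: dict[str, list[str]] = {s: []}
        order = [s]
        queue = deque([s])
        while queue:
            v = queue.popleft()
            dv = dist[v]
            if dv == k:  # do not expand past the depth bound
                continue
            for w in adj[v]:
                if w not in dist:
                    dist[w] = dv + 1
                    sigma[w] = 0.0
                    preds[w] = []
                    order.append(w)
                    queue.append(w)
                if dist[w] == dv + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        delta = dict.fromkeys(order, 0.0)
        for w in reversed(order):
            coeff = (1.0 + delta[w]) / sigma[w]
            for v in preds[w]:
                delta[v] += sigma[v] * coeff
            if w != s:
                bet[w] += delta[w]
    if not ordered:
        for u in bet:
            bet[u] /= 2.0
    return bet


def betweenness_diff(
    ppi: nx.Graph,
    networks: PatientNetworks,
    k: int = 3,
    ordered: bool = True,
) -> pd.DataFrame:
    """Per-gene betweenness in N_p and T_p and their absolute difference.

    Returns a DataFrame with columns ``patient, gene, b_normal, b_tumor,
    b_diff``; ``b_diff = |b_normal - b_tumor|`` is defined only for genes
    present in both networks (NaN otherwise, as is the missing side's value
    for genes in a single network).
    """
    normal, tumor = networks.normal_nodes, networks.tumor_nodes
    shared = normal & tumor
    if not shared:
        logger.warning(
            "patient %s: normal and tumor networks share no genes", networks.patient
        )
        return pd.DataFrame(
            columns=["patient", "gene", "b_normal", "b_tumor", "b_diff"]
        )
    b_n = k_betweenness(ppi, k, nodes=normal, ordered=ordered)
    b_t = k_betweenness(ppi, k, nodes=tumor, ordered=ordered)
    rows = []
    for gene in sorted(normal | tumor):
        bn = b_n.get(gene)
        bt = b_t.get(gene)
        diff = abs(bn - bt) if gene in shared else None
        rows.append((networks.patient, gene, bn, bt, diff))
    return pd.DataFrame(
        rows, columns=["patient", "gene", "b_normal", "b_tumor", "b_diff"]
    )
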