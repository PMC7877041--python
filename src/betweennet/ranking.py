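r"""Greedy remove-and-rerank prioritization of mutated genes.

Each remaining mutated gene i is scored

    S_i = alpha * deg(u_i) / max_j deg(u_j)
        + (1 - alpha) * w_in(u_i) / max_j w_in(u_j)

where degrees are CURRENT bipartite degrees in the (shrinking) influence
graph, recomputed after every selection, while the w_in values -- and the
maximum w_in, taken over the ORIGINAL mutations partition -- are computed
once by the random walk and stay fixed.  The top-scoring gene is appended
to the ranking, then it and its outlier-occurrence neighbors are deleted
from the graph, and the loop repeats up to ``max_rank`` selections.

Ties on S_i are broken by higher current degree, then higher mutation
frequency, then lexicographic gene symbol, so the output is deterministic.
Genes whose degree drops to zero stay eligible (scored by their w_in term
alone).  If the current maximum degree (or the frozen maximum w_in) is
zero, that term is zero for every gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .bipartite_influence import InfluenceGraph

DEFAULT_ALPHA = 0.5
DEFAULT_MAX_RANK = 1000


@dataclass(frozen=True)
class RankEntry:
    rank: int
    gene: str
    score: float
    degree_component: float
    win_component: float
    note: str = ""


@dataclass
class RankedList:
    """Ordered driver-gene candidates with score components."""

    entries: list[RankEntry] = field(default_factory=list)
    alpha: float = DEFAULT_ALPHA

    @property
    def genes(self) -> list[str]:
        return [e.gene for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


def rank_genes(
    influence: InfluenceGraph,
    w_in: dict,
    alpha: float = DEFAULT_ALPHA,
    max_rank: int = DEFAULT_MAX_RANK,
) -> RankedList:
    """Iteratively select, record and remove the top-scoring mutated gene."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    if max_rank < 1:
        raise ValueError(f"max_rank must be >= 1, got {max_rank}")
    remaining = set(influence.mutated_genes)
    if not remaining:
        raise ValueError("empty mutations partition")
    missing = [g for g in remaining if g not in w_in]
    if missing:
        raise ValueError(f"w_in undefined for mutated genes: {sorted(missing)[:5]}")

    graph = influence.graph.copy()
    mf = influence.heat
    max_win = max(w_in[g] for g in influence.mutated_genes)  # frozen

    ranked = RankedList(alpha=alpha)
    while remaining and len(ranked.entries) < len(influence.mutated_genes):
        if len(ranked.entries) >= max_rank:
            break
        degrees = {g: graph.degree(g) for g in remaining}
        max_deg = max(degrees.values())
        scored = []
        for g in remaining:
            deg_term = degrees[g] / max_deg if max_deg > 0 else 0.0
            win_term = w_in[g] / max_win if max_win > 0 else 0.0
            score = alpha * deg_term + (1.0 - alpha) * win_term
            scored.append((-score, -degrees[g], -mf.get(g, 0.0), g))
        scored.sort()
        neg_score, neg_deg, _, best = scored[0]
        deg_term = -neg_deg / max_deg if max_deg > 0 else 0.0
        win_term = w_in[best] / max_win if max_win > 0 else 0.0
        ranked.entries.append(RankEntry(
            rank=len(ranked.entries) + 1,
            gene=best,
            score=-neg_score,
            degree_component=deg_term,
            win_component=win_term,
        ))
        neighbors = list(graph.neighbors(best))
        graph.remove_node(best)
        graph.remove_nodes_from(neighbors)
        remaining.discard(best)
    return ranked


def final_output(
    ranked: RankedList, no_network_genes: dict[str, float]
) -> RankedList:
    """Append PPI-absent mutated genes after the ranked genes.

    These genes have no bipartite degree or diffusion signal; they are
    ordered by mutation frequency descending then gene symbol, and flagged
    ``no-network``.  Their score columns carry the MF for reference.
    """
    entries = list(ranked.entries)
    tail = sorted(no_network_genes.items(), key=lambda kv: (-kv[1], kv[0]))
    for gene, mf in tail:
        entries.append(RankEntry(
            rank=len(entries) + 1,
            gene=gene,
            score=mf,
            degree_component=0.0,
            win_component=0.0,
            note="no-network",
        ))
    return RankedList(entries=entries, alpha=ranked.alpha)
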