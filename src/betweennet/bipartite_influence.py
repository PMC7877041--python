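"""Bipartite influence graph linking mutated genes to outlier occurrences.

One partition holds the cohort's mutated genes (non-silently mutated in at
least one patient and present in the PPI); the other holds one node per
(outlier gene, patient) occurrence -- a gene that is an outlier in several
patients contributes several occurrence nodes.  An edge (u_i, u_j^p)
exists iff gene i is mutated in patient p AND {i, j} is a PPI edge AND j
is an outlier of p.  Both partitions carry mutation-frequency heat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

from .data_io import MutationTable, ValidationError
from .outlier_detection import OutlierCalls

logger = logging.getLogger("betweennet")

Occurrence = tuple[str, str]  # (gene, patient)


def occurrence_key(node: Occurrence) -> str:
    """Serialization key for an occurrence node: ``GENE@PATIENT``."""
    return f"{node[0]}@{node[1]}"


@dataclass
class InfluenceGraph:
    """The bipartite influence graph plus node heats and bookkeeping.

    Mutated-gene nodes are gene-symbol strings; occurrence nodes are
    ``(gene, patient)`` tuples.  ``heat`` maps every node to the mutation
    frequency of its underlying gene (0 for never-mutated outlier genes).
    ``no_network_genes`` records mutated genes absent from the PPI -- they
    cannot carry edges or a degree signal and are excluded from the
    mutations partition, to be appended (flagged) after all ranked genes.
    """

    graph: nx.Graph
    mutated_genes: tuple[str, ...]
    occurrences: tuple[Occurrence, ...]
    heat: dict = field(default_factory=dict)
    no_network_genes: dict[str, float] = field(default_factory=dict)

    @property
    def node_order(self) -> list:
        """Fixed node order: sorted mutated genes, then sorted occurrences."""
        return list(self.mutated_genes) + list(self.occurrences)


def build_influence_graph(
    ppi: nx.Graph,
    mutations: MutationTable,
    outliers: OutlierCalls,
) -> InfluenceGraph:
    """Assemble the influence graph from mutations and outlier calls.

    Isolated nodes are retained in both partitions (a mutated gene with no
    same-patient outlier neighbors still gets ranked; its heat still seeds
    the walk).
    """
    mf = mutations.mf
    mutated_all = mutations.all_mutated_genes
    in_ppi = sorted(g for g in mutated_all if g in ppi)
    no_network = {g: mf[g] for g in sorted(mutated_all - set(in_ppi))}
    if not in_ppi:
        raise ValidationError("empty mutations partition: no mutated gene is in the PPI")
    if no_network:
        logger.info(
            "%d mutated genes absent from the PPI excluded from the mutations "
            "partition: %s%s",
            len(no_network), ", ".join(list(no_network)[:5]),
            "..." if len(no_network) > 5 else "",
        )

    graph = nx.Graph()
    graph.add_nodes_from(in_ppi, bipartite=0)

    occurrences: list[Occurrence] = []
    for patient in sorted(outliers.outliers):
        for gene in sorted(outliers.outlier_genes(patient)):
            occurrences.append((gene, patient))
    graph.add_nodes_from(occurrences, bipartite=1)

    for patient in sorted(outliers.outliers):
        mutated_here = [g for g in in_ppi if g in mutations.mutated_genes(patient)]
        for out_gene in sorted(outliers.outlier_genes(patient)):
            occ = (out_gene, patient)
            for mut_gene in mutated_here:
                if ppi.has_edge(mut_gene, out_gene):
                    graph.add_edge(mut_gene, occ)

    heat = {g: mf[g] for g in in_ppi}
    heat.update({occ: mf.get(occ[0], 0.0) for occ in occurrences})
    nx.set_node_attributes(graph, heat, "heat")

    logger.info(
        "influence graph: %d mutated genes, %d outlier occurrences, %d edges",
        len(in_ppi), len(occurrences), graph.number_of_edges(),
    )
    return InfluenceGraph(
        graph=graph,
        mutated_genes=tuple(in_ppi),
        occurrences=tuple(occurrences),
        heat=heat,
        no_network_genes=no_network,
    )
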