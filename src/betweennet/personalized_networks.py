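"""Per-patient normal and tumor subnetworks of the reference PPI.

For each patient the normal network keeps the PPI genes whose normalized
count in the paired normal sample reaches the expression threshold; the
tumor network additionally removes genes carrying a non-silent somatic
mutation in that patient.  Networks are represented as node sets (masks)
over the shared reference graph rather than graph copies; downstream
queries take (graph, node set).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .data_io import ExpressionMatrix, MutationTable, ValidationError

#: normalized counts below this are "not expressed" (strict: exactly the
#: threshold counts as expressed)
DEFAULT_EXPRESSION_THRESHOLD = 5.0


@dataclass(frozen=True)
class PatientNetworks:
    """Node masks of one patient's normal (N_p) and tumor (T_p) networks."""

    patient: str
    normal_nodes: frozenset[str]
    tumor_nodes: frozenset[str]


def _expressed_genes(expr: ExpressionMatrix, patient: str, threshold: float) -> set[str]:
    if patient not in expr.patients:
        raise ValidationError(f"unknown patient {patient!r} in {expr.condition} expression")
    col = expr.values[patient]
    return set(col.index[col >= threshold])


def build_normal_network(
    ppi: nx.Graph,
    expr_normal: ExpressionMatrix,
    patient: str,
    threshold: float = DEFAULT_EXPRESSION_THRESHOLD,
) -> frozenset[str]:
    """Genes of the PPI expressed (count >= threshold) in the normal sample.

    PPI genes absent from the expression matrix are treated as not measured,
    hence not expressed, and are removed.
    """
    expressed = _expressed_genes(expr_normal, patient, threshold)
    return frozenset(g for g in ppi.nodes if g in expressed)


def build_tumor_network(
    ppi: nx.Graph,
    expr_tumor: ExpressionMatrix,
    mutations: MutationTable,
    patient: str,
    threshold: float = DEFAULT_EXPRESSION_THRESHOLD,
) -> frozenset[str]:
    """Tumor network nodes: expressed in the tumor sample and not mutated.

    Removes (i) genes below the expression threshold in the tumor sample and
    (ii) genes with a non-silent mutation in this patient.  A gene failing
    both rules is simply removed once.
    """
    expressed = _expressed_genes(expr_tumor, patient, threshold)
    mutated = mutations.mutated_genes(patient)
    return frozenset(g for g in ppi.nodes if g in expressed and g not in mutated)


def build_patient_networks(
    ppi: nx.Graph,
    expr_normal: ExpressionMatrix,
    expr_tumor: ExpressionMatrix,
    mutations: MutationTable,
    patient: str,
    threshold: float = DEFAULT_EXPRESSION_THRESHOLD,
) -> PatientNetworks:
    """Build both personalized networks for one patient."""
    return PatientNetworks(
        patient=patient,
        normal_nodes=build_normal_network(ppi, expr_normal, patient, threshold),
        tumor_nodes=build_tumor_network(ppi, expr_tumor, mutations, patient, threshold),
    )
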