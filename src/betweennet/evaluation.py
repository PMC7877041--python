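"""Evaluation of ranked gene lists against reference cancer gene sets.

Protocols: ROC/AUROC over rank prefixes up to a cutoff, stratification to
rare drivers (cohort mutation frequency below a cutoff), one-sided
hypergeometric term enrichment with Benjamini-Hochberg FDR, and the
intersection-over-union consistency of two enriched-term sets.

The ROC universe is the ranked list itself (all genes the method scored):
TPR and FPR denominators are the reference and non-reference genes within
that universe, the curve is traced top-down to the cutoff and integrated by
the trapezoid rule without extrapolation beyond the cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_io import MutationTable, ReferenceGeneSet, ValidationError

logger = logging.getLogger("betweennet")

DEFAULT_RARE_CUTOFF = 0.02
DEFAULT_SIG_CUTOFF = 0.05


@dataclass(frozen=True)
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auroc: float


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-term enrichment table and the significant-term set."""

    table: pd.DataFrame  # columns: term, term_size, overlap, p, q
    significant: frozenset[str]


def roc_auc(
    ranked_genes: Sequence[str],
    reference: Iterable[str] | ReferenceGeneSet,
    cutoff: int | None = None,
) -> ROCResult:
    """ROC of a ranked gene list against a reference set, up to ``cutoff``.

    Walking the list top-down, each gene moves the curve up (reference hit)
    or right (non-hit); AUROC is the trapezoid area under the traced curve.
    """
    ref = reference.genes if isinstance(reference, ReferenceGeneSet) else set(reference)
    universe = list(dict.fromkeys(ranked_genes))
    if cutoff is None:
        cutoff = len(universe)
    if cutoff > len(universe):
        raise ValidationError(
            f"cutoff {cutoff} exceeds ranked list length {len(universe)}"
        )
    n_pos = sum(1 for g in universe if g in ref)
    n_neg = len(universe) - n_pos
    if n_pos == 0:
        raise ValidationError("reference set does not intersect the ranked universe")
    if n_neg == 0:
        raise ValidationError("every ranked gene is in the reference set")
    fpr = [0.0]
    tpr = [0.0]
    tp = fp = 0
    for gene in universe[:cutoff]:
        if gene in ref:
            tp += 1
        else:
            fp += 1
        tpr.append(tp / n_pos)
        fpr.append(fp / n_neg)
    fpr_arr = np.array(fpr)
    tpr_arr = np.array(tpr)
    auroc = float(np.trapezoid(tpr_arr, fpr_arr))
    return ROCResult(fpr=fpr_arr, tpr=tpr_arr, auroc=auroc)


def rare_subset(
    reference: ReferenceGeneSet,
    mutations: MutationTable,
    freq_cutoff: float = DEFAULT_RARE_CUTOFF,
) -> ReferenceGeneSet | None:
    """Reference genes with cohort mutation frequency <= ``freq_cutoff``.

    Genes never mutated in the cohort have MF 0 and are included.  Returns
    None with a warning when no reference gene is rare in this cohort
    (reference sets are never empty, so the stratification is simply
    unavailable).
    """
    if not 0.0 < freq_cutoff < 1.0:
        raise ValidationError(f"freq_cutoff must be in (0, 1), got {freq_cutoff}")
    mf = mutations.mf
    rare = frozenset(g for g in reference.genes if mf.get(g, 0.0) <= freq_cutoff)
    if not rare:
        logger.warning("rare_subset(%s): no gene at MF <= %g", reference.name, freq_cutoff)
        return None
    return ReferenceGeneSet(name=f"{reference.name}-rare", genes=rare)


def enrich(
    gene_set: Iterable[str],
    annotation: Mapping[str, frozenset[str]],
    universe: Iterable[str],
    sig_cutoff: float = DEFAULT_SIG_CUTOFF,
    use_q: bool = True,
) -> EnrichmentResult:
    """One-sided hypergeometric term enrichment with BH-FDR correction.

    For each term with at least one universe gene, the p-value is the
    upper-tail probability of observing at least the overlap between the
    gene set and the term's universe genes, under sampling |gene_set| genes
    from the universe without replacement.  Significance defaults to
    q < ``sig_cutoff``; set ``use_q=False`` to threshold raw p-values.
    """
    uni = set(universe)
    gs = set(gene_set)
    if not gs <= uni:
        raise ValidationError("gene_set must be a subset of the universe")
    rows = []
    m_total = len(uni)
    n_draw = len(gs)
    for term in sorted(annotation):
        term_genes = annotation[term] & uni
        if not term_genes:
            continue
        overlap = len(term_genes & gs)
        p = float(stats.hypergeom.sf(overlap - 1, m_total, len(term_genes), n_draw))
        rows.append((term, len(term_genes), overlap, min(p, 1.0)))
    if not rows:
        raise ValidationError("annotation covers no universe genes")
    table = pd.DataFrame(rows, columns=["term", "term_size", "overlap", "p"])
    table["q"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    key = "q" if use_q else "p"
    significant = frozenset(table.loc[table[key] < sig_cutoff, "term"])
    return EnrichmentResult(table=table, significant=significant)


def consistency(terms_a: Iterable[str], terms_b: Iterable[str]) -> float:
    """Intersection-over-union of two term sets (0 when both are empty)."""
    a, b = set(terms_a), set(terms_b)
    union = a | b
    if not union:
        logger.warning("consistency of two empty term sets defined as 0")
        return 0.0
    return len(a & b) / len(union)


def shared_term_count(terms_a: Iterable[str], terms_b: Iterable[str]) -> int:
    """Raw number of terms common to both sets (pathway-count variant)."""
    return len(set(terms_a) & set(terms_b))
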