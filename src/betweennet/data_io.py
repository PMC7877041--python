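"""Readers and writers for the pipeline's external file formats.

All inputs are plain TSV so that cohorts exported from standard sources
(expression matrices, MAF-style mutation tables, edge lists) can be fed in
without binary dependencies.  Every reader validates its input into one of
the domain types used downstream and raises :class:`ValidationError` with a
message naming the offending record rather than silently repairing data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("betweennet")

DEFAULT_SILENT_CLASSES = frozenset({"Silent"})

#: default MAF-lite column names (configurable in :func:`read_maf`)
MAF_GENE_COL = "Hugo_Symbol"
MAF_PATIENT_COL = "Tumor_Sample_Barcode"
MAF_CLASS_COL = "Variant_Classification"


class ValidationError(ValueError):
    """An input file failed validation against its expected format."""


# ---------------------------------------------------------------------------
# protein-protein interaction network
# ---------------------------------------------------------------------------

def read_ppi(path: str | Path, header: bool = False) -> nx.Graph:
    """Read an undirected PPI network from a two-column gene-symbol edge list.

    Self-loops are dropped and duplicate edges (in either orientation) are
    collapsed, so the result is a simple undirected graph.  Nodes are the
    endpoints of the surviving edges; a gene appearing only in self-loops
    therefore does not survive.

    Parameters
    ----------
    path:
        TSV/whitespace-separated file with at least two columns of gene
        symbols per line; extra columns are ignored.
    header:
        If True the first line is skipped.

    Raises
    ------
    ValidationError
        On a line with fewer than two columns, or when the network is empty
        after cleaning.
    """
    path = Path(path)
    graph = nx.Graph()
    n_self_loops = 0
    n_duplicates = 0
    with path.open() as fh:
        lines = iter(fh)
        if header:
            next(lines, None)
        for lineno, line in enumerate(lines, start=2 if header else 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValidationError(
                    f"{path}:{lineno}: expected at least 2 columns, got {len(parts)}"
                )
            u, v = parts[0], parts[1]
            if u == v:
                n_self_loops += 1
                continue
            if graph.has_edge(u, v):
                n_duplicates += 1
                continue
            graph.add_edge(u, v)
    if graph.number_of_edges() == 0:
        raise ValidationError(f"{path}: empty network after cleaning")
    if n_self_loops or n_duplicates:
        logger.info(
            "read_ppi(%s): dropped %d self-loop and %d duplicate records",
            path.name, n_self_loops, n_duplicates,
        )
    logger.info(
        "read_ppi(%s): %d nodes, %d edges",
        path.name, graph.number_of_nodes(), graph.number_of_edges(),
    )
    return graph


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionMatrix:
    """Normalized expression counts, genes x patients, for one condition.

    ``values`` is indexed by gene symbol with one column per patient ID;
    entries are nonnegative normalized counts (no NaN).
    """

    values: pd.DataFrame
    condition: str  # "normal" | "tumor"

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def patients(self) -> pd.Index:
        return self.values.columns

    def value(self, gene: str, patient: str) -> float:
        return float(self.values.at[gene, patient])


def read_expression(path: str | Path, condition: str) -> ExpressionMatrix:
    """Read a genes x patients expression TSV (first column = gene symbols).

    Rejects duplicate gene rows and duplicate patient columns outright --
    no silent aggregation -- and rejects non-numeric, NaN or negative cells.
    """
    path = Path(path)
    if condition not in ("normal", "tumor"):
        raise ValidationError(f"condition must be 'normal' or 'tumor', got {condition!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate gene rows {dups[:5]}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate patient columns {dups[:5]}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValidationError(
            f"{path}: non-numeric cell at gene {df.index[bad[0]]!r}, "
            f"patient {df.columns[bad[1]]!r}"
        )
    if (numeric.to_numpy() < 0).any():
        bad = np.argwhere((numeric < 0).to_numpy())[0]
        raise ValidationError(
            f"{path}: negative value at gene {df.index[bad[0]]!r}, "
            f"patient {df.columns[bad[1]]!r} (normalized counts must be >= 0)"
        )
    return ExpressionMatrix(values=numeric.astype(float), condition=condition)


# ---------------------------------------------------------------------------
# somatic mutations
# ---------------------------------------------------------------------------

@dataclass
class MutationTable:
    """Somatic mutation records with per-patient non-silent gene sets.

    ``patients`` is the cohort universe used as the denominator of the
    mutation frequency MF(i) = (#patients with >=1 non-silent mutation in
    gene i) / |patients|.  Silent records are kept in ``records`` but
    excluded from every derived structure.
    """

    records: pd.DataFrame  # columns: gene, patient, variant_class
    silent_classes: frozenset = DEFAULT_SILENT_CLASSES
    patients: tuple = ()
    _by_patient: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.patients:
            self.patients = tuple(sorted(self.records["patient"].unique()))
        nonsilent = self.records[
            ~self.records["variant_class"].isin(self.silent_classes)
            & self.records["patient"].isin(self.patients)
        ]
        by_patient: dict[str, set[str]] = {p: set() for p in self.patients}
        for gene, patient in zip(nonsilent["gene"], nonsilent["patient"]):
            by_patient[patient].add(gene)
        self._by_patient = by_patient

    def mutated_genes(self, patient: str) -> frozenset[str]:
        """Genes carrying >=1 non-silent mutation in this patient."""
        return frozenset(self._by_patient.get(patient, frozenset()))

    @property
    def all_mutated_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self._by_patient.values():
            out |= genes
        return frozenset(out)

    def mutation_frequency(self, gene: str) -> float:
        """MF(i): fraction of cohort patients with a non-silent mutation in i."""
        if not self.patients:
            return 0.0
        n = sum(1 for genes in self._by_patient.values() if gene in genes)
        return n / len(self.patients)

    @property
    def mf(self) -> dict[str, float]:
        """Mutation frequency for every gene mutated at least once."""
        denom = len(self.patients)
        counts: dict[str, int] = {}
        for genes in self._by_patient.values():
            for g in genes:
                counts[g] = counts.get(g, 0) + 1
        return {g: c / denom for g, c in sorted(counts.items())}

    def restrict(self, patients: Iterable[str]) -> "MutationTable":
        """A new table whose cohort universe is ``patients``.

        Records of patients outside the universe are dropped; MF is
        recomputed over the new denominator.
        """
        universe = tuple(sorted(set(patients)))
        kept = self.records[self.records["patient"].isin(universe)].reset_index(drop=True)
        return MutationTable(records=kept, silent_classes=self.silent_classes,
                             patients=universe)


def read_maf(
    path: str | Path,
    silent_classes: Iterable[str] = DEFAULT_SILENT_CLASSES,
    gene_col: str = MAF_GENE_COL,
    patient_col: str = MAF_PATIENT_COL,
    class_col: str = MAF_CLASS_COL,
) -> MutationTable:
    """Read a MAF-lite mutation TSV into a :class:`MutationTable`.

    Silent records (``silent_classes``, default ``{"Silent"}``) are excluded
    from the derived mutated-gene sets and mutation frequencies.  An empty
    table after filtering yields a warning, not an error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in (gene_col, patient_col, class_col):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    silent = frozenset(silent_classes)
    records = df[[gene_col, patient_col, class_col]].rename(columns={
        gene_col: "gene", patient_col: "patient", class_col: "variant_class",
    })
    n_silent = int(records["variant_class"].isin(silent).sum())
    logger.info("read_maf(%s): %d records, %d silent (excluded from MF)",
                path.name, len(records), n_silent)
    table = MutationTable(records=records, silent_classes=silent)
    if not table.all_mutated_genes:
        logger.warning("read_maf(%s): no non-silent mutations after filtering", path.name)
    return table


# ---------------------------------------------------------------------------
# reference gene sets and annotations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferenceGeneSet:
    """A named set of reference genes (e.g. known cancer genes)."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"reference gene set {self.name!r} is empty")


def read_gene_set(path: str | Path, name: str | None = None) -> ReferenceGeneSet:
    """Read a one-symbol-per-line gene set; duplicates are collapsed."""
    path = Path(path)
    genes = {line.strip() for line in path.open() if line.strip()}
    if not genes:
        raise ValidationError(f"{path}: empty gene set")
    return ReferenceGeneSet(name=name or path.stem, genes=frozenset(genes))


def read_annotation(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a pre-flattened gene->term TSV into term -> gene-set mapping.

    Two columns per line: gene TAB term.  Flattening a term hierarchy (e.g.
    restricting GO annotations to a fixed level) is the caller's
    responsibility.
    """
    path = Path(path)
    terms: dict[str, set[str]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ValidationError(f"{path}:{lineno}: expected gene TAB term")
            gene, term = parts[0], parts[1]
            terms.setdefault(term, set()).add(gene)
    if not terms:
        raise ValidationError(f"{path}: empty annotation")
    return {t: frozenset(g) for t, g in terms.items()}


# ---------------------------------------------------------------------------
# ranking output
# ---------------------------------------------------------------------------

RANKING_COLUMNS = ("rank", "gene", "score", "degree_component", "win_component", "note")


def write_ranking(ranking, path: str | Path) -> None:
    """Write a :class:`~betweennet.ranking.RankedList` as TSV.

    Columns: rank, gene, score, degree_component, win_component, note
    (note is "no-network" for mutated genes absent from the PPI).
    """
    path = Path(path)
    rows = [
        {
            "rank": e.rank,
            "gene": e.gene,
            "score": f"{e.score:.10g}",
            "degree_component": f"{e.degree_component:.10g}",
            "win_component": f"{e.win_component:.10g}",
            "note": e.note,
        }
        for e in ranking.entries
    ]
    pd.DataFrame(rows, columns=RANKING_COLUMNS).to_csv(path, sep="\t", index=False)


def read_ranking(path: str | Path):
    """Re-read a ranking TSV written by :func:`write_ranking`."""
    from .ranking import RankedList, RankEntry  # local import to avoid cycle

    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "note": str})
    df["note"] = df["note"].fillna("")
    entries = [
        RankEntry(
            rank=int(r["rank"]), gene=str(r["gene"]), score=float(r["score"]),
            degree_component=float(r["degree_component"]),
            win_component=float(r["win_component"]), note=str(r["note"]),
        )
        for _, r in df.iterrows()
    ]
    return RankedList(entries=entries, alpha=float("nan"))
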