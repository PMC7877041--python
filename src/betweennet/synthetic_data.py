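"""Seeded generator of desk-scale cohorts with planted driver genes.

The generator emulates the structure the pipeline consumes: a random PPI,
paired normal/tumor expression for a small cohort, and a mutation table.
A handful of planted "drivers" (mid-to-high-degree network nodes) are
mutated recurrently across patients; in a patient carrying a driver
mutation, genes within a small network radius of the driver are knocked
below the expression threshold in the tumor sample.  Dropping those genes
from the patient's tumor network perturbs the betweenness of their
surviving neighbors -- including other neighbors of the driver -- which is
exactly the topological signal the pipeline detects: outliers adjacent to
the drivers that caused them.  Passenger mutations are sprinkled uniformly
and cause no dysregulation; silent records exercise the MAF filter.

All randomness flows from a single seed; the written files are
byte-identical across runs with the same spec.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

NONSILENT_CLASSES = ("Missense_Mutation", "Nonsense_Mutation", "Frame_Shift_Del")


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Parameters of a synthetic paired-cohort benchmark.

    Defaults describe the standard desk-scale study condition: a 200-gene
    scale-free PPI, 30 paired patients and 5 planted drivers, each driver
    mutated in about half the cohort, with single-hop dysregulation.
    """

    n_genes: int = 200
    n_patients: int = 30
    ppi_model: str = "ba"  # "ba" (Barabasi-Albert) | "er" (Erdos-Renyi)
    ba_m: int = 2
    er_p: float = 0.04
    n_drivers: int = 5
    driver_mutation_prob: float = 0.5
    passenger_rate: float = 0.02
    dysregulation_radius: int = 1
    dysregulation_prob: float = 0.7
    knockdown_factor: float = 1e-3
    baseline_log_mean: float = 5.0
    baseline_log_sd: float = 0.5
    tumor_noise_sd: float = 0.05
    silent_fraction: float = 0.1
    expression_threshold: float = 5.0
    seed: int = 7

    def validate(self) -> None:
        if self.n_drivers >= self.n_genes:
            raise ValueError("n_drivers must be < n_genes")
        for name in ("driver_mutation_prob", "passenger_rate",
                     "dysregulation_prob", "silent_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.ppi_model not in ("ba", "er"):
            raise ValueError(f"ppi_model must be 'ba' or 'er', got {self.ppi_model!r}")
        if self.n_genes < 3 or self.n_patients < 1:
            raise ValueError("need n_genes >= 3 and n_patients >= 1")
        if self.dysregulation_radius < 0:
            raise ValueError("dysregulation_radius must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticCohortSpec":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown spec fields: {sorted(unknown)}")
        return cls(**data)


@dataclass(frozen=True)
class SyntheticCohort:
    """Paths of the generated input files plus the planted truth."""

    ppi: Path
    expr_normal: Path
    expr_tumor: Path
    maf: Path
    truth: Path
    drivers: tuple[str, ...]


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _patient_names(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"P{i:0{width}d}" for i in range(1, n + 1)]


def _sample_ppi(spec: SyntheticCohortSpec, rng: np.random.Generator) -> nx.Graph:
    graph_seed = int(rng.integers(2**31))
    if spec.ppi_model == "ba":
        g = nx.barabasi_albert_graph(spec.n_genes, spec.ba_m, seed=graph_seed)
    else:
        g = nx.erdos_renyi_graph(spec.n_genes, spec.er_p, seed=graph_seed)
    names = _gene_names(spec.n_genes)
    return nx.relabel_nodes(g, dict(enumerate(names)))


def _pick_drivers(
    graph: nx.Graph, n_drivers: int, rng: np.random.Generator
) -> list[str]:
    """Prefer mid-to-high-degree nodes (50th-95th degree percentile)."""
    if n_drivers == 0:
        return []
    degrees = dict(graph.degree())
    nodes = sorted(degrees, key=lambda g: (degrees[g], g))
    lo = int(0.5 * len(nodes))
    hi = max(lo + n_drivers, int(0.95 * len(nodes)))
    pool = nodes[lo:hi]
    picked = rng.choice(len(pool), size=n_drivers, replace=False)
    return sorted(pool[i] for i in picked)


def generate(spec: SyntheticCohortSpec, outdir: str | Path) -> SyntheticCohort:
    """Write all pipeline inputs plus a truth file of planted drivers.

    Files: ``ppi.tsv`` (edge list), ``expr_normal.tsv`` / ``expr_tumor.tsv``
    (genes x patients), ``mutations.maf`` (MAF-lite TSV) and ``truth.tsv``
    (one driver symbol per line).
    """
    spec.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    graph = _sample_ppi(spec, rng)
    genes = _gene_names(spec.n_genes)
    patients = _patient_names(spec.n_patients)
    drivers = _pick_drivers(graph, spec.n_drivers, rng)
    passenger_pool = [g for g in genes if g not in drivers]

    # --- mutations ---------------------------------------------------------
    mutated: dict[str, set[str]] = {p: set() for p in patients}
    for p in patients:
        for d in drivers:
            if rng.random() < spec.driver_mutation_prob:
                mutated[p].add(d)
        hits = rng.random(len(passenger_pool)) < spec.passenger_rate
        mutated[p].update(g for g, h in zip(passenger_pool, hits) if h)
    # every planted driver must appear in the mutation table at least once
    for d in drivers:
        if not any(d in mutated[p] for p in patients):
            mutated[patients[int(rng.integers(len(patients)))]].add(d)

    # --- expression --------------------------------------------------------
    normal = rng.lognormal(
        mean=spec.baseline_log_mean, sigma=spec.baseline_log_sd,
        size=(spec.n_genes, spec.n_patients),
    )
    normal = np.maximum(normal, spec.expression_threshold + 1.0)
    tumor = normal.copy()
    if spec.tumor_noise_sd > 0:
        tumor = tumor * rng.lognormal(
            mean=0.0, sigma=spec.tumor_noise_sd, size=tumor.shape
        )
    gene_index = {g: i for i, g in enumerate(genes)}
    for pj, p in enumerate(patients):
        knocked: set[str] = set()
        for d in drivers:
            if d not in mutated[p]:
                continue
            ball = nx.single_source_shortest_path_length(
                graph, d, cutoff=spec.dysregulation_radius
            )
            for g in sorted(ball):
                if g == d or g in knocked:
                    continue
                if rng.random() < spec.dysregulation_prob:
                    knocked.add(g)
        for g in knocked:
            tumor[gene_index[g], pj] *= spec.knockdown_factor

    # --- serialize ---------------------------------------------------------
    ppi_path = outdir / "ppi.tsv"
    with ppi_path.open("w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in graph.edges()):
            fh.write(f"{u}\t{v}\n")

    def write_expr(matrix: np.ndarray, path: Path) -> None:
        df = pd.DataFrame(matrix, index=genes, columns=patients)
        df.index.name = "gene"
        df.to_csv(path, sep="\t", float_format="%.4f")

    expr_n_path = outdir / "expr_normal.tsv"
    expr_t_path = outdir / "expr_tumor.tsv"
    write_expr(normal, expr_n_path)
    write_expr(tumor, expr_t_path)

    records: list[tuple[str, str, str]] = []
    for p in patients:
        for g in sorted(mutated[p]):
            vc = NONSILENT_CLASSES[int(rng.integers(len(NONSILENT_CLASSES)))]
            records.append((g, p, vc))
    if spec.silent_fraction > 0 and records:
        n_silent = round(
            spec.silent_fraction * len(records) / (1.0 - spec.silent_fraction)
        )
        for _ in range(n_silent):
            g = genes[int(rng.integers(len(genes)))]
            p = patients[int(rng.integers(len(patients)))]
            records.append((g, p, "Silent"))
    maf_path = outdir / "mutations.maf"
    maf = pd.DataFrame(
        records,
        columns=["Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification"],
    )
    maf.to_csv(maf_path, sep="\t", index=False)

    truth_path = outdir / "truth.tsv"
    truth_path.write_text("".join(f"{d}\n" for d in drivers))

    return SyntheticCohort(
        ppi=ppi_path, expr_normal=expr_n_path, expr_tumor=expr_t_path,
        maf=maf_path, truth=truth_path, drivers=tuple(drivers),
    )
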