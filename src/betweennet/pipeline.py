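"""End-to-end orchestration: inputs -> personalized networks -> betweenness
-> outliers -> influence graph -> random walk -> ranking, with a manifest.

The pipeline is deterministic: per-patient betweenness jobs are independent
and may run in parallel workers, and results are assembled in sorted
patient order, so output is identical for any worker count.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml
from joblib import Parallel, delayed

from . import data_io
from .bipartite_influence import build_influence_graph
from .data_io import ValidationError
from .evaluation import consistency, enrich, rare_subset, roc_auc, shared_term_count
from .kbetweenness import betweenness_diff
from .outlier_detection import call_outliers
from .personalized_networks import build_patient_networks
from .random_walk import walk
from .ranking import final_output, rank_genes

logger = logging.getLogger("betweennet")


@dataclass
class RunConfig:
    """All pipeline inputs and parameters; defaults are the method's
    standard setting (k=3, t=0.5, beta=0.4, alpha=0.5, expression
    threshold 5, top-1000 ranking)."""

    ppi: str = ""
    expr_normal: str = ""
    expr_tumor: str = ""
    maf: str = ""
    out_dir: str = "betweennet_out"
    k: int = 3
    t: float = 0.5
    beta: float = 0.4
    alpha: float = 0.5
    expression_threshold: float = 5.0
    max_rank: int = 1000
    tol: float = 1e-6
    max_iter: int = 1000
    silent_classes: tuple = ("Silent",)
    fit_scope: str = "per-gene"
    min_obs: int = 5
    seed: int = 0
    n_jobs: int = 1
    keep_intermediates: bool = False

    def validate(self) -> None:
        required = ("ppi", "expr_normal", "expr_tumor", "maf")
        for name in required:
            if not getattr(self, name):
                raise ValidationError(f"config: missing required path {name!r}")
        for name in required:
            path = getattr(self, name)
            if not Path(path).is_file():
                raise ValidationError(f"config: {name} path not found: {path}")
        if self.k < 1:
            raise ValidationError(f"config: k must be >= 1, got {self.k}")
        if self.t < 0:
            raise ValidationError(f"config: t must be >= 0, got {self.t}")
        if not 0.0 <= self.beta <= 1.0:
            raise ValidationError(f"config: beta must be in [0, 1], got {self.beta}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValidationError(f"config: alpha must be in [0, 1], got {self.alpha}")
        if self.max_rank < 1:
            raise ValidationError(f"config: max_rank must be >= 1, got {self.max_rank}")
        if self.fit_scope not in ("per-gene", "global"):
            raise ValidationError(
                f"config: fit_scope must be 'per-gene' or 'global', got {self.fit_scope!r}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValidationError(f"config: unknown keys {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**data)
        if isinstance(cfg.silent_classes, (list, set)):
            cfg.silent_classes = tuple(sorted(cfg.silent_classes))
        return cfg


def _patient_table(ppi, expr_normal, expr_tumor, mutations, patient, threshold, k):
    networks = build_patient_networks(
        ppi, expr_normal, expr_tumor, mutations, patient, threshold
    )
    return betweenness_diff(ppi, networks, k=k)


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest (also written to disk).

    Writes ``ranking.tsv`` and ``manifest.json`` to ``config.out_dir``, plus
    per-stage dumps (betweenness, outliers, bipartite edges, w_in) when
    ``keep_intermediates`` is set.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    ppi = data_io.read_ppi(config.ppi)
    expr_normal = data_io.read_expression(config.expr_normal, "normal")
    expr_tumor = data_io.read_expression(config.expr_tumor, "tumor")
    mutations_raw = data_io.read_maf(config.maf, silent_classes=config.silent_classes)

    # cohort = patients with both expression modalities and mutation records
    patients = sorted(
        set(expr_normal.patients) & set(expr_tumor.patients)
        & set(mutations_raw.patients)
    )
    dropped = (
        set(expr_normal.patients) | set(expr_tumor.patients)
        | set(mutations_raw.patients)
    ) - set(patients)
    if dropped:
        logger.warning("dropping %d patients missing a modality: %s%s",
                       len(dropped), sorted(dropped)[:5],
                       "..." if len(dropped) > 5 else "")
    if not patients:
        raise ValidationError("no patient has all three modalities")
    mutations = mutations_raw.restrict(patients)

    tables = Parallel(n_jobs=config.n_jobs)(
        delayed(_patient_table)(
            ppi, expr_normal, expr_tumor, mutations, p,
            config.expression_threshold, config.k,
        )
        for p in patients
    )
    table = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame(
        columns=["patient", "gene", "b_normal", "b_tumor", "b_diff"]
    )

    outliers = call_outliers(
        table, t=config.t, min_obs=config.min_obs, scope=config.fit_scope
    )
    influence = build_influence_graph(ppi, mutations, outliers)
    result = walk(
        influence, beta=config.beta, tol=config.tol, max_iter=config.max_iter
    )
    ranked = rank_genes(
        influence, result.w_in, alpha=config.alpha, max_rank=config.max_rank
    )
    ranked = final_output(ranked, influence.no_network_genes)

    ranking_path = out_dir / "ranking.tsv"
    data_io.write_ranking(ranked, ranking_path)

    manifest = {
        "parameters": {
            "k": config.k, "t": config.t, "beta": config.beta,
            "alpha": config.alpha,
            "expression_threshold": config.expression_threshold,
            "max_rank": config.max_rank, "tol": config.tol,
            "max_iter": config.max_iter,
            "silent_classes": sorted(config.silent_classes),
            "fit_scope": config.fit_scope, "min_obs": config.min_obs,
            "seed": config.seed,
        },
        "counts": {
            "ppi_nodes": ppi.number_of_nodes(),
            "ppi_edges": ppi.number_of_edges(),
            "patients_used": len(patients),
            "outliers_per_patient": {
                p: len(outliers.outlier_genes(p)) for p in patients
            },
            "mutations_partition": len(influence.mutated_genes),
            "outliers_partition": len(influence.occurrences),
            "bipartite_edges": influence.graph.number_of_edges(),
            "no_network_genes": len(influence.no_network_genes),
            "walk_iterations": result.iterations,
            "walk_residual": result.residual,
            "ranked_genes": len(ranked),
        },
    }
    with (out_dir / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    if config.keep_intermediates:
        table.to_csv(out_dir / "betweenness.tsv", sep="\t", index=False,
                     float_format="%.10g")
        out_rows = [
            {"patient": p, "gene": g}
            for p in patients for g in sorted(outliers.outlier_genes(p))
        ]
        pd.DataFrame(out_rows, columns=["patient", "gene"]).to_csv(
            out_dir / "outliers.tsv", sep="\t", index=False
        )
        edge_rows = [
            {"mutated_gene": u, "outlier_gene": v[0], "patient": v[1]}
            for u, v in influence.graph.edges()
            if isinstance(v, tuple)
        ] + [
            {"mutated_gene": v, "outlier_gene": u[0], "patient": u[1]}
            for u, v in influence.graph.edges()
            if isinstance(u, tuple)
        ]
        pd.DataFrame(
            edge_rows, columns=["mutated_gene", "outlier_gene", "patient"]
        ).sort_values(
            ["mutated_gene", "outlier_gene", "patient"]
        ).to_csv(out_dir / "bipartite.tsv", sep="\t", index=False)
        win_rows = [
            {"gene": g, "w_in": f"{result.w_in[g]:.10g}"}
            for g in influence.mutated_genes
        ]
        pd.DataFrame(win_rows, columns=["gene", "w_in"]).to_csv(
            out_dir / "win.tsv", sep="\t", index=False
        )
    return manifest


def evaluate_ranking(
    ranking_path: str | Path,
    reference_path: str | Path,
    maf_path: str | Path | None = None,
    annotation_path: str | Path | None = None,
    cutoff: int | None = None,
    rare_cutoff: float = 0.02,
    silent_classes: tuple = ("Silent",),
) -> dict:
    """Evaluate a written ranking against a reference gene set.

    Reports AUROC over the ranked list (up to ``cutoff``), a rare-driver
    stratified AUROC when a MAF is supplied (cohort MF <= ``rare_cutoff``),
    and, when an annotation is supplied, term enrichment of the ranked
    genes and the reference plus their consistency (intersection over
    union of significant term sets).
    """
    ranked = data_io.read_ranking(ranking_path)
    reference = data_io.read_gene_set(reference_path)
    genes = ranked.genes
    use_cutoff = min(cutoff, len(genes)) if cutoff else len(genes)
    report: dict = {
        "reference": reference.name,
        "n_ranked": len(genes),
        "cutoff": use_cutoff,
        "auroc": roc_auc(genes, reference, cutoff=use_cutoff).auroc,
    }
    if maf_path is not None:
        mutations = data_io.read_maf(maf_path, silent_classes=silent_classes)
        rare = rare_subset(reference, mutations, freq_cutoff=rare_cutoff)
        if rare is not None and rare.genes & set(genes):
            report["auroc_rare"] = roc_auc(genes, rare, cutoff=use_cutoff).auroc
        else:
            report["auroc_rare"] = None
    if annotation_path is not None:
        annotation = data_io.read_annotation(annotation_path)
        universe = set(genes) | reference.genes
        enr_method = enrich(set(genes[:use_cutoff]), annotation, universe)
        enr_ref = enrich(reference.genes & universe, annotation, universe)
        report["enrichment"] = {
            "method_terms": sorted(enr_method.significant),
            "reference_terms": sorted(enr_ref.significant),
            "consistency": consistency(enr_method.significant, enr_ref.significant),
            "shared_terms": shared_term_count(
                enr_method.significant, enr_ref.significant
            ),
        }
    return report
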