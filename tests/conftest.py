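from __future__ import annotations

from pathlib import Path

import networkx as nx
import pytest
from hypothesis import HealthCheck, settings

from betweennet import RunConfig, SyntheticCohortSpec, generate, run
from betweennet.data_io import read_ranking

settings.register_profile(
    "suite",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def random_graph(n: int, p: float, seed: int, relabel: bool = True) -> nx.Graph:
    g = nx.erdos_renyi_graph(n, p, seed=seed)
    if relabel:
        g = nx.relabel_nodes(g, {i: f"g{i:02d}" for i in g.nodes})
    return g


@pytest.fixture
def toy_ppi() -> nx.Graph:
    """Small deterministic PPI used across module tests."""
    g = nx.Graph()
    g.add_edges_from([
        ("A", "B"), ("B", "C"), ("C", "D"), ("D", "A"),
        ("B", "E"), ("E", "F"), ("C", "F"),
    ])
    return g


def run_synthetic_pipeline(
    base_dir: Path,
    seed: int,
    n_drivers: int = 5,
    spec_kwargs: dict | None = None,
    **config_kwargs,
):
    """Generate a cohort and run the full pipeline; returns a result bundle."""
    spec_fields = {"n_drivers": n_drivers, **(spec_kwargs or {}), "seed": seed}
    spec = SyntheticCohortSpec(**spec_fields)
    data_dir = base_dir / f"data_s{seed}_d{n_drivers}"
    out_dir = base_dir / f"out_s{seed}_d{n_drivers}"
    cohort = generate(spec, data_dir)
    config = RunConfig(
        ppi=str(cohort.ppi),
        expr_normal=str(cohort.expr_normal),
        expr_tumor=str(cohort.expr_tumor),
        maf=str(cohort.maf),
        out_dir=str(out_dir),
        **config_kwargs,
    )
    manifest = run(config)
    ranked = read_ranking(out_dir / "ranking.tsv")
    return {
        "cohort": cohort,
        "config": config,
        "manifest": manifest,
        "ranked": ranked,
        "out_dir": out_dir,
    }


@pytest.fixture(scope="session")
def small_cohort_run(tmp_path_factory):
    """One fast end-to-end run on a reduced cohort, shared across tests."""
    base = tmp_path_factory.mktemp("small_cohort")
    return run_synthetic_pipeline(
        base, seed=11,
        spec_kwargs={"n_genes": 60, "n_patients": 8, "n_drivers": 2},
    )
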