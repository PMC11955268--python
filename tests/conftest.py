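"""Shared fixtures: a hand-built toy knowledge graph and a small synthetic
run reused by the pipeline-level tests."""

from __future__ import annotations

import numpy as np
import pytest

import dreamer as dr
from dreamer.kg import KGConfig, LinkTable, assemble_kg


def toy_tables() -> dict[str, LinkTable]:
    """Six-protein toy KG exercised throughout the unit tests.

    ADR A1 is shown by drugs D1 (targets P1, P2) and D2 (targets P2, P3);
    DP1 is shown by diseases X1 (gene P1) and X2 (genes P1, P4). D1 is
    indicated for disease IND1 (genes P5, P6). D5 is a bystander drug with
    targets P3, P6 and no ADR.
    """
    return {
        "drug_target": LinkTable("drug_target", frozenset([
            ("D1", "P1"), ("D1", "P2"), ("D2", "P2"), ("D2", "P3"),
            ("D3", "P5"), ("D4", "P6"), ("D5", "P3"), ("D5", "P6"),
        ])),
        "disease_gene": LinkTable("disease_gene", frozenset([
            ("X1", "P1"), ("X2", "P1"), ("X2", "P4"),
            ("X3", "P5"), ("X3", "P6"), ("IND1", "P5"), ("IND1", "P6"),
        ])),
        "drug_adr": LinkTable("drug_adr", frozenset([
            ("D1", "A1"), ("D2", "A1"), ("D3", "A2"),
        ])),
        "disease_dp": LinkTable("disease_dp", frozenset([
            ("X1", "DP1"), ("X2", "DP1"), ("X3", "DP2"),
        ])),
        "drug_indication": LinkTable("drug_indication", frozenset([
            ("D1", "IND1"),
        ])),
        "adr_dp": LinkTable("adr_dp", frozenset([
            ("A1", "DP1"), ("A2", "DP2"),
        ])),
    }


def toy_ppi() -> list[tuple[str, str, float]]:
    return [
        ("P1", "P2", 900), ("P2", "P3", 900), ("P3", "P4", 900),
        ("P4", "P5", 900), ("P5", "P6", 900), ("P2", "P5", 900),
    ]


@pytest.fixture
def toy_kg() -> dr.KnowledgeGraph:
    return assemble_kg(toy_tables(), toy_ppi(), KGConfig(rng_seed=0))


@pytest.fixture(scope="session")
def small_synthetic():
    """A compact planted-module KG plus a full pipeline run (B=200)."""
    params = dr.GeneratorParams(
        rng_seed=2, n_proteins=300, n_modules=3, module_size=10,
        n_pairs_planted=3, n_pairs_null=2, background_edge_prob=0.015,
    )
    kg, truth, raw = dr.generate_kg(params)
    run = dr.run_dreamer(kg, dr.PipelineParams(rng_seed=2, n_permutations=200))
    return kg, truth, raw, run


def ppr_dense_oracle(graph, seed_weights: dict, alpha: float) -> dict[str, float]:
    """Independent dense-linear-algebra fixed point: P = (1-a)(I - a W)^-1 P0.

    Built from the raw adjacency and degree vector, not from the package's
    operator, so it cross-checks the iterative implementation.
    """
    nodes = sorted(graph.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    A = np.zeros((n, n))
    for u, v in graph.edges:
        A[idx[u], idx[v]] = A[idx[v], idx[u]] = 1.0
    W = A / A.sum(axis=0, keepdims=True)
    p0 = np.zeros(n)
    for k, w in seed_weights.items():
        p0[idx[k]] = w
    sol = np.linalg.solve(np.eye(n) - alpha * W, (1 - alpha) * p0)
    return {nodes[i]: sol[i] for i in range(n)}
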