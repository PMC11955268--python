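"""Seed-vector construction and personalized PageRank over the PPI.

A seed vector assigns each PPI protein its probability of being the start of
a random walk: for an ADR, the fraction of all drug->target links (among
drugs showing that ADR) that point at the protein; for a DP, the analogous
fraction of disease->gene links; for an indication analysis, the fraction of
disease->gene links among the union of diseases indicated for the ADR's
drugs. Diffusion follows the damped iteration

    P_{t+1} = alpha * W * P_t + (1 - alpha) * P_0

with W the column-stochastic transition matrix of the (unweighted, by
default) filtered PPI and damping alpha = 0.7.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .kg import KnowledgeGraph

DEFAULT_ALPHA = 0.7
DEFAULT_TOL = 1e-12
DEFAULT_MAX_ITER = 1000


class SeedConstructionError(ValueError):
    """No qualifying link exists to build the requested seed."""


class ConvergenceError(RuntimeError):
    """Power iteration failed to reach the tolerance within max_iter."""

    def __init__(self, residual: float, max_iter: int):
        super().__init__(f"PPR did not converge within {max_iter} iterations (residual {residual:.3e})")
        self.residual = residual


@dataclass(frozen=True)
class SeedVector:
    """Probability distribution over PPI proteins initializing one diffusion."""

    weights: Mapping[str, float]
    origin: str  # adr | dp | indication
    phenotype: str

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"seed mass {total!r} != 1")
        if any(v < 0 for v in self.weights.values()):
            raise ValueError("negative seed weight")


@dataclass
class DiffusionResult:
    scores: dict[str, float]
    alpha: float
    iterations: int
    converged: bool
    residual: float


class DiffusionOperator:
    """Fixed node ordering and transition matrix for one PPI network.

    Column j of ``W`` spreads unit mass uniformly over j's neighbors
    (optionally weighted by edge confidence). Built once per graph and reused
    across seeds and permutations.
    """

    def __init__(self, ppi: nx.Graph, weighted: bool = False):
        if ppi.number_of_nodes() == 0:
            raise ValueError("empty PPI network")
        self.nodes: list[str] = sorted(ppi.nodes)
        self.index: dict[str, int] = {n: i for i, n in enumerate(self.nodes)}
        weight = "score" if weighted else None
        A = nx.to_scipy_sparse_array(ppi, nodelist=self.nodes, weight=weight, format="csr", dtype=float)
        colsum = np.asarray(A.sum(axis=0)).ravel()
        self.dangling = colsum == 0
        inv = np.where(self.dangling, 0.0, 1.0 / np.where(self.dangling, 1.0, colsum))
        self.W = (A @ sp.diags(inv)).tocsr()

    @property
    def n(self) -> int:
        return len(self.nodes)

    def seed_array(self, seed: SeedVector) -> np.ndarray:
        v = np.zeros(self.n)
        for prot, w in seed.weights.items():
            if prot not in self.index:
                raise SeedConstructionError(f"seed protein {prot!r} not in PPI")
            v[self.index[prot]] = w
        return v

    def to_dict(self, values: np.ndarray) -> dict[str, float]:
        return {n: float(values[i]) for i, n in enumerate(self.nodes)}

    def propagate(
        self,
        p0: np.ndarray,
        alpha: float = DEFAULT_ALPHA,
        tol: float = DEFAULT_TOL,
        max_iter: int = DEFAULT_MAX_ITER,
    ) -> tuple[np.ndarray, int, float]:
        """Iterate ``P <- alpha W P + (1-alpha) P0`` to the fixed point.

        ``p0`` may be a vector or an (n, B) matrix of seed columns, in which
        case all columns are propagated simultaneously. Convergence is the
        max-over-columns L1 change. Mass lost through dangling columns (only
        possible when LCC restriction was disabled) teleports back to the
        seed, the standard correction.
        """
        if not 0 <= alpha < 1:
            raise ValueError("alpha must be in [0, 1)")
        p = p0.copy().astype(float)
        has_dangling = bool(self.dangling.any())
        residual = np.inf
        for it in range(1, max_iter + 1):
            wp = self.W @ p
            if has_dangling:
                lost = p[self.dangling].sum(axis=0)
                wp = wp + p0 * lost
            nxt = alpha * wp + (1 - alpha) * p0
            diff = np.abs(nxt - p).sum(axis=0)
            residual = float(np.max(diff))
            p = nxt
            if residual < tol:
                return p, it, residual
        raise ConvergenceError(residual, max_iter)


def personalized_pagerank(
    ppi_or_operator: nx.Graph | DiffusionOperator,
    seed: SeedVector,
    alpha: float = DEFAULT_ALPHA,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    weighted: bool = False,
) -> DiffusionResult:
    """Run damped diffusion from ``seed`` and return per-protein scores."""
    op = ppi_or_operator if isinstance(ppi_or_operator, DiffusionOperator) else DiffusionOperator(ppi_or_operator, weighted=weighted)
    p0 = op.seed_array(seed)
    scores, iters, residual = op.propagate(p0, alpha=alpha, tol=tol, max_iter=max_iter)
    return DiffusionResult(
        scores=op.to_dict(scores), alpha=alpha, iterations=iters,
        converged=True, residual=residual,
    )


# ---------------------------------------------------------------------------
# Seed constructions
# ---------------------------------------------------------------------------

def _link_count_seed(
    entities: set[str],
    links_of: Mapping[str, set[str]],
    universe: set[str],
    origin: str,
    phenotype: str,
) -> SeedVector:
    counts: dict[str, int] = {}
    total = 0
    for e in sorted(entities):
        for prot in links_of.get(e, ()):  # links already restricted to PPI at assembly
            if prot in universe:
                counts[prot] = counts.get(prot, 0) + 1
                total += 1
    if total == 0:
        raise SeedConstructionError(
            f"no qualifying protein link to build the {origin} seed for {phenotype!r}"
        )
    return SeedVector(
        weights={p: c / total for p, c in counts.items()},
        origin=origin, phenotype=phenotype,
    )


def build_adr_seed(kg: KnowledgeGraph, adr: str, drugs: set[str] | None = None) -> SeedVector:
    """Seed protein i with (# links from drugs showing the ADR to i) /
    (all drug->target links among those drugs).

    ``drugs`` optionally restricts the qualifying drug set (holdout discovery
    subsets, organ-based drug removal); the formula renormalizes over the
    surviving link multiset automatically.
    """
    qualifying = kg.drugs_with_adr(adr)
    if drugs is not None:
        qualifying = qualifying & drugs
    if not qualifying:
        raise SeedConstructionError(f"no drug linked to ADR {adr!r}")
    return _link_count_seed(qualifying, kg.tables["drug_target"].by_source(), kg.proteins, "adr", adr)


def build_dp_seed(kg: KnowledgeGraph, dp: str, diseases: set[str] | None = None) -> SeedVector:
    """Seed protein i with (# links from diseases showing the DP to i) /
    (all disease->gene links among those diseases)."""
    qualifying = kg.diseases_with_dp(dp)
    if diseases is not None:
        qualifying = qualifying & diseases
    if not qualifying:
        raise SeedConstructionError(f"no disease linked to DP {dp!r}")
    return _link_count_seed(qualifying, kg.tables["disease_gene"].by_source(), kg.proteins, "dp", dp)


def build_indication_seed(kg: KnowledgeGraph, adr: str) -> SeedVector:
    """Seed from the union of diseases indicated for the ADR's drugs.

    Each indicated disease contributes its disease->gene links once, however
    many drugs share it. Raises :class:`SeedConstructionError` when no
    indicated disease has an associated gene, which excludes the phenotype
    from the indication-confounder analysis.
    """
    drugs = kg.drugs_with_adr(adr)
    if not drugs:
        raise SeedConstructionError(f"no drug linked to ADR {adr!r}")
    indications_by_drug = kg.tables["drug_indication"].by_source()
    indicated: set[str] = set()
    for d in drugs:
        indicated |= indications_by_drug.get(d, set())
    if not indicated:
        raise SeedConstructionError(f"no indication among drugs with ADR {adr!r}")
    return _link_count_seed(indicated, kg.tables["disease_gene"].by_source(), kg.proteins, "indication", adr)
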