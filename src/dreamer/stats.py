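"""Significance machinery: permutation null with exponential fit, BH
correction, hypergeometric overlap, and one-sided Fisher's exact test.

The permutation null shuffles the seed vector's entries uniformly over all
PPI proteins B times (default 1000) and re-runs the diffusion for each,
which preserves the multiset of seed masses while destroying their linkage
to the topology. Each protein's one-sided p-value comes from a
maximum-likelihood exponential fit to its own null scores (rate = 1 / null
mean): hub proteins have systematically larger null scores, so a single
pooled null would mistake centrality for signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .diffusion import DiffusionOperator, SeedVector, DEFAULT_ALPHA, DEFAULT_TOL, DEFAULT_MAX_ITER

_P_FLOOR = np.finfo(float).tiny  # p = 0 is never emitted

MIN_PERMUTATIONS = 100


@dataclass
class NullModel:
    """Per-protein means of B null diffusion scores (permuted seeds)."""

    null_mean: np.ndarray  # aligned with operator.nodes
    n_permutations: int
    rng_seed: int | None
    null_scores: np.ndarray | None = None  # (n, B), kept only on request


def permutation_null(
    operator: DiffusionOperator,
    seed: SeedVector,
    B: int = 1000,
    rng_seed: int | np.random.Generator = 0,
    alpha: float = DEFAULT_ALPHA,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    keep_null_scores: bool = False,
    batch_size: int = 256,
) -> NullModel:
    """Build the empirical null by diffusing B permuted copies of the seed.

    Permuted seeds are propagated in batches as dense (n, batch) blocks so a
    single sparse-dense product drives many permutations at once.
    """
    if B < MIN_PERMUTATIONS:
        raise ValueError(f"B={B} permutations is below the minimum of {MIN_PERMUTATIONS}")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    base = operator.seed_array(seed)
    n = operator.n
    sums = np.zeros(n)
    kept = np.empty((n, B)) if keep_null_scores else None
    done = 0
    while done < B:
        b = min(batch_size, B - done)
        p0 = np.empty((n, b))
        for j in range(b):
            p0[:, j] = base[rng.permutation(n)]
        scores, _, _ = operator.propagate(p0, alpha=alpha, tol=tol, max_iter=max_iter)
        sums += scores.sum(axis=1)
        if kept is not None:
            kept[:, done:done + b] = scores
        done += b
    return NullModel(
        null_mean=sums / B,
        n_permutations=B,
        rng_seed=None if isinstance(rng_seed, np.random.Generator) else int(rng_seed),
        null_scores=kept,
    )


def exponential_pvalue(score, null_mean):
    """Upper-tail p under an exponential MLE fit: p = exp(-score / mean).

    Accepts scalars or aligned arrays; the result is floored at the smallest
    positive float so p = 0 is never reported.
    """
    score = np.asarray(score, dtype=float)
    null_mean = np.asarray(null_mean, dtype=float)
    if np.any(null_mean <= 0):
        raise ValueError("null_mean must be positive")
    if np.any(score < 0):
        raise ValueError("diffusion scores are nonnegative")
    p = np.maximum(np.exp(-score / null_mean), _P_FLOOR)
    return float(p) if p.ndim == 0 else p


def empirical_pvalue(score: np.ndarray, null_scores: np.ndarray) -> np.ndarray:
    """Rank-based permutation p: (1 + #{null >= observed}) / (B + 1)."""
    score = np.asarray(score, dtype=float)
    exceed = (null_scores >= score[:, None]).sum(axis=1)
    return (1.0 + exceed) / (null_scores.shape[1] + 1.0)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def make_significance_table(
    proteins: list[str],
    scores: np.ndarray,
    null_mean: np.ndarray,
    alpha_level: float = 0.05,
) -> pd.DataFrame:
    """Assemble the per-protein table: score, raw p, BH-adjusted p, flag."""
    p_raw = exponential_pvalue(scores, null_mean)
    p_adj = bh_adjust(p_raw)
    return pd.DataFrame(
        {
            "score": scores,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "significant": p_adj < alpha_level,
        },
        index=pd.Index(proteins, name="protein_id"),
    )


def significant_set(table: pd.DataFrame, alpha_level: float = 0.05) -> set[str]:
    """Proteins with BH-adjusted p strictly below ``alpha_level``."""
    return set(table.index[table["p_adj"] < alpha_level])


def hypergeometric_overlap(set_a: set, set_b: set, universe: set) -> float:
    """Upper-tail hypergeometric p for the overlap of two sets in a universe.

    P(X >= |a & b|) with population |universe|, |a| successes, |b| draws.
    """
    if not (set_a <= universe and set_b <= universe):
        raise ValueError("both sets must be subsets of the universe")
    k = len(set_a & set_b)
    return float(sps.hypergeom.sf(k - 1, len(universe), len(set_a), len(set_b)))


def fisher_exact_greater(a: int, b: int, c: int, d: int) -> float:
    """One-sided (greater) Fisher exact p for the 2x2 table [[a, b], [c, d]]."""
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be nonnegative")
    return float(sps.fisher_exact([[a, b], [c, d]], alternative="greater")[1])
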