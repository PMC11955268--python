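"""Holdout validation by network proximity, and the overlap-test baseline.

Holdout design: per phenotype pair, 80% of its drugs and diseases form the
discovery set and 20% the validation set ("positive assets"); an equal
number of non-associated drugs/diseases with at least one PPI-resident
protein are sampled as "negative assets". The pipeline runs on the
discovery subsets only, and every asset is scored by the shortest-path
distance from its proteins to the discovery-phase ADR-DP set. Counts of
assets at distance <= X are pooled across phenotypes into one 2x2 table per
threshold X and tested with a one-sided Fisher exact test.

The baseline assigns a protein to a phenotype when the set of drugs (or
diseases) linked to the protein overlaps significantly (hypergeometric, BH
across proteins) with the set linked to the phenotype -- no diffusion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from . import stats as st
from .kg import KnowledgeGraph, PhenotypePair
from .pipeline import PipelineParams, identify_related_proteins, intersect_pair, finalize_intersections
from . import diffusion as dif

UNREACHABLE = math.inf  # distance when no path exists; counts as > X for all X


class HoldoutError(ValueError):
    """Holdout construction failed (too few entities or negatives)."""


@dataclass
class HoldoutSplit:
    """One phenotype's discovery/validation/negative asset partition."""

    pair: PhenotypePair
    discovery_drugs: set[str]
    validation_drugs: set[str]
    negative_drugs: set[str]
    discovery_diseases: set[str]
    validation_diseases: set[str]
    negative_diseases: set[str]
    rng_seed: int


@dataclass
class HoldoutReport:
    """Pooled 2x2 counts and Fisher p-values per shortest-path threshold X."""

    asset_kind: str  # drug | disease
    split_policy: str  # random | dissimilarity
    rows: pd.DataFrame  # columns: X, a, b, c, d, fisher_p
    n_pairs_pooled: int = 0
    skipped: dict[str, str] = field(default_factory=dict)


def _split_sizes(n: int, frac: float) -> tuple[int, int]:
    """Validation size = max(1, round((1-frac) * n)); discovery gets the rest."""
    n_val = max(1, round((1 - frac) * n))
    if n_val >= n:
        raise HoldoutError(f"cannot split {n} entities at frac={frac}")
    return n - n_val, n_val


def make_holdout_split(
    kg: KnowledgeGraph,
    pair: PhenotypePair,
    frac: float = 0.8,
    rng_seed: int = 0,
) -> HoldoutSplit:
    """Random 80/20 split plus size-matched negative assets.

    Negatives are sampled uniformly from drugs (diseases) not linked to the
    phenotype that have at least one PPI-resident target (gene), so their
    network distance is defined. Deterministic given ``rng_seed``.
    """
    rng = np.random.default_rng(rng_seed)
    drugs = sorted(kg.drugs_with_adr(pair.adr_id))
    diseases = sorted(kg.diseases_with_dp(pair.dp_id))
    if len(drugs) < 2 or len(diseases) < 2:
        raise HoldoutError(
            f"pair {pair.key} needs >=2 drugs and >=2 diseases (has {len(drugs)}/{len(diseases)})"
        )

    def _partition(items: list[str]) -> tuple[set[str], set[str]]:
        n_disc, n_val = _split_sizes(len(items), frac)
        perm = rng.permutation(len(items))
        shuffled = [items[i] for i in perm]
        return set(shuffled[:n_disc]), set(shuffled[n_disc:])

    disc_drugs, val_drugs = _partition(drugs)
    disc_dis, val_dis = _partition(diseases)

    def _negatives(pool: list[str], exclude: set[str], k: int, kind: str) -> set[str]:
        candidates = sorted(set(pool) - exclude)
        if len(candidates) < k:
            raise HoldoutError(f"not enough negative {kind}s for pair {pair.key}")
        picked = rng.choice(len(candidates), size=k, replace=False)
        return {candidates[i] for i in picked}

    targets_by_drug = kg.tables["drug_target"].by_source()
    genes_by_disease = kg.tables["disease_gene"].by_source()
    drug_pool = [d for d in sorted(kg.drugs) if targets_by_drug.get(d)]
    disease_pool = [d for d in sorted(kg.diseases) if genes_by_disease.get(d)]
    neg_drugs = _negatives(drug_pool, set(drugs), len(val_drugs), "drug")
    neg_dis = _negatives(disease_pool, set(diseases), len(val_dis), "disease")
    return HoldoutSplit(
        pair=pair,
        discovery_drugs=disc_drugs, validation_drugs=val_drugs, negative_drugs=neg_drugs,
        discovery_diseases=disc_dis, validation_diseases=val_dis, negative_diseases=neg_dis,
        rng_seed=rng_seed,
    )


def asset_distance(ppi: nx.Graph, asset_proteins: set[str], target_set: set[str]) -> float:
    """Min unweighted shortest-path length from any asset protein to the set.

    0 when the sets intersect; ``UNREACHABLE`` (inf) when no asset protein
    reaches the set.
    """
    if not target_set:
        raise ValueError("target_set must be nonempty")
    present = {p for p in asset_proteins if p in ppi}
    if not present:
        return UNREACHABLE
    if present & target_set:
        return 0.0
    dist = _distances_from_set(ppi, target_set)
    best = min((dist.get(p, UNREACHABLE) for p in present), default=UNREACHABLE)
    return best


def _distances_from_set(ppi: nx.Graph, target_set: set[str]) -> dict[str, float]:
    """Multi-source BFS: distance of every reachable node to the nearest source."""
    from collections import deque

    sources = [p for p in target_set if p in ppi]
    if not sources:
        return {}
    dist: dict[str, float] = {s: 0.0 for s in sources}
    queue = deque(sources)
    while queue:
        u = queue.popleft()
        for v in ppi.neighbors(u):
            if v not in dist:
                dist[v] = dist[u] + 1.0
                queue.append(v)
    return dist


def holdout_fisher(
    kg: KnowledgeGraph,
    splits: Sequence[HoldoutSplit],
    discovery_sets: Mapping[str, set[str]],
    x_max: int = 6,
    split_policy: str = "random",
) -> dict[str, HoldoutReport]:
    """Pool distance counts across phenotypes into one 2x2 per threshold X.

    ``discovery_sets`` maps pair keys to the ADR-DP protein sets identified
    on the discovery subsets; pairs whose discovery set is empty contribute
    no assets (distance to an empty set is undefined) and are recorded under
    ``skipped``. Returns one report per asset kind (drug, disease).
    """
    reports: dict[str, HoldoutReport] = {}
    for kind in ("drug", "disease"):
        pos_dists: list[float] = []
        neg_dists: list[float] = []
        skipped: dict[str, str] = {}
        n_pooled = 0
        for split in splits:
            target = discovery_sets.get(split.pair.key, set())
            if not target:
                skipped[split.pair.key] = "empty discovery ADR-DP set"
                continue
            dist_map = _distances_from_set(kg.ppi, target)
            if kind == "drug":
                positives, negatives = split.validation_drugs, split.negative_drugs
                proteins_of = kg.tables["drug_target"].by_source()
            else:
                positives, negatives = split.validation_diseases, split.negative_diseases
                proteins_of = kg.tables["disease_gene"].by_source()

            def _d(entity: str) -> float:
                prots = proteins_of.get(entity, set())
                return min((dist_map.get(p, UNREACHABLE) for p in prots), default=UNREACHABLE)

            pos_dists.extend(_d(e) for e in sorted(positives))
            neg_dists.extend(_d(e) for e in sorted(negatives))
            n_pooled += 1
        if not pos_dists:
            raise HoldoutError(f"no {kind} assets pooled (all pairs skipped)")
        rows = []
        pos = np.asarray(pos_dists)
        neg = np.asarray(neg_dists)
        for x in range(x_max + 1):
            a = int((pos <= x).sum())
            b = int((pos > x).sum())
            c = int((neg <= x).sum())
            d = int((neg > x).sum())
            rows.append({"X": x, "a": a, "b": b, "c": c, "d": d,
                         "fisher_p": st.fisher_exact_greater(a, b, c, d)})
        reports[kind] = HoldoutReport(
            asset_kind=kind, split_policy=split_policy,
            rows=pd.DataFrame(rows), n_pairs_pooled=n_pooled, skipped=skipped,
        )
    return reports


def run_holdout(
    kg: KnowledgeGraph,
    params: PipelineParams | None = None,
    frac: float = 0.8,
    x_max: int = 6,
    rng_seed: int = 0,
) -> tuple[dict[str, HoldoutReport], dict[str, set[str]], list[HoldoutSplit]]:
    """Full holdout experiment: split, discovery-phase pipeline, pooled Fisher.

    The discovery phase reruns the identification with the ADR's drugs and
    the DP's diseases restricted to the discovery subsets, then applies the
    cross-pair BH to the discovery intersections, mirroring the main run.
    """
    params = params or PipelineParams()
    op = dif.DiffusionOperator(kg.ppi, weighted=params.weighted)
    splits: list[HoldoutSplit] = []
    results = []
    skipped: dict[str, str] = {}
    for i, pair in enumerate(sorted(kg.pairs, key=lambda p: p.key)):
        try:
            split = make_holdout_split(kg, pair, frac=frac, rng_seed=rng_seed + i)
        except HoldoutError as exc:
            skipped[pair.key] = str(exc)
            continue
        try:
            adr_table = identify_related_proteins(
                kg, pair.adr_id, "adr", params, op, restrict_entities=split.discovery_drugs)
            dp_table = identify_related_proteins(
                kg, pair.dp_id, "dp", params, op, restrict_entities=split.discovery_diseases)
        except (dif.SeedConstructionError, dif.ConvergenceError) as exc:
            skipped[pair.key] = str(exc)
            continue
        splits.append(split)
        results.append(intersect_pair(kg, pair, adr_table, dp_table, params.alpha_level))
    finalize_intersections(results, params.alpha_level)
    discovery_sets = {r.pair.key: r.adr_dp_proteins for r in results}
    reports = holdout_fisher(kg, splits, discovery_sets, x_max=x_max)
    for rep in reports.values():
        rep.skipped.update(skipped)
    return reports, discovery_sets, splits


def dissimilarity_split_hook(
    drugs: Sequence[str],
    similarity_provider: Callable[[str, str], float] | None,
    frac: float = 0.8,
) -> tuple[set[str], set[str]]:
    """Split drugs so the two sets are mutually dissimilar (pluggable policy).

    ``similarity_provider(a, b)`` must return a pairwise similarity (e.g.,
    Tanimoto over fingerprints, supplied by the caller -- no fingerprinting
    happens here). Greedy assignment: seed the validation set with the drug
    least similar to the rest, then grow it with the drug most similar to the
    current validation set (keeping clusters together) until it reaches the
    20% size. With a constant provider the order degenerates to the stable
    input order, i.e., an arbitrary (effectively random) split.
    """
    if similarity_provider is None:
        raise ValueError("no similarity provider supplied; use the random split instead")
    items = sorted(drugs)
    if len(items) < 2:
        raise HoldoutError("need >=2 drugs to split")
    _, n_val = _split_sizes(len(items), frac)
    total_sim = {a: sum(similarity_provider(a, b) for b in items if b != a) for a in items}
    first = min(items, key=lambda a: (total_sim[a], a))
    validation = {first}
    while len(validation) < n_val:
        remaining = [a for a in items if a not in validation]
        nxt = max(remaining, key=lambda a: (sum(similarity_provider(a, v) for v in validation), a))
        validation.add(nxt)
    return set(items) - validation, validation


def baseline_protein_assoc(
    kg: KnowledgeGraph,
    phenotype: str,
    origin: str = "adr",
    alpha_level: float = 0.05,
) -> set[str]:
    """Overlap-test baseline: no diffusion, direct drug/disease sharing.

    For each PPI protein, tests whether the drugs (diseases) linked to the
    protein overlap the drugs (diseases) linked to the phenotype more than
    chance (hypergeometric upper tail, universe = all drugs [diseases] in the
    KG), BH-corrected across proteins.
    """
    if origin == "adr":
        entity_universe = kg.drugs
        linked = kg.drugs_with_adr(phenotype)
        by_protein = kg.tables["drug_target"].by_target()
    elif origin == "dp":
        entity_universe = kg.diseases
        linked = kg.diseases_with_dp(phenotype)
        by_protein = kg.tables["disease_gene"].by_target()
    else:
        raise ValueError(f"baseline origin must be adr or dp, got {origin!r}")
    proteins = sorted(kg.proteins)
    pvals = np.ones(len(proteins))
    for i, prot in enumerate(proteins):
        entities = by_protein.get(prot, set())
        if entities and linked:
            pvals[i] = st.hypergeometric_overlap(entities, linked, entity_universe)
    p_adj = st.bh_adjust(pvals)
    return {prot for prot, q in zip(proteins, p_adj) if q < alpha_level}


def known_overlap_count(
    results: Mapping[str, set[str]],
    known: Mapping[str, set[str]],
    universe: set[str],
    alpha_level: float = 0.05,
) -> int:
    """Count phenotypes whose result set overlaps its known-protein set
    significantly (hypergeometric, BH across phenotypes, adjusted p < 0.05)."""
    keys = sorted(set(results) & set(known))
    if not keys:
        return 0
    pvals = []
    for k in keys:
        a, b = results[k] & universe, known[k] & universe
        pvals.append(1.0 if not (a and b) else st.hypergeometric_overlap(a, b, universe))
    p_adj = st.bh_adjust(pvals)
    return int(np.sum(p_adj < alpha_level))
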