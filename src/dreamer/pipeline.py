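"""End-to-end orchestration: per-phenotype protein identification, pair
intersection, confounder analyses, and diffusion-map export.

For every ADR-DP phenotype pair the pipeline (i) diffuses from the ADR's
drug targets and the DP's disease genes, (ii) calls significant proteins on
each side against a permuted-seed null, (iii) intersects the two significant
sets, keeping the intersection only when its hypergeometric overlap survives
a BH correction across all pairs in the run. Two confounder controls follow:
an organ/tissue rerun that removes drugs indicated for the same organ as the
ADR, and an overlap test against indication-related proteins.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import diffusion as dif
from . import stats as st
from .kg import KnowledgeGraph, PhenotypePair


@dataclass
class PipelineParams:
    """Knobs shared by every diffusion/significance computation in a run."""

    alpha: float = dif.DEFAULT_ALPHA  # PPR damping factor
    tol: float = dif.DEFAULT_TOL
    max_iter: int = dif.DEFAULT_MAX_ITER
    n_permutations: int = 1000  # B
    alpha_level: float = 0.05  # strict BH-adjusted threshold
    rng_seed: int = 0  # master seed; per-phenotype streams derive from it
    weighted: bool = False  # use PPI confidence scores as transition weights
    keep_null_scores: bool = False


def _substream(master_seed: int, *labels: str) -> np.random.Generator:
    """Deterministic per-phenotype RNG independent of iteration order."""
    key = zlib.crc32("|".join(labels).encode("utf-8"))
    return np.random.default_rng([int(master_seed) & 0x7FFFFFFF, key])


@dataclass
class ADRDPResult:
    """Outcome for one phenotype pair."""

    pair: PhenotypePair
    adr_set: set[str]
    dp_set: set[str]
    intersection: set[str]
    hyper_p: float
    hyper_p_adj: float = float("nan")
    adr_dp_proteins: set[str] = field(default_factory=set)
    adr_table: pd.DataFrame | None = None
    dp_table: pd.DataFrame | None = None


@dataclass
class RunResult:
    results: list[ADRDPResult]
    errors: dict[str, str]
    params: PipelineParams
    n_pairs_tested: int = 0
    n_pairs_significant: int = 0

    def ranked(self) -> list[ADRDPResult]:
        """Phenotype pairs ranked by intersection significance."""
        return sorted(self.results, key=lambda r: (r.hyper_p_adj, r.hyper_p, r.pair.key))

    def by_key(self) -> dict[str, ADRDPResult]:
        return {r.pair.key: r for r in self.results}


def identify_related_proteins(
    kg: KnowledgeGraph,
    phenotype: str,
    origin: str,
    params: PipelineParams | None = None,
    operator: dif.DiffusionOperator | None = None,
    restrict_entities: set[str] | None = None,
) -> pd.DataFrame:
    """Seed -> diffusion -> permutation null -> exponential p -> BH.

    ``origin`` selects the seed construction (``adr``, ``dp`` or
    ``indication``); ``restrict_entities`` limits the qualifying drugs (adr)
    or diseases (dp), used by holdout discovery and the organ rerun.
    Returns the per-protein significance table.
    """
    params = params or PipelineParams()
    op = operator or dif.DiffusionOperator(kg.ppi, weighted=params.weighted)
    if origin == "adr":
        qualifying = kg.drugs_with_adr(phenotype)
        if restrict_entities is not None:
            qualifying = qualifying & restrict_entities
        seed = dif.build_adr_seed(kg, phenotype, drugs=qualifying)
        stream_labels = sorted(qualifying)
    elif origin == "dp":
        qualifying = kg.diseases_with_dp(phenotype)
        if restrict_entities is not None:
            qualifying = qualifying & restrict_entities
        seed = dif.build_dp_seed(kg, phenotype, diseases=qualifying)
        stream_labels = sorted(qualifying)
    elif origin == "indication":
        seed = dif.build_indication_seed(kg, phenotype)
        stream_labels = []
    else:
        raise ValueError(f"unknown origin {origin!r}")
    observed = op.propagate(op.seed_array(seed), alpha=params.alpha, tol=params.tol, max_iter=params.max_iter)[0]
    # the permutation stream keys on the qualifying entity set, so a
    # restriction equal to the full set reproduces the unrestricted run
    rng = _substream(params.rng_seed, origin, phenotype, *stream_labels)
    null = st.permutation_null(
        op, seed, B=params.n_permutations, rng_seed=rng,
        alpha=params.alpha, tol=params.tol, max_iter=params.max_iter,
        keep_null_scores=params.keep_null_scores,
    )
    table = st.make_significance_table(op.nodes, observed, null.null_mean, params.alpha_level)
    table.attrs["origin"] = origin
    table.attrs["phenotype"] = phenotype
    if params.keep_null_scores:
        table.attrs["null_scores"] = null.null_scores
    return table


def intersect_pair(
    kg: KnowledgeGraph,
    pair: PhenotypePair,
    adr_table: pd.DataFrame,
    dp_table: pd.DataFrame,
    alpha_level: float = 0.05,
) -> ADRDPResult:
    """Hypergeometric overlap of the two significant sets over the PPI universe.

    ``hyper_p_adj`` and ``adr_dp_proteins`` are finalized by the caller after
    BH across all pairs in the run; an empty side yields p = 1 by convention.
    """
    universe = kg.proteins
    adr_set = st.significant_set(adr_table, alpha_level)
    dp_set = st.significant_set(dp_table, alpha_level)
    inter = adr_set & dp_set
    p = 1.0 if (not adr_set or not dp_set) else st.hypergeometric_overlap(adr_set, dp_set, universe)
    return ADRDPResult(
        pair=pair, adr_set=adr_set, dp_set=dp_set, intersection=inter,
        hyper_p=p, adr_table=adr_table, dp_table=dp_table,
    )


def finalize_intersections(results: list[ADRDPResult], alpha_level: float = 0.05) -> None:
    """Apply BH across pairs and set the final ADR-DP protein sets in place."""
    if not results:
        return
    order = sorted(results, key=lambda r: r.pair.key)
    p_adj = st.bh_adjust([r.hyper_p for r in order])
    for r, q in zip(order, p_adj):
        r.hyper_p_adj = float(q)
        r.adr_dp_proteins = set(r.intersection) if q < alpha_level else set()


def run_dreamer(kg: KnowledgeGraph, params: PipelineParams | None = None) -> RunResult:
    """Run the full pipeline over every phenotype pair in the KG.

    Per-pair seed or convergence errors are recorded and the run continues.
    """
    params = params or PipelineParams()
    op = dif.DiffusionOperator(kg.ppi, weighted=params.weighted)
    results: list[ADRDPResult] = []
    errors: dict[str, str] = {}
    for pair in sorted(kg.pairs, key=lambda p: p.key):
        try:
            adr_table = identify_related_proteins(kg, pair.adr_id, "adr", params, op)
            dp_table = identify_related_proteins(kg, pair.dp_id, "dp", params, op)
        except (dif.SeedConstructionError, dif.ConvergenceError) as exc:
            errors[pair.key] = str(exc)
            continue
        results.append(intersect_pair(kg, pair, adr_table, dp_table, params.alpha_level))
    finalize_intersections(results, params.alpha_level)
    run = RunResult(results=results, errors=errors, params=params)
    run.n_pairs_tested = len(results)
    run.n_pairs_significant = sum(bool(r.adr_dp_proteins) for r in results)
    return run


# ---------------------------------------------------------------------------
# Confounder controls
# ---------------------------------------------------------------------------

def _organ_set(value) -> set[str]:
    if value is None:
        return set()
    if isinstance(value, str):
        return {value}
    return set(value)


@dataclass
class OrganReport:
    pair_key: str
    dropped: bool  # every drug shared the ADR's organ; phenotype leaves the list
    n_drugs_before: int
    n_drugs_after: int
    rerun_adr_dp: set[str] = field(default_factory=set)
    overlap_p: float = float("nan")  # before/after ADR-DP overlap, hypergeometric
    consistent: bool = False  # overlap_p < 0.05


@dataclass
class IndicationReport:
    pair_key: str
    excluded: bool  # no indication seed could be built
    reason: str = ""
    indication_set: set[str] = field(default_factory=set)
    overlap_p: float = float("nan")
    overlap_p_adj: float = float("nan")
    confounded: bool = False  # adjusted p < 0.05


@dataclass
class ConfounderReport:
    organ: dict[str, OrganReport]
    indication: dict[str, IndicationReport]
    final_keys: list[str]  # significant, organ-surviving, not confounded
    accounting: dict


def organ_confounder_rerun(
    kg: KnowledgeGraph,
    result: ADRDPResult,
    adr_organs: Mapping[str, set[str] | str],
    disease_organs: Mapping[str, set[str] | str],
    params: PipelineParams | None = None,
    operator: dif.DiffusionOperator | None = None,
) -> OrganReport:
    """Remove the ADR's drugs whose indications affect the ADR's organ/tissue,
    re-run the ADR side and the intersection, and test the overlap between
    the before/after ADR-DP protein sets (hypergeometric, PPI universe)."""
    params = params or PipelineParams()
    pair = result.pair
    adr_org = _organ_set(adr_organs.get(pair.adr_id))
    drugs = kg.drugs_with_adr(pair.adr_id)
    surviving = {
        d for d in drugs
        if not any(_organ_set(disease_organs.get(ind)) & adr_org for ind in kg.indications_of(d))
    }
    report = OrganReport(
        pair_key=pair.key, dropped=not surviving,
        n_drugs_before=len(drugs), n_drugs_after=len(surviving),
    )
    if report.dropped:
        return report
    op = operator or dif.DiffusionOperator(kg.ppi, weighted=params.weighted)
    adr_table = identify_related_proteins(kg, pair.adr_id, "adr", params, op, restrict_entities=surviving)
    rerun = intersect_pair(kg, pair, adr_table, result.dp_table, params.alpha_level)
    # single-pair rerun: the intersection stands on its own raw p
    rerun.adr_dp_proteins = set(rerun.intersection) if rerun.hyper_p < params.alpha_level else set()
    report.rerun_adr_dp = rerun.adr_dp_proteins
    if result.adr_dp_proteins and report.rerun_adr_dp:
        report.overlap_p = st.hypergeometric_overlap(result.adr_dp_proteins, report.rerun_adr_dp, kg.proteins)
    else:
        report.overlap_p = 1.0
    report.consistent = report.overlap_p < params.alpha_level
    return report


def indication_confounder_test(
    kg: KnowledgeGraph,
    result: ADRDPResult,
    params: PipelineParams | None = None,
    operator: dif.DiffusionOperator | None = None,
) -> IndicationReport:
    """Overlap of indication-related proteins with the pair's ADR-DP set.

    ``overlap_p_adj`` and the ``confounded`` flag are finalized by the caller
    after BH across phenotypes.
    """
    params = params or PipelineParams()
    pair = result.pair
    try:
        table = identify_related_proteins(kg, pair.adr_id, "indication", params, operator)
    except dif.SeedConstructionError as exc:
        return IndicationReport(pair_key=pair.key, excluded=True, reason=str(exc))
    ind_set = st.significant_set(table, params.alpha_level)
    p = 1.0 if not (ind_set and result.adr_dp_proteins) else st.hypergeometric_overlap(
        ind_set, result.adr_dp_proteins, kg.proteins)
    return IndicationReport(pair_key=pair.key, excluded=False, indication_set=ind_set, overlap_p=p)


def run_confounder_analysis(
    kg: KnowledgeGraph,
    run: RunResult,
    adr_organs: Mapping[str, set[str] | str] | None = None,
    disease_organs: Mapping[str, set[str] | str] | None = None,
    params: PipelineParams | None = None,
) -> ConfounderReport:
    """Both confounder controls over the run's significant pairs.

    The final phenotype list keeps pairs that are significant at the
    intersection step, survive the organ-based drug removal (when organ
    annotations are supplied), and show no significant overlap with
    indication-related proteins (BH across phenotypes).
    """
    params = params or run.params
    op = dif.DiffusionOperator(kg.ppi, weighted=params.weighted)
    significant = [r for r in run.results if r.adr_dp_proteins]
    organ_reports: dict[str, OrganReport] = {}
    if adr_organs is not None:
        for r in significant:
            organ_reports[r.pair.key] = organ_confounder_rerun(
                kg, r, adr_organs, disease_organs or {}, params, op)
    organ_ok = [
        r for r in significant
        if r.pair.key not in organ_reports or not organ_reports[r.pair.key].dropped
    ]
    ind_reports: dict[str, IndicationReport] = {}
    for r in organ_ok:
        ind_reports[r.pair.key] = indication_confounder_test(kg, r, params, op)
    testable = sorted(k for k, rep in ind_reports.items() if not rep.excluded)
    if testable:
        p_adj = st.bh_adjust([ind_reports[k].overlap_p for k in testable])
        for k, q in zip(testable, p_adj):
            ind_reports[k].overlap_p_adj = float(q)
            ind_reports[k].confounded = bool(q < params.alpha_level)
    final = [
        r.pair.key for r in organ_ok
        if r.pair.key in ind_reports
        and not ind_reports[r.pair.key].excluded
        and not ind_reports[r.pair.key].confounded
    ]
    accounting = {
        "significant_pairs": len(significant),
        "organ_dropped": sum(rep.dropped for rep in organ_reports.values()),
        "organ_consistent": sum(rep.consistent for rep in organ_reports.values()),
        "indication_excluded": sum(rep.excluded for rep in ind_reports.values()),
        "indication_confounded": sum(rep.confounded for rep in ind_reports.values()),
        "final": len(final),
    }
    return ConfounderReport(
        organ=organ_reports, indication=ind_reports,
        final_keys=sorted(final), accounting=accounting,
    )


# ---------------------------------------------------------------------------
# Diffusion-map export
# ---------------------------------------------------------------------------

def export_diffusion_map(
    kg: KnowledgeGraph,
    result: ADRDPResult,
    indication_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-protein coordinates for the 2D/3D diffusion map of one pair.

    x = ADR diffusion score, y = DP diffusion score, z (optional) =
    indication diffusion score; the role column distinguishes drug targets
    (of drugs with this ADR), disease proteins (of diseases with this DP),
    both, or neither, and ``is_adr_dp`` flags the pair's final protein set.
    """
    pair = result.pair
    targets: set[str] = set()
    for d in kg.drugs_with_adr(pair.adr_id):
        targets |= kg.targets_of(d)
    disease_prots: set[str] = set()
    for d in kg.diseases_with_dp(pair.dp_id):
        disease_prots |= kg.genes_of(d)
    proteins = list(result.adr_table.index)
    role = [
        "both" if p in targets and p in disease_prots
        else "drug_target" if p in targets
        else "disease_protein" if p in disease_prots
        else "neither"
        for p in proteins
    ]
    out = pd.DataFrame(
        {
            "x": result.adr_table["score"].to_numpy(),
            "y": result.dp_table["score"].to_numpy(),
            "role": role,
            "adr_significant": result.adr_table["significant"].to_numpy(),
            "dp_significant": result.dp_table["significant"].to_numpy(),
            "is_adr_dp": [p in result.adr_dp_proteins for p in proteins],
        },
        index=pd.Index(proteins, name="protein_id"),
    )
    if indication_table is not None:
        out.insert(2, "z", indication_table["score"].reindex(out.index).to_numpy())
    return out


# ---------------------------------------------------------------------------
# Result serialization (deterministic byte-stable TSV/JSON writers)
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return f"{x:.12g}"


def write_run_results(run: RunResult, outdir: str | Path) -> None:
    """Write ranked pairs, final protein sets, per-pair tables and a summary.

    Output is byte-stable: rows are sorted and floats use a fixed format, so
    two runs with the same master seed produce identical files.
    """
    outdir = Path(outdir)
    (outdir / "tables").mkdir(parents=True, exist_ok=True)
    with open(outdir / "pairs_ranked.tsv", "w", encoding="utf-8") as fh:
        fh.write("rank\tadr\tdp\tn_adr\tn_dp\tn_intersection\thyper_p\thyper_p_adj\tsignificant\n")
        for rank, r in enumerate(run.ranked(), start=1):
            fh.write(
                f"{rank}\t{r.pair.adr_id}\t{r.pair.dp_id}\t{len(r.adr_set)}\t{len(r.dp_set)}\t"
                f"{len(r.intersection)}\t{_fmt(r.hyper_p)}\t{_fmt(r.hyper_p_adj)}\t"
                f"{int(bool(r.adr_dp_proteins))}\n"
            )
    with open(outdir / "adr_dp_proteins.tsv", "w", encoding="utf-8") as fh:
        fh.write("adr\tdp\tprotein_id\n")
        for r in sorted(run.results, key=lambda r: r.pair.key):
            for p in sorted(r.adr_dp_proteins):
                fh.write(f"{r.pair.adr_id}\t{r.pair.dp_id}\t{p}\n")
    for r in sorted(run.results, key=lambda r: r.pair.key):
        for side, table in (("adr", r.adr_table), ("dp", r.dp_table)):
            if table is None:
                continue
            path = outdir / "tables" / f"{r.pair.key}.{side}.tsv"
            with open(path, "w", encoding="utf-8") as fh:
                fh.write("protein_id\tscore\tp_raw\tp_adj\tsignificant\n")
                for prot in sorted(table.index):
                    row = table.loc[prot]
                    fh.write(
                        f"{prot}\t{_fmt(row['score'])}\t{_fmt(row['p_raw'])}\t"
                        f"{_fmt(row['p_adj'])}\t{int(row['significant'])}\n"
                    )
    summary = {
        "n_pairs_tested": run.n_pairs_tested,
        "n_pairs_significant": run.n_pairs_significant,
        "alpha": run.params.alpha,
        "n_permutations": run.params.n_permutations,
        "alpha_level": run.params.alpha_level,
        "rng_seed": run.params.rng_seed,
        "errors": dict(sorted(run.errors.items())),
    }
    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
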