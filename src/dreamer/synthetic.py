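"""Synthetic knowledge graphs with planted ground-truth mechanism modules.

The generator emulates the structure the analysis assumes in real data:
a sparse background PPI with dense planted modules, and phenotype pairs
whose drugs' targets and diseases' genes fall inside the pair's module with
a configurable probability. "Planted" pairs share a mechanism module;
"null" pairs get uniformly random targets/genes and carry no signal.
Optional extras: indication diseases placed inside ("near") or away from
("far") the module, organ annotations that make a fraction of each ADR's
drugs share the ADR's organ, a low-confidence decoy edge layer exercising
the PPI score filter, and background phenotypes with heavy-tailed degrees
exercising the common-ADR/common-DP filters.

It emulates module-level signal and degree heterogeneity only -- not the
full degree distribution, clustering, or annotation biases of a real
STRING-scale network -- so recovery results on it bound what the method can
do under its own assumptions, not performance on real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .kg import (
    KGConfig,
    KnowledgeGraph,
    LinkTable,
    assemble_kg,
)


@dataclass
class GeneratorParams:
    """Study-condition knobs for the synthetic KG.

    The defaults are the strong-signal profile: 500 proteins, five disjoint
    10-protein modules wired at 0.6 intra-module edge probability over a
    0.01-density background, drug targets/disease genes landing in-module
    with probability 0.9, and five planted plus five null phenotype pairs.
    """

    n_proteins: int = 500
    n_modules: int = 5
    module_size: int = 10
    intra_module_edge_prob: float = 0.6
    background_edge_prob: float = 0.01
    n_pairs_planted: int = 5
    n_pairs_null: int = 5
    drugs_per_adr: int = 14  # matches the reported average drugs per ADR
    diseases_per_dp: int = 10
    targets_per_drug: int = 3
    genes_per_disease: int = 3
    on_module_target_prob: float = 0.9
    # indications: probability a drug carries one indication disease, and
    # whether that disease's genes sit inside the pair's module or far away
    indication_rate: float = 0.0
    indication_placement: str = "far"  # near | far
    genes_per_indication: int = 3
    # organ annotations: fraction of a planted ADR's drugs whose indication
    # shares the ADR's organ (the organ-confounder rerun removes these)
    organ_overlap_frac: float = 0.0
    n_organs: int = 5
    # background entities with heavy-tailed degrees (truncated power law)
    n_extra_adrs: int = 0
    n_extra_dps: int = 0
    extra_degree_max: int = 60
    # decoy PPI edges at or below the confidence threshold
    n_low_confidence_edges: int = 200
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_modules * self.module_size > self.n_proteins:
            raise ValueError("modules do not fit into the protein set")
        if self.n_pairs_planted > self.n_modules:
            raise ValueError("need one module per planted pair")
        for p in (self.intra_module_edge_prob, self.background_edge_prob,
                  self.on_module_target_prob, self.indication_rate,
                  self.organ_overlap_frac):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.indication_placement not in ("near", "far"):
            raise ValueError("indication_placement must be 'near' or 'far'")


@dataclass
class GroundTruth:
    """Pair key -> planted module protein set (empty for null pairs)."""

    modules: dict[str, set[str]] = field(default_factory=dict)

    def planted_keys(self) -> list[str]:
        return sorted(k for k, v in self.modules.items() if v)

    def null_keys(self) -> list[str]:
        return sorted(k for k, v in self.modules.items() if not v)


@dataclass
class RawTables:
    """Pre-assembly link tables plus side annotations, as a generator output."""

    tables: dict[str, LinkTable]
    ppi_edges: list[tuple[str, str, float]]
    truth: GroundTruth
    adr_organs: dict[str, set[str]]
    disease_organs: dict[str, set[str]]
    equivalence: dict[str, set[str]]  # ADR -> terminologically equivalent diseases
    params: GeneratorParams


def _power_law_degrees(rng: np.random.Generator, n: int, d_min: int, d_max: int,
                       gamma: float = 2.1) -> list[int]:
    """Degrees from a truncated discrete power law P(d) ~ d^-gamma."""
    support = np.arange(d_min, d_max + 1)
    weights = support.astype(float) ** -gamma
    weights /= weights.sum()
    return [int(d) for d in rng.choice(support, size=n, p=weights)]


def generate_tables(params: GeneratorParams | None = None) -> RawTables:
    """Build raw link tables and a scored PPI with planted modules."""
    params = params or GeneratorParams()
    params.validate()
    rng = np.random.default_rng(params.rng_seed)

    proteins = [f"P{i:04d}" for i in range(params.n_proteins)]
    modules = [
        proteins[m * params.module_size:(m + 1) * params.module_size]
        for m in range(params.n_modules)
    ]
    module_proteins = {p for mod in modules for p in mod}
    far_pool = [p for p in proteins if p not in module_proteins]

    # --- PPI: dense modules over a sparse Erdos-Renyi background ----------
    edges: dict[tuple[str, str], float] = {}

    def _add(a: str, b: str, score: float) -> None:
        if a == b:
            return
        key = (a, b) if a < b else (b, a)
        edges.setdefault(key, score)

    n = params.n_proteins
    upper = np.triu_indices(n, k=1)
    mask = rng.random(len(upper[0])) < params.background_edge_prob
    for i, j in zip(upper[0][mask], upper[1][mask]):
        _add(proteins[i], proteins[j], float(rng.integers(801, 1001)))
    for mod in modules:
        for i in range(len(mod)):
            for j in range(i + 1, len(mod)):
                if rng.random() < params.intra_module_edge_prob:
                    _add(mod[i], mod[j], float(rng.integers(801, 1001)))
    ppi_edges = [(a, b, s) for (a, b), s in sorted(edges.items())]
    # decoy low-confidence edges; the score filter must remove all of them
    for _ in range(params.n_low_confidence_edges):
        i, j = rng.integers(n), rng.integers(n)
        if i != j:
            a, b = sorted((proteins[i], proteins[j]))
            if (a, b) not in edges:
                ppi_edges.append((a, b, float(rng.integers(1, 801))))

    # --- phenotype pairs ---------------------------------------------------
    drug_target: set[tuple[str, str]] = set()
    disease_gene: set[tuple[str, str]] = set()
    drug_adr: set[tuple[str, str]] = set()
    disease_dp: set[tuple[str, str]] = set()
    drug_indication: set[tuple[str, str]] = set()
    adr_dp: set[tuple[str, str]] = set()
    truth = GroundTruth()
    adr_organs: dict[str, set[str]] = {}
    disease_organs: dict[str, set[str]] = {}
    organs = [f"organ{k}" for k in range(params.n_organs)]

    def _pick_targets(module: list[str] | None, k: int) -> set[str]:
        chosen: set[str] = set()
        while len(chosen) < k:
            if module is not None and rng.random() < params.on_module_target_prob:
                chosen.add(module[rng.integers(len(module))])
            else:
                chosen.add(proteins[rng.integers(n)])
        return chosen

    n_pairs = params.n_pairs_planted + params.n_pairs_null
    drug_counter = 0
    disease_counter = 0
    for pair_idx in range(n_pairs):
        planted = pair_idx < params.n_pairs_planted
        module = modules[pair_idx] if planted else None
        adr = f"ADR{pair_idx:03d}"
        dp = f"DP{pair_idx:03d}"
        adr_dp.add((adr, dp))
        pair_key = f"{adr}--{dp}"
        truth.modules[pair_key] = set(module) if planted else set()
        adr_organ = organs[pair_idx % params.n_organs]
        adr_organs[adr] = {adr_organ}

        pair_drugs = []
        for _ in range(params.drugs_per_adr):
            drug = f"D{drug_counter:04d}"
            drug_counter += 1
            pair_drugs.append(drug)
            drug_adr.add((drug, adr))
            for t in _pick_targets(module, params.targets_per_drug):
                drug_target.add((drug, t))
        for _ in range(params.diseases_per_dp):
            disease = f"X{disease_counter:04d}"
            disease_counter += 1
            disease_dp.add((disease, dp))
            for g in _pick_targets(module, params.genes_per_disease):
                disease_gene.add((disease, g))

        # indication diseases: genes in-module ("near") or off-module ("far")
        if params.indication_rate > 0:
            n_overlap = int(round(params.organ_overlap_frac * len(pair_drugs)))
            for d_idx, drug in enumerate(pair_drugs):
                if rng.random() >= params.indication_rate:
                    continue
                ind = f"IND{drug}"
                drug_indication.add((drug, ind))
                if params.indication_placement == "near" and module is not None:
                    genes = {module[int(g)] for g in
                             rng.choice(len(module), size=min(params.genes_per_indication, len(module)), replace=False)}
                else:
                    genes = {far_pool[int(g)] for g in
                             rng.choice(len(far_pool), size=params.genes_per_indication, replace=False)}
                for g in genes:
                    disease_gene.add((ind, g))
                if d_idx < n_overlap:
                    disease_organs[ind] = {adr_organ}  # triggers organ-based removal
                else:
                    disease_organs[ind] = {organs[(pair_idx + 1 + d_idx) % params.n_organs] }

    # --- heavy-tailed background phenotypes -------------------------------
    all_drugs = sorted({d for d, _ in drug_target})
    all_diseases = sorted({d for d, _ in disease_gene})
    for k, deg in enumerate(_power_law_degrees(rng, params.n_extra_adrs, 1, params.extra_degree_max)):
        adr = f"XADR{k:03d}"
        take = min(deg, len(all_drugs))
        for i in rng.choice(len(all_drugs), size=take, replace=False):
            drug_adr.add((all_drugs[int(i)], adr))
    for k, deg in enumerate(_power_law_degrees(rng, params.n_extra_dps, 1, params.extra_degree_max)):
        dp = f"XDP{k:03d}"
        take = min(deg, len(all_diseases))
        for i in rng.choice(len(all_diseases), size=take, replace=False):
            disease_dp.add((all_diseases[int(i)], dp))

    tables = {
        "drug_target": LinkTable("drug_target", frozenset(drug_target)),
        "disease_gene": LinkTable("disease_gene", frozenset(disease_gene)),
        "drug_adr": LinkTable("drug_adr", frozenset(drug_adr)),
        "disease_dp": LinkTable("disease_dp", frozenset(disease_dp)),
        "drug_indication": LinkTable("drug_indication", frozenset(drug_indication)),
        "adr_dp": LinkTable("adr_dp", frozenset(adr_dp)),
    }
    return RawTables(
        tables=tables, ppi_edges=ppi_edges, truth=truth,
        adr_organs=adr_organs, disease_organs=disease_organs,
        equivalence={}, params=params,
    )


def generate_kg(
    params: GeneratorParams | None = None,
    config: KGConfig | None = None,
) -> tuple[KnowledgeGraph, GroundTruth, RawTables]:
    """Generate raw tables and assemble them into an analysis-ready KG.

    The assembly seed follows the generator seed so the whole artifact is a
    function of one integer. Ground-truth modules are intersected with the
    assembled PPI so recovery metrics never charge the method for proteins
    the preprocessing legitimately removed (e.g., module members that landed
    outside the largest connected component).
    """
    params = params or GeneratorParams()
    raw = generate_tables(params)
    config = config or KGConfig(rng_seed=params.rng_seed)
    kg = assemble_kg(raw.tables, raw.ppi_edges, config, raw.equivalence)
    surviving = {p.key for p in kg.pairs}
    truth = GroundTruth(modules={
        k: (v & kg.proteins) for k, v in raw.truth.modules.items() if k in surviving
    })
    return kg, truth, raw


def write_tables(raw: RawTables, outdir: str | Path) -> None:
    """Emit the raw tables in the TSV dialect the parsers read, plus truth."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for kind, table in raw.tables.items():
        with open(outdir / f"{kind}.tsv", "w", encoding="utf-8") as fh:
            fh.write(f"# {kind}\n")
            for s, t in sorted(table.links):
                fh.write(f"{s}\t{t}\n")
    with open(outdir / "ppi.tsv", "w", encoding="utf-8") as fh:
        fh.write("# protein\tprotein\tscore\n")
        for a, b, s in sorted(raw.ppi_edges):
            fh.write(f"{a}\t{b}\t{s:g}\n")
    ann = {
        "adr_organs": {k: sorted(v) for k, v in sorted(raw.adr_organs.items())},
        "disease_organs": {k: sorted(v) for k, v in sorted(raw.disease_organs.items())},
        "truth": {k: sorted(v) for k, v in sorted(raw.truth.modules.items())},
    }
    with open(outdir / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(ann, fh, indent=2, sort_keys=True)
        fh.write("\n")


def evaluate_recovery(
    results: list,
    truth: GroundTruth,
) -> "pd.DataFrame":
    """Set precision/recall/F1 of recovered ADR-DP proteins against truth.

    Planted pairs are scored on their module; null pairs count as a correct
    rejection when their recovered set is empty. Accepts the ADRDPResult
    list from a pipeline run.
    """
    import pandas as pd

    rows = []
    by_key = {r.pair.key: r for r in results}
    for key in sorted(truth.modules):
        module = truth.modules[key]
        found = by_key[key].adr_dp_proteins if key in by_key else set()
        if module:
            tp = len(found & module)
            precision = tp / len(found) if found else 0.0
            recall = tp / len(module)
            f1 = (2 * precision * recall / (precision + recall)) if (precision + recall) else 0.0
            rows.append({"pair": key, "planted": True, "precision": precision,
                         "recall": recall, "f1": f1, "correct_rejection": np.nan})
        else:
            rows.append({"pair": key, "planted": False, "precision": np.nan,
                         "recall": np.nan, "f1": np.nan,
                         "correct_rejection": float(not found)})
    return pd.DataFrame(rows).set_index("pair")
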