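"""Heterogeneous knowledge-graph model, parsing, and preprocessing filters.

The knowledge graph (KG) connects five node types -- drugs, diseases,
proteins, adverse drug reactions (ADRs) and disease phenotypes (DPs) --
through six bipartite link tables, plus a weighted protein-protein
interaction (PPI) network on a 0-1000 confidence scale (STRING-style).
``assemble_kg`` applies the preprocessing rules that turn raw link tables
into an analysis-ready graph: confidence thresholding of the PPI,
restriction of protein links to PPI-resident proteins, removal of drugs
without targets and diseases without genes, removal of drug-ADR links whose
drug is indicated for a disease equivalent to the ADR, degree filters on
very common ADRs/DPs, and random one-ADR-per-DP pair selection.
"""

from __future__ import annotations

import json
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

#: link-table kind -> (source namespace, target namespace)
LINK_KINDS: dict[str, tuple[str, str]] = {
    "drug_target": ("drug", "protein"),
    "disease_gene": ("disease", "protein"),
    "drug_adr": ("drug", "adr"),
    "disease_dp": ("disease", "dp"),
    "drug_indication": ("drug", "disease"),
    "adr_dp": ("adr", "dp"),
}


class KGError(Exception):
    """Base error for knowledge-graph construction problems."""


class ParseError(KGError):
    """Malformed input row; message carries the 1-based line number."""


class ValidationError(KGError):
    """Input violates a documented invariant (e.g., negative PPI score)."""


class AssemblyError(KGError):
    """Assembly produced an unusable graph (e.g., zero surviving pairs)."""


@dataclass(frozen=True)
class LinkTable:
    """A deduplicated set of directed (source, target) links of one kind."""

    kind: str
    links: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.kind not in LINK_KINDS:
            raise ValidationError(f"unknown link kind {self.kind!r}")

    def __len__(self) -> int:
        return len(self.links)

    def sources(self) -> set[str]:
        return {s for s, _ in self.links}

    def targets(self) -> set[str]:
        return {t for _, t in self.links}

    def by_source(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = defaultdict(set)
        for s, t in self.links:
            out[s].add(t)
        return dict(out)

    def by_target(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = defaultdict(set)
        for s, t in self.links:
            out[t].add(s)
        return dict(out)

    def restrict_targets(self, keep: set[str]) -> "LinkTable":
        return LinkTable(self.kind, frozenset((s, t) for s, t in self.links if t in keep))

    def restrict_sources(self, keep: set[str]) -> "LinkTable":
        return LinkTable(self.kind, frozenset((s, t) for s, t in self.links if s in keep))


@dataclass(frozen=True)
class PhenotypePair:
    """An ADR and a DP mapped to the same clinical phenotype."""

    adr_id: str
    dp_id: str
    label: str = ""

    @property
    def key(self) -> str:
        return f"{self.adr_id}--{self.dp_id}"


@dataclass
class KGConfig:
    """Preprocessing thresholds; defaults follow the published filtering rules."""

    min_ppi_score: float = 800.0  # edges kept strictly above this confidence
    strict_ppi_threshold: bool = True  # False keeps score == min_ppi_score too
    max_adr_drugs: int = 50  # ADRs with more distinct drugs are dropped
    max_dp_diseases: int = 100  # DPs with more distinct diseases are dropped
    restrict_to_lcc: bool = True  # keep only the PPI's largest connected component
    rng_seed: int = 0  # drives the one-ADR-per-DP random selection


@dataclass
class KnowledgeGraph:
    """Analysis-ready knowledge graph.

    ``tables`` hold the filtered links; ``raw_drug_targets`` preserves each
    drug's pre-filter target set so that target-coverage denominators can
    optionally count targets outside the filtered PPI.
    """

    drugs: set[str]
    diseases: set[str]
    adrs: set[str]
    dps: set[str]
    tables: dict[str, LinkTable]
    ppi: nx.Graph
    pairs: list[PhenotypePair]
    provenance: dict = field(default_factory=dict)
    config: KGConfig = field(default_factory=KGConfig)
    raw_drug_targets: dict[str, set[str]] = field(default_factory=dict)

    # -- convenience accessors -------------------------------------------
    @property
    def proteins(self) -> set[str]:
        return set(self.ppi.nodes)

    def drugs_with_adr(self, adr: str) -> set[str]:
        return self.tables["drug_adr"].by_target().get(adr, set())

    def diseases_with_dp(self, dp: str) -> set[str]:
        return self.tables["disease_dp"].by_target().get(dp, set())

    def targets_of(self, drug: str) -> set[str]:
        return self.tables["drug_target"].by_source().get(drug, set())

    def genes_of(self, disease: str) -> set[str]:
        return self.tables["disease_gene"].by_source().get(disease, set())

    def indications_of(self, drug: str) -> set[str]:
        return self.tables["drug_indication"].by_source().get(drug, set())

    def validate(self) -> None:
        """Raise ValidationError if any structural invariant is violated."""
        ns_nodes = {
            "drug": self.drugs,
            "disease": self.diseases,
            "protein": self.proteins,
            "adr": self.adrs,
            "dp": self.dps,
        }
        for kind, table in self.tables.items():
            src_ns, tgt_ns = LINK_KINDS[kind]
            for s, t in table.links:
                if s not in ns_nodes[src_ns]:
                    raise ValidationError(f"{kind}: source {s!r} missing from {src_ns} nodes")
                if t not in ns_nodes[tgt_ns]:
                    raise ValidationError(f"{kind}: target {t!r} missing from {tgt_ns} nodes")
        adr_deg = self.tables["drug_adr"].by_target()
        if any(len(v) > self.config.max_adr_drugs for v in adr_deg.values()):
            raise ValidationError("ADR drug-degree filter violated")
        dp_deg = self.tables["disease_dp"].by_target()
        if any(len(v) > self.config.max_dp_diseases for v in dp_deg.values()):
            raise ValidationError("DP disease-degree filter violated")


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def _iter_rows(path: Path) -> Iterable[tuple[int, list[str]]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_link_table(path: str | Path, kind: str) -> LinkTable:
    """Read a two-column tab-separated edge list into a deduplicated table.

    Lines starting with ``#`` are comments; an empty file yields an empty
    table. A row with the wrong column count raises :class:`ParseError`
    naming the line number.
    """
    path = Path(path)
    links: set[tuple[str, str]] = set()
    for lineno, fields in _iter_rows(path):
        if len(fields) != 2:
            raise ParseError(f"{path}: line {lineno}: expected 2 columns, got {len(fields)}")
        links.add((fields[0], fields[1]))
    return LinkTable(kind, frozenset(links))


def read_ppi_table(path: str | Path) -> list[tuple[str, str, float]]:
    """Read a three-column (protein, protein, confidence score) edge list."""
    path = Path(path)
    edges: list[tuple[str, str, float]] = []
    for lineno, fields in _iter_rows(path):
        if len(fields) != 3:
            raise ParseError(f"{path}: line {lineno}: expected 3 columns, got {len(fields)}")
        try:
            score = float(fields[2])
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: bad score {fields[2]!r}") from exc
        edges.append((fields[0], fields[1], score))
    return edges


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_ppi_by_score(
    ppi_raw: Sequence[tuple[str, str, float]],
    min_score: float = 800.0,
    strict: bool = True,
) -> nx.Graph:
    """Threshold a scored edge list into an unweighted simple graph.

    Edges with confidence strictly above ``min_score`` (or ``>=`` when
    ``strict`` is False) are kept; self-loops are dropped with a warning and
    proteins left without any edge disappear from the node set.
    """
    g = nx.Graph()
    for a, b, score in ppi_raw:
        if score < 0:
            raise ValidationError(f"negative PPI score {score} on edge ({a}, {b})")
        if score > 1000:
            raise ValidationError(f"PPI score {score} above the 0-1000 scale on ({a}, {b})")
        if a == b:
            logger.warning("dropping PPI self-loop on %s", a)
            continue
        if (score > min_score) if strict else (score >= min_score):
            g.add_edge(a, b, score=score)
    return g


def _filter_common(table: LinkTable, max_sources: int) -> LinkTable:
    deg = table.by_target()
    drop = {t for t, srcs in deg.items() if len(srcs) > max_sources}
    return LinkTable(table.kind, frozenset((s, t) for s, t in table.links if t not in drop))


def filter_common_adrs(drug_adr: LinkTable, max_drugs: int = 50) -> LinkTable:
    """Drop ADRs linked to strictly more than ``max_drugs`` distinct drugs."""
    return _filter_common(drug_adr, max_drugs)


def filter_common_dps(disease_dp: LinkTable, max_diseases: int = 100) -> LinkTable:
    """Drop DPs linked to strictly more than ``max_diseases`` distinct diseases."""
    return _filter_common(disease_dp, max_diseases)


def remove_indication_equivalent_links(
    drug_adr: LinkTable,
    drug_indication: LinkTable,
    adr_disease_equivalence: Mapping[str, set[str]],
) -> LinkTable:
    """Remove drug-ADR links where the drug is indicated for a disease
    terminologically equivalent to the ADR (e.g., a hypertension drug with
    hypertension listed among its ADRs)."""
    indications = drug_indication.by_source()
    kept = set()
    for drug, adr in drug_adr.links:
        equivalent = adr_disease_equivalence.get(adr, set())
        if equivalent and indications.get(drug, set()) & set(equivalent):
            continue
        kept.add((drug, adr))
    return LinkTable("drug_adr", frozenset(kept))


def select_unique_adr_per_dp(adr_dp: LinkTable, rng_seed: int) -> list[PhenotypePair]:
    """Pick one ADR uniformly at random for every DP with several candidates.

    Deterministic given ``rng_seed``; DPs are processed in sorted order so the
    result does not depend on set iteration order.
    """
    rng = np.random.default_rng(rng_seed)
    by_dp = defaultdict(list)
    for adr, dp in adr_dp.links:
        by_dp[dp].append(adr)
    pairs = []
    for dp in sorted(by_dp):
        candidates = sorted(by_dp[dp])
        adr = candidates[0] if len(candidates) == 1 else candidates[rng.integers(len(candidates))]
        pairs.append(PhenotypePair(adr_id=adr, dp_id=dp, label=dp))
    return pairs


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def assemble_kg(
    tables: Mapping[str, LinkTable],
    ppi_raw: Sequence[tuple[str, str, float]],
    config: KGConfig | None = None,
    adr_disease_equivalence: Mapping[str, set[str]] | None = None,
) -> KnowledgeGraph:
    """Apply the full preprocessing cascade and return an analysis-ready KG.

    Filter order (recorded in ``provenance``): PPI confidence threshold (and
    optional largest-connected-component restriction) -> restriction of
    drug-target / disease-gene links to PPI proteins -> removal of drugs
    without targets and diseases without genes -> indication-equivalent
    drug-ADR link removal -> common-ADR / common-DP degree filters ->
    one-ADR-per-DP pair selection -> retention of diffusible pairs.
    """
    config = config or KGConfig()
    equivalence = adr_disease_equivalence or {}
    prov: dict = {"config": {
        "min_ppi_score": config.min_ppi_score,
        "strict_ppi_threshold": config.strict_ppi_threshold,
        "max_adr_drugs": config.max_adr_drugs,
        "max_dp_diseases": config.max_dp_diseases,
        "restrict_to_lcc": config.restrict_to_lcc,
        "rng_seed": config.rng_seed,
    }}

    t = {k: tables.get(k, LinkTable(k, frozenset())) for k in LINK_KINDS}
    input_counts = {k: len(v) for k, v in t.items()}

    # 1. PPI threshold and LCC restriction
    ppi = filter_ppi_by_score(ppi_raw, config.min_ppi_score, config.strict_ppi_threshold)
    prov["ppi_edges_input"] = len(ppi_raw)
    prov["ppi_edges_kept"] = ppi.number_of_edges()
    if config.restrict_to_lcc and ppi.number_of_nodes():
        lcc = max(nx.connected_components(ppi), key=len)
        prov["ppi_nodes_outside_lcc"] = ppi.number_of_nodes() - len(lcc)
        ppi = ppi.subgraph(lcc).copy()
    prov["ppi_nodes"] = ppi.number_of_nodes()
    ppi_nodes = set(ppi.nodes)

    raw_drug_targets = t["drug_target"].by_source()

    # 2. restrict protein links to PPI-resident proteins
    for kind in ("drug_target", "disease_gene"):
        before = len(t[kind])
        t[kind] = t[kind].restrict_targets(ppi_nodes)
        prov[f"{kind}_links_dropped_non_ppi"] = before - len(t[kind])

    # 3. drop drugs with no surviving targets, diseases with no surviving genes
    drugs_with_targets = t["drug_target"].sources()
    diseases_with_genes = t["disease_gene"].sources()
    for kind in ("drug_adr", "drug_indication"):
        before = len(t[kind])
        t[kind] = t[kind].restrict_sources(drugs_with_targets)
        prov[f"{kind}_links_dropped_targetless_drug"] = before - len(t[kind])
    before = len(t["disease_dp"])
    t["disease_dp"] = t["disease_dp"].restrict_sources(diseases_with_genes)
    prov["disease_dp_links_dropped_geneless_disease"] = before - len(t["disease_dp"])

    # 4. indication-equivalent drug-ADR link removal
    before = len(t["drug_adr"])
    t["drug_adr"] = remove_indication_equivalent_links(t["drug_adr"], t["drug_indication"], equivalence)
    prov["drug_adr_links_dropped_indication_equivalent"] = before - len(t["drug_adr"])

    # 5. degree filters on common phenotypes
    before = len(t["drug_adr"])
    t["drug_adr"] = filter_common_adrs(t["drug_adr"], config.max_adr_drugs)
    prov["drug_adr_links_dropped_common_adr"] = before - len(t["drug_adr"])
    before = len(t["disease_dp"])
    t["disease_dp"] = filter_common_dps(t["disease_dp"], config.max_dp_diseases)
    prov["disease_dp_links_dropped_common_dp"] = before - len(t["disease_dp"])

    # 6. pair selection among ADR-DP links whose endpoints survived
    surviving_adrs = t["drug_adr"].targets()
    surviving_dps = t["disease_dp"].targets()
    before = len(t["adr_dp"])
    t["adr_dp"] = LinkTable("adr_dp", frozenset(
        (a, d) for a, d in t["adr_dp"].links if a in surviving_adrs and d in surviving_dps
    ))
    prov["adr_dp_links_dropped_endpoint"] = before - len(t["adr_dp"])
    pairs = select_unique_adr_per_dp(t["adr_dp"], config.rng_seed)

    # 7. retain diffusible pairs: ADR with >=1 drug with >=1 target,
    #    DP with >=1 disease with >=1 gene (guaranteed by steps 3/6 but
    #    re-checked so the invariant is explicit)
    adr_drugs = t["drug_adr"].by_target()
    dp_diseases = t["disease_dp"].by_target()
    targets_by_drug = t["drug_target"].by_source()
    genes_by_disease = t["disease_gene"].by_source()
    diffusible = [
        p for p in pairs
        if any(targets_by_drug.get(d) for d in adr_drugs.get(p.adr_id, ()))
        and any(genes_by_disease.get(d) for d in dp_diseases.get(p.dp_id, ()))
    ]
    prov["pairs_candidate"] = len(pairs)
    prov["pairs_retained"] = len(diffusible)
    if not diffusible:
        raise AssemblyError("no phenotype pair survived assembly")

    # keep only adr_dp links matching the selected pairs
    after_endpoint = len(t["adr_dp"])
    t["adr_dp"] = LinkTable("adr_dp", frozenset((p.adr_id, p.dp_id) for p in diffusible))
    prov["adr_dp_links_dropped_unselected"] = after_endpoint - len(t["adr_dp"])

    for k in LINK_KINDS:
        prov[f"{k}_links_input"] = input_counts[k]
        prov[f"{k}_links_output"] = len(t[k])

    kg = KnowledgeGraph(
        drugs=t["drug_target"].sources() | t["drug_adr"].sources() | t["drug_indication"].sources(),
        diseases=t["disease_gene"].sources() | t["disease_dp"].sources() | t["drug_indication"].targets(),
        adrs=t["drug_adr"].targets() | t["adr_dp"].sources(),
        dps=t["disease_dp"].targets() | t["adr_dp"].targets(),
        tables=t,
        ppi=ppi,
        pairs=diffusible,
        provenance=prov,
        config=config,
        raw_drug_targets=raw_drug_targets,
    )
    kg.validate()
    return kg


# ---------------------------------------------------------------------------
# Bundle I/O
# ---------------------------------------------------------------------------

def save_kg(kg: KnowledgeGraph, outdir: str | Path) -> None:
    """Write the filtered KG as a directory of TSVs plus a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for kind, table in kg.tables.items():
        with open(outdir / f"{kind}.tsv", "w", encoding="utf-8") as fh:
            fh.write(f"# {kind}: {LINK_KINDS[kind][0]}\t{LINK_KINDS[kind][1]}\n")
            for s, tgt in sorted(table.links):
                fh.write(f"{s}\t{tgt}\n")
    with open(outdir / "ppi.tsv", "w", encoding="utf-8") as fh:
        fh.write("# protein\tprotein\tscore\n")
        for a, b, data in sorted(kg.ppi.edges(data=True), key=lambda e: (min(e[0], e[1]), max(e[0], e[1]))):
            lo, hi = sorted((a, b))
            fh.write(f"{lo}\t{hi}\t{data.get('score', 1000):g}\n")
    with open(outdir / "pairs.tsv", "w", encoding="utf-8") as fh:
        fh.write("# adr\tdp\tlabel\n")
        for p in sorted(kg.pairs, key=lambda p: p.key):
            fh.write(f"{p.adr_id}\t{p.dp_id}\t{p.label}\n")
    with open(outdir / "raw_drug_targets.tsv", "w", encoding="utf-8") as fh:
        fh.write("# drug\tprotein (pre-filter targets)\n")
        for drug in sorted(kg.raw_drug_targets):
            for prot in sorted(kg.raw_drug_targets[drug]):
                fh.write(f"{drug}\t{prot}\n")
    manifest = {
        "nodes": {
            "drugs": len(kg.drugs), "diseases": len(kg.diseases),
            "proteins": kg.ppi.number_of_nodes(), "adrs": len(kg.adrs), "dps": len(kg.dps),
        },
        "ppi_edges": kg.ppi.number_of_edges(),
        "pairs": len(kg.pairs),
        "provenance": kg.provenance,
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_kg(indir: str | Path) -> KnowledgeGraph:
    """Load a KG bundle written by :func:`save_kg` without re-filtering."""
    indir = Path(indir)
    tables = {kind: read_link_table(indir / f"{kind}.tsv", kind) for kind in LINK_KINDS}
    ppi_edges = read_ppi_table(indir / "ppi.tsv")
    ppi = nx.Graph()
    for a, b, score in ppi_edges:
        ppi.add_edge(a, b, score=score)
    pairs = []
    for _, fields in _iter_rows(indir / "pairs.tsv"):
        adr, dp = fields[0], fields[1]
        label = fields[2] if len(fields) > 2 else dp
        pairs.append(PhenotypePair(adr, dp, label))
    manifest = json.loads((indir / "manifest.json").read_text())
    cfg_dict = manifest.get("provenance", {}).get("config", {})
    config = KGConfig(**cfg_dict) if cfg_dict else KGConfig()
    raw_targets_path = indir / "raw_drug_targets.tsv"
    raw_drug_targets: dict[str, set[str]] = defaultdict(set)
    if raw_targets_path.exists():
        for _, fields in _iter_rows(raw_targets_path):
            raw_drug_targets[fields[0]].add(fields[1])
    kg = KnowledgeGraph(
        drugs=tables["drug_target"].sources() | tables["drug_adr"].sources() | tables["drug_indication"].sources(),
        diseases=tables["disease_gene"].sources() | tables["disease_dp"].sources() | tables["drug_indication"].targets(),
        adrs=tables["drug_adr"].targets() | tables["adr_dp"].sources(),
        dps=tables["disease_dp"].targets() | tables["adr_dp"].targets(),
        tables=tables,
        ppi=ppi,
        pairs=pairs,
        provenance=manifest.get("provenance", {}),
        config=config,
        raw_drug_targets=dict(raw_drug_targets),
    )
    kg.validate()
    return kg
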