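"""Drug-repurposing ranking by coverage of the ADR-DP protein set.

"Indicated drugs" are drugs whose indication matches the phenotype's
terminology (via a user-supplied ADR/DP <-> disease crosswalk) and that
target at least one ADR-DP protein. All other drugs targeting the set are
scored by the fraction of their targets inside it; drugs that themselves
show the ADR, or that already carry a matching indication, are excluded
from candidacy. The ranking is pure set arithmetic on the link tables --
PPI topology plays no role at this stage, and the tool deliberately makes
no claim about whether a candidate would treat or induce the phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import logging

from .kg import KnowledgeGraph
from .pipeline import ADRDPResult

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RepurposingRow:
    drug: str
    targets_in_set: int
    targets_total: int
    score: float  # targets_in_set / targets_total
    category: str  # indicated | candidate | excluded
    overlaps_indicated_targets: bool


def find_indicated_drugs(
    kg: KnowledgeGraph,
    result: ADRDPResult,
    terminology_map: Mapping[str, set[str]],
) -> set[str]:
    """Drugs indicated for a disease equivalent to the phenotype that target
    at least one ADR-DP protein.

    ``terminology_map`` maps ADR or DP identifiers to the equivalent disease
    (indication) identifiers -- the cross-vocabulary bridge that, e.g., ties
    a MedDRA-coded ADR and an HPO-coded DP to the same Mondo disease entry.
    Returns the empty set (with a logged reason) when the phenotype has no
    mapping.
    """
    pair = result.pair
    equivalent: set[str] = set()
    equivalent |= set(terminology_map.get(pair.adr_id, ()))
    equivalent |= set(terminology_map.get(pair.dp_id, ()))
    if not equivalent:
        logger.info("no terminology mapping for pair %s; no indicated drugs", pair.key)
        return set()
    indications = kg.tables["drug_indication"].by_source()
    out = set()
    for drug in sorted(kg.drugs):
        if not indications.get(drug, set()) & equivalent:
            continue
        if kg.targets_of(drug) & result.adr_dp_proteins:
            out.add(drug)
    return out


def rank_candidates(
    kg: KnowledgeGraph,
    result: ADRDPResult,
    terminology_map: Mapping[str, set[str]] | None = None,
    indicated: set[str] | None = None,
    denominator_in_ppi_only: bool = False,
) -> list[RepurposingRow]:
    """Score every drug with >=1 target in the ADR-DP set and rank them.

    score = (targets inside the set) / (the drug's total targets); the
    denominator counts all KG-known targets by default, or only PPI-resident
    ones when ``denominator_in_ppi_only``. Categories: ``indicated`` (matching
    indication, >=1 set target), ``excluded`` (shows the ADR itself, or
    carries a matching indication without being indicated), ``candidate``
    (everything else). Sorted by score desc, then targets_in_set desc, then
    drug id. ``overlaps_indicated_targets`` flags candidates sharing >=1 set
    target with any indicated drug.
    """
    adr_dp = result.adr_dp_proteins
    if not adr_dp:
        return []
    terminology_map = terminology_map or {}
    if indicated is None:
        indicated = find_indicated_drugs(kg, result, terminology_map)
    equivalent: set[str] = set(terminology_map.get(result.pair.adr_id, ())) | set(
        terminology_map.get(result.pair.dp_id, ()))
    drugs_with_adr = kg.drugs_with_adr(result.pair.adr_id)
    indications = kg.tables["drug_indication"].by_source()

    indicated_targets: set[str] = set()
    for d in indicated:
        indicated_targets |= kg.targets_of(d) & adr_dp

    rows: list[RepurposingRow] = []
    for drug in sorted(kg.drugs):
        in_ppi = kg.targets_of(drug)
        hits = in_ppi & adr_dp
        if not hits:
            continue
        total_targets = in_ppi if denominator_in_ppi_only else (kg.raw_drug_targets.get(drug) or in_ppi)
        if drug in indicated:
            category = "indicated"
        elif drug in drugs_with_adr or (indications.get(drug, set()) & equivalent):
            category = "excluded"
        else:
            category = "candidate"
        rows.append(RepurposingRow(
            drug=drug,
            targets_in_set=len(hits),
            targets_total=len(total_targets),
            score=len(hits) / len(total_targets),
            category=category,
            overlaps_indicated_targets=bool(hits & indicated_targets),
        ))
    rows.sort(key=lambda r: (-r.score, -r.targets_in_set, r.drug))
    return rows
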