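"""Rank drug-repurposing candidates by coverage of the mechanism proteins.

After a pipeline run, every drug targeting at least one ADR-DP protein is
scored by the fraction of its targets inside that set. Drugs already
indicated for the phenotype's terminology anchor the list ("indicated");
drugs that themselves show the ADR are excluded from candidacy.
"""

import dreamer as dr
from dreamer.repurposing import find_indicated_drugs, rank_candidates

kg, truth, raw = dr.generate_kg(dr.GeneratorParams(
    rng_seed=1, indication_rate=0.5, indication_placement="far"))
run = dr.run_dreamer(kg, dr.PipelineParams(rng_seed=1))
result = next(r for r in run.ranked() if r.adr_dp_proteins)
print(f"phenotype pair {result.pair.key}: "
      f"{len(result.adr_dp_proteins)} mechanism proteins")

# terminology crosswalk: map the ADR to the indication vocabulary; here we
# declare one planted indication disease equivalent to the phenotype
some_indication = sorted(
    ind for d in kg.drugs_with_adr(result.pair.adr_id)
    for ind in kg.indications_of(d))[0]
terms = {result.pair.adr_id: {some_indication}}

indicated = find_indicated_drugs(kg, result, terms)
print(f"indicated drugs (matching indication + >=1 set target): {sorted(indicated)}")

rows = rank_candidates(kg, result, terms)
print("\ndrug    hits/total  score  category   shares-indicated-target")
for r in rows[:6]:
    print(f"{r.drug:<7} {r.targets_in_set}/{r.targets_total:<9} {r.score:<6.2f} "
          f"{r.category:<10} {'yes' if r.overlaps_indicated_targets else 'no'}")
candidates = [r for r in rows if r.category == "candidate"]
print(f"\ntop repurposing candidates ({len(candidates)} drugs neither show the "
      "ADR nor carry a matching indication):")
for r in candidates[:5]:
    print(f"{r.drug:<7} {r.targets_in_set}/{r.targets_total:<9} {r.score:.2f}")
# score 1.0 means every known target of the drug lies inside the mechanism
# set; candidates are sorted by that coverage, a proxy for on-mechanism
# specificity (with no claim about treating versus inducing).
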