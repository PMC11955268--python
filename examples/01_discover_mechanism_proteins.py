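"""Discover shared ADR-DP mechanism proteins on a synthetic knowledge graph.

Generates a knowledge graph with five planted mechanism modules and five
signal-free phenotype pairs, runs the full diffusion pipeline, and compares
the recovered protein sets against the planted ground truth.
"""

import dreamer as dr

kg, truth, raw = dr.generate_kg(dr.GeneratorParams(rng_seed=1))
print(f"KG: {kg.ppi.number_of_nodes()} proteins, {kg.ppi.number_of_edges()} "
      f"PPI edges, {len(kg.pairs)} phenotype pairs")

run = dr.run_dreamer(kg, dr.PipelineParams(rng_seed=1))
print(f"\n{run.n_pairs_significant}/{run.n_pairs_tested} pairs show a "
      "significant ADR/DP protein-set overlap (BH-adjusted hypergeometric p < 0.05)\n")

print("rank  pair             |ADR set| |DP set| |shared|  adj. p")
for rank, r in enumerate(run.ranked(), start=1):
    print(f"{rank:>4}  {r.pair.key:<16} {len(r.adr_set):>8} {len(r.dp_set):>8} "
          f"{len(r.adr_dp_proteins):>8}  {r.hyper_p_adj:.3g}")

ev = dr.evaluate_recovery(run.results, truth)
planted = ev[ev["planted"]]
print(f"\nmean F1 against planted modules: {planted['f1'].mean():.3f}")
print("Signal-free pairs correctly rejected:",
      int(ev[~ev['planted']]['correct_rejection'].sum()), "of", (~ev['planted']).sum())
# A pair's 'shared' proteins are the inferred mechanism: significant for
# both the ADR and the DP side, with an overlap larger than chance.
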