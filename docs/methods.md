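# Methods

## Problem and model

Many adverse drug reactions (ADRs) and disease phenotypes (DPs) are
clinically the same phenotype arrived at by different routes: a drug
perturbs a set of proteins, a disease carries variants in a set of genes,
and when the two sets sit in the same region of the protein-protein
interaction (PPI) network the phenotype plausibly shares a molecular
mechanism. This package identifies such shared mechanism proteins on a
heterogeneous knowledge graph (KG) of drugs, diseases, proteins, ADRs and
DPs, then stress-tests the finding against two confounders and a
network-proximity holdout.

For one phenotype pair (an ADR and a DP mapped to the same phenotype):

1. **Seed construction.** The ADR seed assigns protein *i* the probability

       p(i) = (# links between i and drugs showing the ADR)
              / (all drug-target links among those drugs)

   so a protein targeted by many of the ADR's drugs carries more initial
   mass. The DP seed is the same construction over disease-gene links of
   the diseases showing the DP; the indication seed uses the union of
   diseases indicated for the ADR's drugs (each indicated disease counted
   once, however many drugs share it).

2. **Diffusion.** Personalized PageRank on the filtered PPI:
   P(t+1) = α·W·P(t) + (1−α)·P0, with W the column-stochastic transition
   matrix of the unweighted graph and damping α = 0.7 (the value
   recommended for high-confidence STRING-scale networks). The fixed point
   scores every protein by proximity to the seed.

3. **Significance.** The seed vector is permuted uniformly over all PPI
   proteins B = 1000 times and diffused again; each protein's one-sided p
   comes from a maximum-likelihood exponential fit to its own null scores
   (p = exp(−score/null mean)), followed by Benjamini-Hochberg (BH)
   correction across proteins. Adjusted p < 0.05 (strict) defines the
   ADR-related (or DP-related, indication-related) set. Fitting per protein
   rather than pooling matters because hub proteins have systematically
   larger null scores; a pooled null would reward centrality.

4. **Intersection.** The ADR-set/DP-set overlap is tested with the
   upper-tail hypergeometric over the PPI universe; BH across all pairs in
   the run; pairs with adjusted p < 0.05 keep their intersection as the
   ADR-DP protein set, others get the empty set.

5. **Confounder controls.** (a) Organ/tissue: drugs whose indications
   affect the ADR's organ are removed, the ADR side and intersection are
   recomputed, and the before/after ADR-DP sets must overlap
   (hypergeometric p < 0.05) for the phenotype to count as robust; if every
   drug is removed the phenotype is dropped. (b) Indication proteins: the
   indication seed is diffused and tested like the others; a significant
   overlap (BH across phenotypes) between indication-related proteins and
   the ADR-DP set flags the phenotype as confounded. The final phenotype
   list is: intersection-significant, organ-surviving, not confounded.

6. **Holdout validation.** Per phenotype, 80% of drugs/diseases form the
   discovery set (the pipeline reruns on them alone), 20% are positive
   assets, and an equal number of non-associated drugs/diseases with at
   least one PPI-resident protein are negative assets. Each asset's
   shortest-path distance to the discovery ADR-DP set is computed;
   counts of assets at distance ≤ X are pooled across phenotypes into one
   2×2 table per X and tested one-sided with Fisher's exact test.

7. **Baseline.** The no-diffusion comparator assigns a protein to a
   phenotype when the drugs (diseases) linked to the protein overlap the
   phenotype's drugs (diseases) beyond chance (hypergeometric, BH across
   proteins).

8. **Repurposing.** Drugs targeting at least one ADR-DP protein are scored
   by (targets inside the set)/(all targets); drugs already indicated for
   the phenotype's terminology (via a user-supplied ADR/DP-disease
   crosswalk) that hit the set are "indicated"; drugs showing the ADR or
   carrying a matching indication are excluded from candidacy. The ranking
   makes no claim of treat-versus-induce directionality.

## Preprocessing rules

`assemble_kg` applies, in order: PPI confidence threshold (keep score
strictly > 800 on the 0–1000 scale; boundary behavior config-exposed) and
restriction to the largest connected component; restriction of drug-target
and disease-gene links to PPI proteins; removal of drugs without targets
and diseases without genes; removal of drug-ADR links where the drug is
indicated for a disease equivalent to the ADR; removal of ADRs with > 50
drugs and DPs with > 100 diseases (very common, uninformative phenotypes);
random selection of one ADR per DP (seeded); retention of pairs whose ADR
has a targeted drug and whose DP has a gene-bearing disease. Every step
logs its drop count; the provenance log reconciles exactly with input minus
output per table.

Order matters and is a package choice: entity-level validity filters run
before the degree filters so that degree reflects usable links. Gene-less
diseases lose their DP links but keep their indication links — indication
equivalence and organ matching are terminological and do not require genes;
the indication seed errors out at seed time instead when no indicated
disease has a gene.

## Numerical choices

- Power iteration stops when the L1 change falls below 1e-12 (max 1000
  iterations; both config-exposed); non-convergence raises with the last
  residual rather than returning a stale vector.
- Permutation nulls propagate in dense (n × batch) blocks (default 256
  columns) so one sparse-dense product advances many permutations; batching
  does not change results (tested).
- On a connected graph scores sum to 1 to 1e-9 and every protein's null
  mean is positive, so the exponential rate is always defined. If LCC
  restriction is disabled, mass reaching a dangling column teleports back
  to the seed (standard correction).
- p = 0 is never emitted; exponential p-values are floored at the smallest
  positive double.
- All randomness flows from one master seed. Per-phenotype permutation
  streams are keyed on (seed, origin, phenotype, qualifying entity set), so
  results are independent of pair iteration order, and a rerun restricted
  to the full entity set reproduces the unrestricted run bitwise.
- Ranking ties in repurposing break by target count, then drug identifier;
  result TSVs are written with sorted rows and fixed float formatting, so a
  fixed master seed reproduces output files byte for byte.
- Holdout rounding: validation size = max(1, round(0.2·n)); unreachable
  assets count as "> X" for every X; phenotypes whose discovery-phase
  ADR-DP set is empty contribute no assets (distance to an empty set is
  undefined) and are reported as skipped.
- BH families: across proteins within one phenotype table; across pairs for
  intersection tests; across phenotypes for indication-overlap and
  known-protein-overlap tests. The organ before/after comparison is a
  single-pair test and uses the raw hypergeometric p.

## Synthetic data: what it emulates and what it does not

Real inputs at the scale of SIDER/HPO/DisGeNET/STRING are licensed or
large; the generator builds KGs with the structural features the method
relies on, so every stage is testable offline:

- a 500-protein PPI (sparse Erdős–Rényi background, density 0.01) with five
  planted 10-protein modules wired at intra-module edge probability 0.6 and
  confidence scores in (800, 1000], plus ~200 decoy edges at or below 800
  that the confidence filter must remove;
- planted phenotype pairs: 14 drugs per ADR (the reported average drugs per
  ADR in the real KG) with 3 targets each, 10 diseases per DP with 3 genes
  each; targets/genes land inside the pair's module with probability 0.9
  and uniformly elsewhere otherwise; null pairs draw uniformly — their
  truth set is empty;
- optional indication diseases per drug with genes placed inside the
  module ("near", a deliberately confounded phenotype) or away from it
  ("far"); organ annotations that make a chosen fraction (default 0.3,
  mirroring the reported ~30% average drug removal) of each ADR's drugs
  share the ADR's organ;
- optional background phenotypes with truncated-power-law degrees (up to
  60) to exercise the > 50/> 100 common-phenotype filters.

Not emulated: the real degree distribution and clustering of STRING,
overlapping or nested mechanism modules, target-popularity reuse across
pharmacological classes, annotation biases, and identifier noise. Passing
the recovery benchmarks therefore shows the method works under its own
assumptions at desk scale — not that it attains the same operating point on
real databases. Target popularity in particular is drawn uniformly on
purpose: popularity-weighted drawing would seed "null" pairs on shared hub
proteins and quietly plant real signal in the negative controls.

Problem sizes used by the test suite and acceptance script (500 proteins,
50 calibration phenotypes, 20 baseline replicates, 20 holdout phenotypes,
B = 1000) were chosen as the smallest scales at which the planted-module
benchmarks are stable across seeds.

## Known limitations

- **The exponential null fit is approximate at desk scale.** On the
  500-protein synthetic PPI the per-protein permutation nulls are visibly
  non-exponential (hop structure makes score levels decay geometrically
  while hit probabilities grow geometrically, giving power-law-like
  tails); the pooled Kolmogorov distance between exponential-fit p-values
  and rank-based permutation p-values measures ≈ 0.12–0.14 under the
  default conditions. The practical false-positive rate remains controlled
  (BH-significant fraction ≤ 1% on structureless phenotypes), and the
  rank-based empirical p is available (`keep_null_scores` +
  `empirical_pvalue`) for anyone wanting a fit-free alternative.
- Permutation of the seed destroys topology linkage but preserves nothing
  about degree; the degree-relationship is handled by fitting per protein,
  not by stratified permutation (a stratified variant would be a natural
  extension for hub-bias sensitivity analysis).
- Organ/tissue matching is exact string match on a user-supplied controlled
  vocabulary; no anatomy-ontology reasoning.
- Gene-protein identity is one-to-one via shared identifiers; no isoform
  handling.
- The dissimilarity split hook requires a caller-supplied similarity
  function (e.g., Tanimoto over fingerprints); no fingerprinting in-core.
- Scores from the PPI confidence column are used only for thresholding by
  default; a config switch enables score-weighted transitions for
  sensitivity analysis, but all reported results use the unweighted graph.
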