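"""Holdout splitting, network-proximity counting, baseline, known-set overlap."""

from math import comb, inf

import pytest

import dreamer as dr
from dreamer.kg import KGConfig, LinkTable, assemble_kg
from dreamer.validation import (
    HoldoutError,
    HoldoutSplit,
    asset_distance,
    baseline_protein_assoc,
    dissimilarity_split_hook,
    holdout_fisher,
    known_overlap_count,
    make_holdout_split,
)


class TestSplit:
    def test_eighty_twenty_arithmetic(self, small_synthetic):
        kg = small_synthetic[0]
        pair = kg.pairs[0]
        split = make_holdout_split(kg, pair, rng_seed=0)
        n = len(kg.drugs_with_adr(pair.adr_id))  # 14 at defaults
        assert len(split.validation_drugs) == max(1, round(0.2 * n))
        assert len(split.discovery_drugs) == n - len(split.validation_drugs)
        assert split.discovery_drugs.isdisjoint(split.validation_drugs)
        assert len(split.negative_drugs) == len(split.validation_drugs)

    def test_negatives_disjoint_from_phenotype_and_ppi_resident(self, small_synthetic):
        kg = small_synthetic[0]
        pair = kg.pairs[0]
        split = make_holdout_split(kg, pair, rng_seed=1)
        assert split.negative_drugs.isdisjoint(kg.drugs_with_adr(pair.adr_id))
        assert split.negative_diseases.isdisjoint(kg.diseases_with_dp(pair.dp_id))
        for d in split.negative_drugs:
            assert kg.targets_of(d)
        for x in split.negative_diseases:
            assert kg.genes_of(x)

    def test_single_drug_phenotype_is_skipped(self, toy_kg):
        pair = next(p for p in toy_kg.pairs if p.key == "A2--DP2")  # one drug
        with pytest.raises(HoldoutError):
            make_holdout_split(toy_kg, pair)

    def test_same_seed_same_split(self, small_synthetic):
        kg = small_synthetic[0]
        a = make_holdout_split(kg, kg.pairs[0], rng_seed=9)
        b = make_holdout_split(kg, kg.pairs[0], rng_seed=9)
        assert a.discovery_drugs == b.discovery_drugs
        assert a.negative_diseases == b.negative_diseases


class TestAssetDistance:
    def test_distances(self, toy_kg):
        # toy PPI: P1-P2-P3-P4-P5-P6 path plus P2-P5 shortcut
        assert asset_distance(toy_kg.ppi, {"P1"}, {"P1", "P4"}) == 0
        assert asset_distance(toy_kg.ppi, {"P1"}, {"P2"}) == 1
        assert asset_distance(toy_kg.ppi, {"P1"}, {"P6"}) == 3  # via P2-P5
        assert asset_distance(toy_kg.ppi, {"absent"}, {"P1"}) == inf

    def test_disconnected_is_unreachable(self):
        import networkx as nx
        g = nx.Graph([("A", "B"), ("C", "D")])
        assert asset_distance(g, {"C"}, {"A"}) == inf


def _two_component_kg():
    """Two PPI components: a hub T with 8 satellites, and 8 isolated-pair
    proteins reachable only within the far component."""
    ppi = [("T", f"S{i}", 900) for i in range(8)]
    ppi += [(f"F{i}", f"F{i+1}", 900) for i in range(8)]
    drug_target = {(f"DP{i}", "T") for i in range(8)}          # positives hit T
    drug_target |= {(f"DN{i}", f"F{i}") for i in range(8)}     # negatives far
    drug_target |= {("Da", "T"), ("Db", "S0")}
    disease_gene = {("Xa", "T"), ("Xb", "S1")}
    tables = {
        "drug_target": LinkTable("drug_target", frozenset(drug_target)),
        "disease_gene": LinkTable("disease_gene", frozenset(disease_gene)),
        "drug_adr": LinkTable("drug_adr", frozenset([("Da", "A1"), ("Db", "A1")])),
        "disease_dp": LinkTable("disease_dp", frozenset([("Xa", "DP1"), ("Xb", "DP1")])),
        "drug_indication": LinkTable("drug_indication", frozenset()),
        "adr_dp": LinkTable("adr_dp", frozenset([("A1", "DP1")])),
    }
    return assemble_kg(tables, ppi, KGConfig(rng_seed=0, restrict_to_lcc=False))


class TestHoldoutFisher:
    def test_degenerate_table_closed_form(self):
        kg = _two_component_kg()
        pair = kg.pairs[0]
        split = HoldoutSplit(
            pair=pair,
            discovery_drugs={"Da"}, validation_drugs={f"DP{i}" for i in range(8)},
            negative_drugs={f"DN{i}" for i in range(8)},
            discovery_diseases={"Xa"}, validation_diseases={"Xa"},
            negative_diseases={"Xb"}, rng_seed=0,
        )
        reports = holdout_fisher(kg, [split], {pair.key: {"T"}}, x_max=2)
        drug = reports["drug"].rows
        # all 8 positives at distance 0, all 8 negatives unreachable
        assert drug.loc[0, ["a", "b", "c", "d"]].tolist() == [8, 0, 0, 8]
        assert drug.loc[0, "fisher_p"] == pytest.approx(1 / comb(16, 8), rel=1e-9)

    def test_identical_profiles_show_no_enrichment(self):
        kg = _two_component_kg()
        pair = kg.pairs[0]
        same = {f"DP{i}" for i in range(4)}
        split = HoldoutSplit(
            pair=pair,
            discovery_drugs={"Da"}, validation_drugs=same, negative_drugs=same,
            discovery_diseases={"Xa"}, validation_diseases={"Xa"}, negative_diseases={"Xa"},
            rng_seed=0,
        )
        reports = holdout_fisher(kg, [split], {pair.key: {"T"}}, x_max=3)
        assert (reports["drug"].rows["fisher_p"] >= 0.5).all()

    def test_counts_monotone_and_margins_fixed(self, small_synthetic):
        kg, truth, raw, run = small_synthetic
        reports, discovery_sets, splits = dr.run_holdout(
            kg, run.params, x_max=4, rng_seed=3)
        for rep in reports.values():
            rows = rep.rows
            assert rows["a"].is_monotonic_increasing
            assert rows["c"].is_monotonic_increasing
            assert (rows["a"] + rows["b"]).nunique() == 1
            assert (rows["c"] + rows["d"]).nunique() == 1

    def test_empty_pool_is_an_error(self):
        kg = _two_component_kg()
        with pytest.raises(HoldoutError):
            holdout_fisher(kg, [], {}, x_max=2)


class TestDissimilaritySplit:
    def test_block_similarity_separates_clusters(self):
        cluster = {"a1": 0, "a2": 0, "b1": 1, "b2": 1}

        def sim(x, y):
            return 0.9 if cluster[x] == cluster[y] else 0.1

        disc, val = dissimilarity_split_hook(["a1", "a2", "b1", "b2"], sim, frac=0.5)
        assert val in ({"a1", "a2"}, {"b1", "b2"})
        assert disc == {"a1", "a2", "b1", "b2"} - val

    def test_constant_provider_degenerates_gracefully(self):
        disc, val = dissimilarity_split_hook([f"d{i}" for i in range(10)], lambda a, b: 0.5)
        assert len(val) == 2 and len(disc) == 8

    def test_missing_provider_errors(self):
        with pytest.raises(ValueError, match="random split"):
            dissimilarity_split_hook(["d1", "d2"], None)


@pytest.fixture(scope="module")
def wide_kg():
# 100 drugs; the ADR's five drugs all target PX; 95 others target PY
    ppi = [("PX", "PY", 900), ("PY", "PZ", 900)]
    drug_target = {(f"D{i:03d}", "PX") for i in range(5)}
    drug_target |= {(f"D{i:03d}", "PY") for i in range(5, 100)}
    tables = {
        "drug_target": LinkTable("drug_target", frozenset(drug_target)),
        "disease_gene": LinkTable("disease_gene", frozenset([("X1", "PZ"), ("X2", "PZ")])),
        "drug_adr": LinkTable("drug_adr", frozenset((f"D{i:03d}", "A1") for i in range(5))),
        "disease_dp": LinkTable("disease_dp", frozenset([("X1", "DP1"), ("X2", "DP1")])),
        "drug_indication": LinkTable("drug_indication", frozenset()),
        "adr_dp": LinkTable("adr_dp", frozenset([("A1", "DP1")])),
    }
    return assemble_kg(tables, ppi, KGConfig(rng_seed=0))

class TestBaseline:
    def test_perfectly_shared_protein_assigned(self, wide_kg):
        # PX is hit by exactly the ADR's 5 drugs out of 100: p = 1/C(100,5)
        found = baseline_protein_assoc(wide_kg, "A1", "adr")
        assert "PX" in found

    def test_protein_sharing_no_drugs_not_assigned(self, wide_kg):
        found = baseline_protein_assoc(wide_kg, "A1", "adr")
        assert "PY" not in found and "PZ" not in found

    def test_dp_origin_uses_disease_universe(self, wide_kg):
        found = baseline_protein_assoc(wide_kg, "DP1", "dp")
        # PZ is linked to both DP1 diseases, but the universe has only two
        # diseases, so the overlap carries no evidence (p = 1)
        assert found == set()


class TestKnownOverlap:
    def test_exact_match_counts_all(self):
        universe = {f"P{i}" for i in range(100)}
        sets = {f"ph{i}": set(sorted(universe)[:10]) for i in range(10)}
        assert known_overlap_count(sets, sets, universe) == 10

    def test_disjoint_counts_none(self):
        universe = {f"P{i}" for i in range(100)}
        res = {"ph": set(sorted(universe)[:10])}
        known = {"ph": set(sorted(universe)[10:20])}
        assert known_overlap_count(res, known, universe) == 0

    def test_half_matching(self):
        universe = {f"P{i}" for i in range(200)}
        items = sorted(universe)
        res = {f"ph{i}": set(items[:10]) for i in range(10)}
        known = {f"ph{i}": (set(items[:10]) if i < 5 else set(items[100:110]))
                 for i in range(10)}
        assert known_overlap_count(res, known, universe) == 5
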