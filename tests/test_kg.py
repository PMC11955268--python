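"""Knowledge-graph parsing, filtering and assembly."""

import pytest

import dreamer as dr
from dreamer.kg import (
    AssemblyError,
    KGConfig,
    LinkTable,
    ParseError,
    ValidationError,
    assemble_kg,
    filter_common_adrs,
    filter_common_dps,
    filter_ppi_by_score,
    load_kg,
    read_link_table,
    read_ppi_table,
    remove_indication_equivalent_links,
    save_kg,
    select_unique_adr_per_dp,
)

from conftest import toy_ppi, toy_tables


class TestParsing:
    def test_duplicate_rows_are_collapsed(self, tmp_path):
        p = tmp_path / "dt.tsv"
        p.write_text("D1\tP1\nD1\tP1\nD2\tP2\n")
        table = read_link_table(p, "drug_target")
        assert len(table) == 2

    def test_empty_file_gives_empty_table(self, tmp_path):
        p = tmp_path / "dt.tsv"
        p.write_text("# only a comment\n\n")
        assert len(read_link_table(p, "drug_target")) == 0

    def test_wrong_column_count_names_line(self, tmp_path):
        p = tmp_path / "dt.tsv"
        p.write_text("D1\n")
        with pytest.raises(ParseError, match="line 1"):
            read_link_table(p, "drug_target")

    def test_ppi_bad_score_is_a_parse_error(self, tmp_path):
        p = tmp_path / "ppi.tsv"
        p.write_text("P1\tP2\thigh\n")
        with pytest.raises(ParseError, match="line 1"):
            read_ppi_table(p)


class TestPPIFilter:
    def test_threshold_is_strictly_greater(self):
        g = filter_ppi_by_score([("A", "B", 801), ("A", "C", 800), ("A", "D", 799)])
        assert set(g.edges) == {("A", "B")}
        assert "C" not in g and "D" not in g  # isolated proteins dropped

    def test_all_max_score_edges_retained(self):
        edges = [("A", "B", 1000), ("B", "C", 1000)]
        g = filter_ppi_by_score(edges)
        assert g.number_of_edges() == 2

    def test_self_loop_dropped(self):
        g = filter_ppi_by_score([("A", "A", 900), ("A", "B", 900)])
        assert set(g.edges) == {("A", "B")}

    def test_negative_score_rejected(self):
        with pytest.raises(ValidationError):
            filter_ppi_by_score([("A", "B", -1)])

    def test_inclusive_mode_keeps_boundary(self):
        g = filter_ppi_by_score([("A", "B", 800)], strict=False)
        assert g.number_of_edges() == 1


class TestDegreeFilters:
    @pytest.mark.parametrize(
        "n_drugs,kept", [(51, False), (50, True)],
        ids=["over-limit-removed", "boundary-kept"],
    )
    def test_common_adr_boundary(self, n_drugs, kept):
        links = frozenset((f"D{i}", "A1") for i in range(n_drugs))
        out = filter_common_adrs(LinkTable("drug_adr", links))
        assert (len(out) == n_drugs) is kept

    @pytest.mark.parametrize(
        "n_dis,kept", [(101, False), (100, True)],
        ids=["over-limit-removed", "boundary-kept"],
    )
    def test_common_dp_boundary(self, n_dis, kept):
        links = frozenset((f"X{i}", "DP1") for i in range(n_dis))
        out = filter_common_dps(LinkTable("disease_dp", links))
        assert (len(out) == n_dis) is kept

    def test_empty_tables_pass_through(self):
        assert len(filter_common_adrs(LinkTable("drug_adr", frozenset()))) == 0
        assert len(filter_common_dps(LinkTable("disease_dp", frozenset()))) == 0


class TestIndicationEquivalentRemoval:
    def test_equivalent_indication_link_removed(self):
        # a drug treating the very condition it reportedly causes
        drug_adr = LinkTable("drug_adr", frozenset([("D", "hypertension_adr"), ("E", "hypertension_adr")]))
        drug_ind = LinkTable("drug_indication", frozenset([("D", "hypertension")]))
        out = remove_indication_equivalent_links(
            drug_adr, drug_ind, {"hypertension_adr": {"hypertension"}})
        assert out.links == frozenset([("E", "hypertension_adr")])

    def test_no_equivalence_leaves_table_unchanged(self):
        drug_adr = LinkTable("drug_adr", frozenset([("D", "A1")]))
        drug_ind = LinkTable("drug_indication", frozenset([("D", "X1")]))
        assert remove_indication_equivalent_links(drug_adr, drug_ind, {}).links == drug_adr.links

    def test_equivalence_without_link_is_noop(self):
        drug_adr = LinkTable("drug_adr", frozenset([("E", "A1")]))
        drug_ind = LinkTable("drug_indication", frozenset([("D", "X1")]))
        out = remove_indication_equivalent_links(drug_adr, drug_ind, {"A1": {"X1"}})
        assert out.links == drug_adr.links


class TestPairSelection:
    def test_single_candidate_kept_regardless_of_seed(self):
        t = LinkTable("adr_dp", frozenset([("A1", "DP1")]))
        for seed in (0, 99):
            pairs = select_unique_adr_per_dp(t, seed)
            assert [(p.adr_id, p.dp_id) for p in pairs] == [("A1", "DP1")]

    def test_deterministic_given_seed(self):
        t = LinkTable("adr_dp", frozenset([("A1", "DP1"), ("A2", "DP1"), ("A3", "DP1")]))
        first = select_unique_adr_per_dp(t, 7)
        assert select_unique_adr_per_dp(t, 7) == first
        assert len(first) == 1

    def test_disjoint_dps_yield_one_pair_each(self):
        t = LinkTable("adr_dp", frozenset([("A1", "DP1"), ("A2", "DP2")]))
        assert len(select_unique_adr_per_dp(t, 0)) == 2


class TestAssembly:
    def test_toy_assembly_satisfies_invariants(self, toy_kg):
        toy_kg.validate()
        assert {p.key for p in toy_kg.pairs} == {"A1--DP1", "A2--DP2"}
        assert toy_kg.ppi.number_of_nodes() == 6

    def test_drug_with_only_non_ppi_target_is_dropped(self):
        # D2's single target P9 is absent from the filtered PPI, so D2 and
        # its ADR link must vanish while D1 survives
        tables = toy_tables()
        tables["drug_target"] = LinkTable("drug_target", frozenset([
            ("D1", "P1"), ("D1", "P2"), ("D2", "P9"),
        ]))
        kg = assemble_kg(tables, toy_ppi(), KGConfig(rng_seed=0))
        assert "D2" not in kg.drugs
        assert kg.drugs_with_adr("A1") == {"D1"}

    def test_geneless_disease_loses_dp_links(self):
        tables = toy_tables()
        tables["disease_gene"] = LinkTable("disease_gene", frozenset(
            (d, g) for d, g in tables["disease_gene"].links if d != "X3"
        ))
        # DP2's only disease lost its genes -> pair A2--DP2 cannot survive
        kg = assemble_kg(tables, toy_ppi(), KGConfig(rng_seed=0))
        assert {p.key for p in kg.pairs} == {"A1--DP1"}

    def test_zero_surviving_pairs_is_an_error(self):
        tables = toy_tables()
        tables["adr_dp"] = LinkTable("adr_dp", frozenset())
        with pytest.raises(AssemblyError):
            assemble_kg(tables, toy_ppi(), KGConfig(rng_seed=0))

    def test_assembly_is_idempotent(self, toy_kg):
        edges = [(a, b, d.get("score", 1000.0)) for a, b, d in toy_kg.ppi.edges(data=True)]
        again = assemble_kg(toy_kg.tables, edges, toy_kg.config)
        assert {k: t.links for k, t in again.tables.items()} == \
               {k: t.links for k, t in toy_kg.tables.items()}
        assert {frozenset(e) for e in again.ppi.edges} == {frozenset(e) for e in toy_kg.ppi.edges}
        assert [p.key for p in again.pairs] == [p.key for p in toy_kg.pairs]

    def test_provenance_accounts_for_every_dropped_link(self, small_synthetic):
        kg = small_synthetic[0]
        prov = kg.provenance
        audits = {
            "drug_target": ["drug_target_links_dropped_non_ppi"],
            "disease_gene": ["disease_gene_links_dropped_non_ppi"],
            "drug_indication": ["drug_indication_links_dropped_targetless_drug"],
            "drug_adr": [
                "drug_adr_links_dropped_targetless_drug",
                "drug_adr_links_dropped_indication_equivalent",
                "drug_adr_links_dropped_common_adr",
            ],
            "disease_dp": [
                "disease_dp_links_dropped_geneless_disease",
                "disease_dp_links_dropped_common_dp",
            ],
            "adr_dp": [
                "adr_dp_links_dropped_endpoint",
                "adr_dp_links_dropped_unselected",
            ],
        }
        for kind, keys in audits.items():
            dropped = sum(prov[k] for k in keys)
            assert prov[f"{kind}_links_input"] - prov[f"{kind}_links_output"] == dropped, kind

    def test_every_pair_is_diffusible(self, small_synthetic):
        kg = small_synthetic[0]
        for pair in kg.pairs:
            dr.build_adr_seed(kg, pair.adr_id)
            dr.build_dp_seed(kg, pair.dp_id)


class TestBundleIO:
    def test_save_load_roundtrip(self, toy_kg, tmp_path):
        save_kg(toy_kg, tmp_path / "kg")
        back = load_kg(tmp_path / "kg")
        assert {k: t.links for k, t in back.tables.items()} == \
               {k: t.links for k, t in toy_kg.tables.items()}
        assert {frozenset(e) for e in back.ppi.edges} == {frozenset(e) for e in toy_kg.ppi.edges}
        assert [p.key for p in back.pairs] == [p.key for p in toy_kg.pairs]
        assert back.raw_drug_targets == toy_kg.raw_drug_targets
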