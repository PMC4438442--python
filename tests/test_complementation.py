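import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from symbionet.complementation import (
    CLASSIFICATIONS,
    ComplementationInputError,
    augment_sources_with_cofactors,
    call_pseudogene,
    classify_sources,
    complementation_report,
    pathway_complementation,
)
from symbionet.datasets import lysine_pathway_case
from symbionet.network_io import network_from_reactions
from symbionet.seed_scope import build_compound_graph, detect_seeds, scope

from conftest import rxn


class TestCallPseudogene:
    def test_exactly_twenty_percent_reduction_is_intact(self):
        assert call_pseudogene(800, [1000]) == "intact"

    def test_just_over_twenty_percent_is_pseudogene(self):
        assert call_pseudogene(799, [1000]) == "pseudogene"

    def test_median_reference_with_multiple_orthologs(self):
        assert call_pseudogene(1000, [900, 1000, 1100]) == "intact"
        assert call_pseudogene(700, [900, 1000, 1100]) == "pseudogene"

    def test_empty_ortholog_list_is_error(self):
        with pytest.raises(ComplementationInputError):
            call_pseudogene(500, [])

    @given(
        length=st.integers(min_value=1, max_value=5000),
        orthologs=st.lists(st.integers(min_value=1, max_value=5000), min_size=1, max_size=7),
        factor=st.integers(min_value=2, max_value=10),
    )
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance(self, length, orthologs, factor):
        base = call_pseudogene(length, orthologs)
        scaled = call_pseudogene(length * factor, [x * factor for x in orthologs])
        assert base == scaled


class TestClassifySources:
    def _setup(self):
        # partner P synthesizes CHOR from its own seed S; organism H needs
        # CHOR, PROTO (host) and MYSTERY (nothing provides it)
        net_p = network_from_reactions("P", [rxn("p1", ["S"], ["CHOR"])])
        net_h = network_from_reactions(
            "H",
            [
                rxn("h1", ["CHOR"], ["X"]),
                rxn("h2", ["PROTO"], ["Y"]),
                rxn("h3", ["MYSTERY"], ["Z"]),
            ],
        )
        seeds_h = detect_seeds(build_compound_graph(net_h), "H")
        seeds_p = detect_seeds(build_compound_graph(net_p), "P")
        scope_p = scope(net_p, seeds_p.seed_ids)
        return seeds_h, scope_p

    def test_priority_partner_host_diet(self):
        seeds_h, scope_p = self._setup()
        out = classify_sources(seeds_h, scope_p, {"PROTO": "mitochondria"}, "P")
        by_id = {c.metabolite_id: c for c in out}
        assert by_id["CHOR"].provenance == "partner"
        assert by_id["CHOR"].provider == "P"
        assert by_id["PROTO"].provenance == "host"
        assert by_id["PROTO"].provider == "mitochondria"
        assert by_id["MYSTERY"].provenance == "diet_or_unknown"

    def test_partner_wins_over_whitelist(self):
        seeds_h, scope_p = self._setup()
        out = classify_sources(seeds_h, scope_p, {"CHOR": "cytosol"}, "P")
        assert {c.provenance for c in out if c.metabolite_id == "CHOR"} == {"partner"}

    def test_partner_own_seed_is_not_partner_provided(self):
        """A compound the partner merely imports (its own seed) is not
        something the partner synthesizes for its neighbour."""
        seeds_h, scope_p = self._setup()
        assert "S" in scope_p.producible  # sources are producible...
        net_h2 = network_from_reactions("H", [rxn("h", ["S"], ["Q"])])
        seeds_h2 = detect_seeds(build_compound_graph(net_h2), "H")
        out = classify_sources(seeds_h2, scope_p, {}, "P")
        assert out[0].metabolite_id == "S"
        assert out[0].provenance == "diet_or_unknown"  # ...but not synthesized

    def test_output_sorted_by_provenance_then_id(self):
        seeds_h, scope_p = self._setup()
        out = classify_sources(seeds_h, scope_p, {"PROTO": "mitochondria"}, "P")
        keys = [(c.provenance, c.metabolite_id) for c in out]
        rank = {"partner": 0, "host": 1, "diet_or_unknown": 2}
        assert keys == sorted(keys, key=lambda t: (rank[t[0]], t[1]))

    def test_every_seed_gets_exactly_one_provenance(self):
        seeds_h, scope_p = self._setup()
        out = classify_sources(seeds_h, scope_p, {}, "P")
        assert sorted(c.metabolite_id for c in out) == sorted(seeds_h.seed_ids)


class TestCofactorAugmentation:
    def test_unproducible_cofactor_added(self):
        net = network_from_reactions("P", [rxn("r", ["A"], ["B"], ec=["1.1.1.1"])])
        out = augment_sources_with_cofactors(net, {"1.1.1.1": ["NAD"]}, {"A"})
        assert out == {"A", "NAD"}

    def test_producible_cofactor_not_added(self):
        net = network_from_reactions(
            "P",
            [rxn("r", ["A"], ["NAD"], ec=["1.1.1.1"]), rxn("u", ["NAD"], ["B"])],
        )
        out = augment_sources_with_cofactors(net, {"1.1.1.1": ["NAD"]}, {"A"})
        assert out == {"A"}

    def test_cofactor_already_a_source_is_identity(self):
        net = network_from_reactions("P", [rxn("r", ["A"], ["B"], ec=["1.1.1.1"])])
        out = augment_sources_with_cofactors(net, {"1.1.1.1": ["A"]}, {"A"})
        assert out == {"A"}

    def test_empty_map_is_identity(self):
        net = network_from_reactions("P", [rxn("r", ["A"], ["B"], ec=["1.1.1.1"])])
        assert augment_sources_with_cofactors(net, {}, {"A"}) == {"A"}

    def test_ec_absent_from_network_ignored(self):
        net = network_from_reactions("P", [rxn("r", ["A"], ["B"], ec=["1.1.1.1"])])
        out = augment_sources_with_cofactors(net, {"9.9.9.9": ["FAD"]}, {"A"})
        assert out == {"A"}


class TestPathwayComplementation:
    def test_lysine_worked_example_is_reciprocal(self):
        genes, portiera, hamiltonella = lysine_pathway_case()
        prof = pathway_complementation(
            "lysine", genes, portiera, hamiltonella,
            genome_a="Portiera", genome_b="Hamiltonella",
        )
        assert prof.classification == "reciprocal_complementation"
        assert prof.missing_in_a_covered_by_b == 3
        assert prof.missing_in_b_covered_by_a == 1
        assert prof.missing_in_both == 0

    def test_gap_in_both_without_host_evidence_is_holobiont_gap(self):
        genes = ["hisG", "hisB", "hisD"]
        a = {"hisG": "intact", "hisB": "absent", "hisD": "absent"}
        b = {"hisG": "intact", "hisB": "absent", "hisD": "absent"}
        prof = pathway_complementation("histidine", genes, a, b)
        assert prof.classification == "holobiont_gap"
        assert prof.missing_in_both == 2

    def test_gap_in_both_with_host_evidence_is_host_complemented(self):
        genes = ["ilvC", "ilvE"]
        a = {"ilvC": "intact", "ilvE": "absent"}
        b = {"ilvC": "intact", "ilvE": "absent"}
        prof = pathway_complementation("bcaa", genes, a, b, host_evidence={"ilvE"})
        assert prof.classification == "host_complemented"

    def test_all_intact_everywhere_is_redundant(self):
        genes = ["g1", "g2"]
        ok = {"g1": "intact", "g2": "intact"}
        assert pathway_complementation("p", genes, ok, dict(ok)).classification == "redundant"

    def test_entire_pathway_in_one_genome_only(self):
        genes = ["g1", "g2"]
        ok = {"g1": "intact", "g2": "intact"}
        gone = {"g1": "absent", "g2": "absent"}
        assert (
            pathway_complementation("p", genes, ok, gone).classification == "complete_in_A"
        )
        assert (
            pathway_complementation("p", genes, gone, ok).classification == "complete_in_B"
        )

    def test_partial_gap_on_one_side_is_one_way(self):
        genes = ["g1", "g2", "g3"]
        ok = {g: "intact" for g in genes}
        partial = {"g1": "intact", "g2": "absent", "g3": "pseudogene"}
        prof = pathway_complementation("p", genes, ok, partial)
        assert prof.classification == "one_way_complementation"
        assert prof.missing_in_b_covered_by_a == 2

    def test_missing_status_names_the_gene(self):
        with pytest.raises(ComplementationInputError, match="g2"):
            pathway_complementation("p", ["g1", "g2"], {"g1": "intact"}, {"g1": "intact", "g2": "intact"})

    @pytest.mark.parametrize("kind", CLASSIFICATIONS)
    def test_swap_symmetry(self, kind):
        from symbionet.synthetic_data import generate_pathway_case

        genes, a, b, host, label = generate_pathway_case(kind, 5, rng_seed=7)
        fwd = pathway_complementation("p", genes, a, b, host).classification
        swp = pathway_complementation("p", genes, b, a, host).classification
        flip = {"complete_in_A": "complete_in_B", "complete_in_B": "complete_in_A"}
        assert swp == flip.get(fwd, fwd)


class TestReport:
    def test_empty_inputs_give_zero_count_summary(self):
        report = complementation_report([], [])
        assert report["summary"]["n_sources"] == 0
        assert report["summary"]["n_pathways"] == 0
        assert set(report["summary"]["pathways_by_classification"]) == set(CLASSIFICATIONS)

    def test_summary_counts_match_row_sections(self):
        genes, a, b = lysine_pathway_case()
        prof = pathway_complementation("lysine", genes, a, b)
        net_p = network_from_reactions("P", [rxn("p1", ["S"], ["CHOR"])])
        net_h = network_from_reactions("H", [rxn("h1", ["CHOR"], ["X"])])
        seeds_h = detect_seeds(build_compound_graph(net_h), "H")
        seeds_p = detect_seeds(build_compound_graph(net_p), "P")
        classes = classify_sources(seeds_h, scope(net_p, seeds_p.seed_ids), {}, "P")
        report = complementation_report([prof], classes)
        assert report["summary"]["n_sources"] == len(report["sources"]) == len(classes)
        assert report["summary"]["n_pathways"] == len(report["pathways"]) == 1
        assert sum(report["summary"]["sources_by_provenance"].values()) == len(classes)
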