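import numpy as np
import pytest

from symbionet.curation import (
    CurationConfigError,
    apply_taxon_blocklist,
    curate_pair,
    filter_spontaneous,
    instantiate_generic_metabolites,
    prune_multifunctional,
    remove_disconnected_reactions,
)
from symbionet.network_io import MetabolicNetwork, Metabolite, network_from_reactions

from conftest import rxn
from oracles import all_disconnection_outcomes


def empty_net(org="b"):
    return MetabolicNetwork(organism=org)


class TestRemoveDisconnected:
    def test_unfed_reaction_removed(self):
        net_a = network_from_reactions("a", [rxn("r1", ["X", "Y"], ["Z"])])
        out_a, _, log = remove_disconnected_reactions(net_a, empty_net(), set())
        assert out_a.n_reactions == 0
        assert log.removed_reactions[0][:2] == ("r1", "disconnected")

    def test_partner_product_triggers_safeguard(self):
        net_a = network_from_reactions("a", [rxn("r1", ["X", "Y"], ["Z"])])
        net_b = network_from_reactions("b", [rxn("rb", ["W"], ["Y"])])
        # rb itself is fed by nothing, but its product Y protects r1 only
        # while rb is retained; declare W a source so rb survives.
        out_a, out_b, log = remove_disconnected_reactions(net_a, net_b, {"W"})
        assert "r1" in out_a.reactions
        assert "r1" in log.retained_by_partner_check

    def test_cascade_removed_at_fixpoint(self):
        net_a = network_from_reactions(
            "a", [rxn("r1", ["orphan"], ["M"]), rxn("r2", ["M"], ["N"])]
        )
        out_a, _, log = remove_disconnected_reactions(net_a, empty_net(), set())
        assert out_a.n_reactions == 0
        assert {r[0] for r in log.removed_reactions} == {"r1", "r2"}

    def test_declared_source_keeps_chain(self):
        net_a = network_from_reactions(
            "a", [rxn("r1", ["S"], ["M"]), rxn("r2", ["M"], ["N"])]
        )
        out_a, _, _ = remove_disconnected_reactions(net_a, empty_net(), {"S"})
        assert out_a.n_reactions == 2

    def test_idempotent(self):
        net_a = network_from_reactions(
            "a", [rxn("r1", ["S"], ["M"]), rxn("r2", ["X"], ["Y"])]
        )
        a1, b1, _ = remove_disconnected_reactions(net_a, empty_net(), {"S"})
        a2, b2, log2 = remove_disconnected_reactions(a1, b1, {"S"})
        assert a2 == a1 and b2 == b1 and log2.n_removed == 0

    @pytest.mark.parametrize("seed", range(20))
    def test_order_independence_vs_exhaustive_permutations(self, seed):
        """The fixpoint must equal the unique terminal state of every
        one-at-a-time removal order on small random two-network instances."""
        rng = np.random.default_rng(seed)
        mets = [f"m{i}" for i in range(6)]
        sources = frozenset(m for m in mets if rng.random() < 0.3)

        def random_rxns(prefix, n):
            out = []
            for i in range(n):
                subs = rng.choice(6, size=rng.integers(1, 3), replace=False)
                remaining = [j for j in range(6) if j not in subs]
                prods = rng.choice(remaining, size=rng.integers(1, 3), replace=False)
                out.append(
                    rxn(
                        f"{prefix}{i}",
                        [mets[j] for j in subs],
                        [mets[j] for j in prods],
                    )
                )
            return out

        rxns_a = random_rxns("a", int(rng.integers(1, 4)))
        rxns_b = random_rxns("b", int(rng.integers(0, 3)))
        net_a = network_from_reactions("a", rxns_a)
        net_b = network_from_reactions("b", rxns_b)

        terminals = all_disconnection_outcomes(rxns_a, rxns_b, sources)
        assert len(terminals) == 1, "brute force found order-dependent outcomes"
        out_a, out_b, _ = remove_disconnected_reactions(net_a, net_b, sources)
        assert (frozenset(out_a.reactions), frozenset(out_b.reactions)) in terminals


class TestFilterSpontaneous:
    def test_connected_spontaneous_retained(self):
        net = network_from_reactions(
            "a",
            [rxn("enz", ["A"], ["B"]), rxn("sp", ["B"], ["C"], spontaneous=True)],
        )
        out, log = filter_spontaneous(net)
        assert "sp" in out.reactions and log.n_removed == 0

    def test_isolated_spontaneous_removed(self):
        net = network_from_reactions(
            "a",
            [rxn("enz", ["A"], ["B"]), rxn("sp", ["X"], ["Y"], spontaneous=True)],
        )
        out, log = filter_spontaneous(net)
        assert "sp" not in out.reactions
        assert log.removed_reactions[0][1] == "spontaneous_unconnected"

    def test_all_spontaneous_network_emptied(self):
        net = network_from_reactions(
            "a",
            [
                rxn("s1", ["A"], ["B"], spontaneous=True),
                rxn("s2", ["B"], ["C"], spontaneous=True),
            ],
        )
        out, log = filter_spontaneous(net)
        assert out.n_reactions == 0 and log.n_removed == 2

    def test_idempotent(self):
        net = network_from_reactions(
            "a",
            [rxn("enz", ["A"], ["B"]), rxn("sp", ["X"], ["Y"], spontaneous=True)],
        )
        once, _ = filter_spontaneous(net)
        twice, log = filter_spontaneous(once)
        assert twice == once and log.n_removed == 0


class TestInstantiateGeneric:
    def _sugar_net(self):
        return network_from_reactions(
            "a",
            [
                rxn("mk", ["X"], ["glucose"]),
                rxn("r", ["a sugar"], ["P"]),
            ],
            metabolites={"a sugar": Metabolite("a sugar", is_generic=True)},
        )

    def test_mapped_generic_instantiated_and_disconnected_copy_dropped(self):
        net = self._sugar_net()
        out, log = instantiate_generic_metabolites(
            net, {"a sugar": ["glucose", "fructose"]}
        )
        kept = [r for r in out.reactions.values() if r.id.startswith("r__")]
        assert len(kept) == 1
        assert kept[0].substrates == ("glucose",)
        dropped = [r for r in log.removed_reactions if r[0] == "r__fructose"]
        assert dropped and dropped[0][1] == "disconnected"
        assert ("a sugar", "glucose") in log.replaced_metabolites
        assert "a sugar" not in out.metabolites

    def test_no_generics_is_identity(self, linear_net):
        out, log = instantiate_generic_metabolites(linear_net, {})
        assert out == linear_net and log.n_removed == 0

    def test_unmapped_generic_removes_reaction(self):
        net = self._sugar_net()
        out, log = instantiate_generic_metabolites(net, {})
        assert "r" not in out.reactions
        assert log.removed_reactions[0][:2] == ("r", "generic_unresolvable")

    def test_empty_mapping_list_is_config_error(self):
        with pytest.raises(CurationConfigError):
            instantiate_generic_metabolites(self._sugar_net(), {"a sugar": []})

    def test_declared_source_keeps_copy(self):
        net = network_from_reactions(
            "a",
            [rxn("r", ["a sugar"], ["P"])],
            metabolites={"a sugar": Metabolite("a sugar", is_generic=True)},
        )
        out, _ = instantiate_generic_metabolites(
            net, {"a sugar": ["fructose"]}, declared_sources={"fructose"}
        )
        assert any(r.substrates == ("fructose",) for r in out.reactions.values())


class TestTaxonBlocklist:
    def test_blocklisted_ec_removed(self):
        net = network_from_reactions(
            "a", [rxn("r1", ["A"], ["B"], ec=["1.2.3.4"]), rxn("r2", ["B"], ["C"])]
        )
        out, log = apply_taxon_blocklist(net, {"1.2.3.4"})
        assert set(out.reactions) == {"r2"}
        assert log.removed_reactions[0][1] == "taxon_blocklist"

    def test_empty_blocklist_is_identity(self, linear_net):
        out, log = apply_taxon_blocklist(linear_net, set())
        assert out == linear_net and log.n_removed == 0

    def test_unmatched_entry_logs_notice(self, linear_net):
        out, log = apply_taxon_blocklist(linear_net, {"9.9.9.9"})
        assert out == linear_net
        assert any("9.9.9.9" in n for n in log.notices)


class TestPruneMultifunctional:
    def test_isolated_copy_removed_connected_kept(self):
        net = network_from_reactions(
            "a",
            [
                rxn("base", ["A"], ["B"]),
                rxn("c1", ["B"], ["C"], ec=["2.2.2.2"]),
                rxn("c2", ["X"], ["Y"], ec=["2.2.2.2"]),
            ],
        )
        out, log = prune_multifunctional(net)
        assert "c1" in out.reactions and "c2" not in out.reactions
        assert log.removed_reactions[0][1] == "multifunctional_unconnected"

    def test_unique_ec_reactions_untouched(self):
        net = network_from_reactions(
            "a",
            [rxn("r1", ["A"], ["B"], ec=["1.1.1.1"]), rxn("r2", ["X"], ["Y"], ec=["2.2.2.2"])],
        )
        out, log = prune_multifunctional(net)
        assert out == net and log.n_removed == 0

    def test_both_copies_connected_both_kept(self):
        net = network_from_reactions(
            "a",
            [
                rxn("base", ["A"], ["B", "X"]),
                rxn("c1", ["B"], ["C"], ec=["2.2.2.2"]),
                rxn("c2", ["X"], ["Y"], ec=["2.2.2.2"]),
            ],
        )
        out, _ = prune_multifunctional(net)
        assert {"c1", "c2"} <= set(out.reactions)

    def test_all_copies_disconnected_all_removed(self):
        net = network_from_reactions(
            "a",
            [
                rxn("c1", ["B"], ["C"], ec=["2.2.2.2"]),
                rxn("c2", ["X"], ["Y"], ec=["2.2.2.2"]),
            ],
        )
        out, log = prune_multifunctional(net)
        assert out.n_reactions == 0 and log.n_removed == 2


class TestCuratePair:
    def test_log_accounts_for_reaction_count_difference(self):
        net_a = network_from_reactions(
            "a",
            [
                rxn("keep", ["S"], ["B"]),
                rxn("dead", ["X"], ["Y"]),
                rxn("sp", ["P"], ["Q"], spontaneous=True),
                rxn("rev", ["B"], ["C"], reversible=True),
            ],
        )
        net_b = network_from_reactions("b", [rxn("bk", ["S"], ["Z"])])
        from symbionet.network_io import split_reversible

        n_in = split_reversible(net_a).n_reactions + split_reversible(net_b).n_reactions
        out_a, out_b, log = curate_pair(net_a, net_b, declared_sources={"S"})
        n_out = out_a.n_reactions + out_b.n_reactions
        # conservation: nothing instantiated here, so in = out + removed
        assert n_in == n_out + log.n_removed

    def test_no_new_metabolites_introduced(self):
        net_a = network_from_reactions(
            "a",
            [rxn("mk", ["S"], ["glucose"]), rxn("g", ["a sugar"], ["P"])],
            metabolites={"a sugar": Metabolite("a sugar", is_generic=True)},
        )
        net_b = network_from_reactions("b", [rxn("b1", ["S"], ["W"])])
        gmap = {"a sugar": ["glucose", "ribose"]}
        out_a, out_b, _ = curate_pair(net_a, net_b, {"S"}, generic_map=gmap)
        allowed = (
            net_a.metabolite_ids
            | net_b.metabolite_ids
            | {s for v in gmap.values() for s in v}
        )
        assert out_a.metabolite_ids | out_b.metabolite_ids <= allowed
        assert not out_a.generic_metabolite_ids()
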