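"""Network-curation rules applied before source detection.

Automatic metabolic reconstructions carry artifacts — isolated reactions fed
by nothing either symbiont makes, spontaneous reactions placed everywhere
because they need no enzyme, generic compound-class placeholders, and
reactions that do not occur in prokaryotes. Each rule here removes one class
of artifact and records every removal in an auditable :class:`CurationLog`,
replacing manual control with a reproducible record.

The disconnection rule is a *joint* rule over the two co-resident symbionts:
before a reaction is removed from one network, we check that none of its
metabolites is a product or a declared source of the partner's metabolism —
a reaction that looks dead in isolation may be fed by cross-feeding. Ties
resolve in favour of retention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .network_io import (
    MetabolicNetwork,
    Metabolite,
    NetworkValidationError,
    Reaction,
)

CURATION_RULES = frozenset(
    {
        "disconnected",
        "spontaneous_unconnected",
        "generic_unresolvable",
        "taxon_blocklist",
        "multifunctional_unconnected",
    }
)


class CurationConfigError(ValueError):
    """A curation configuration (generic map, blocklist) is unusable."""


@dataclass
class CurationLog:
    """Auditable record of what a curation pass did and why.

    ``removed_reactions`` holds (reaction id, rule name, justification);
    ``replaced_metabolites`` holds (generic id, specific id) pairs from
    instantiation; ``retained_by_partner_check`` lists reactions that met a
    removal condition but were kept because a metabolite of theirs is a
    product or declared source of the partner network.
    """

    removed_reactions: list[tuple[str, str, str]] = field(default_factory=list)
    replaced_metabolites: list[tuple[str, str]] = field(default_factory=list)
    retained_by_partner_check: list[str] = field(default_factory=list)
    notices: list[str] = field(default_factory=list)

    def record_removal(self, reaction_id: str, rule: str, justification: str) -> None:
        if rule not in CURATION_RULES:
            raise ValueError(f"unknown curation rule {rule!r}")
        self.removed_reactions.append((reaction_id, rule, justification))

    def merge(self, other: "CurationLog") -> None:
        self.removed_reactions.extend(other.removed_reactions)
        self.replaced_metabolites.extend(other.replaced_metabolites)
        self.retained_by_partner_check.extend(other.retained_by_partner_check)
        self.notices.extend(other.notices)

    @property
    def n_removed(self) -> int:
        return len(self.removed_reactions)


def _rebuild(net: MetabolicNetwork, reactions: dict[str, Reaction]) -> MetabolicNetwork:
    """New network keeping only metabolites still referenced by a reaction."""
    referenced: set[str] = set()
    for rxn in reactions.values():
        referenced.update(rxn.metabolite_ids)
    mets = {mid: met for mid, met in net.metabolites.items() if mid in referenced}
    for mid in referenced - mets.keys():
        mets[mid] = Metabolite(id=mid, name=mid)
    return MetabolicNetwork(organism=net.organism, reactions=reactions, metabolites=mets)


# ---------------------------------------------------------------------------
# Joint two-network disconnection fixpoint
# ---------------------------------------------------------------------------


def remove_disconnected_reactions(
    net_a: MetabolicNetwork,
    net_b: MetabolicNetwork,
    declared_sources: set[str] | frozenset[str],
) -> tuple[MetabolicNetwork, MetabolicNetwork, CurationLog]:
    """Remove reactions no input can ever feed, jointly over both symbionts.

    A reaction is a removal candidate when none of its substrates is a
    declared source or a product of a retained reaction of its own network.
    Before removal, a safeguard checks the partner network: if any metabolite
    of the reaction (substrate or product) is a product of the partner's
    retained reactions or a declared source, the reaction is retained and
    logged under ``retained_by_partner_check``. The net effect is that a
    reaction disappears only when no input of either symbiont's metabolism
    can ever feed it and removing it strands nothing the partner makes.
    Iterates to a fixpoint; the result is independent of removal order
    because removals only shrink the product pools (monotone).
    """
    declared = frozenset(declared_sources)
    log = CurationLog()
    retained = {
        "a": dict(net_a.reactions),
        "b": dict(net_b.reactions),
    }

    def products_of(side: str) -> frozenset[str]:
        out: set[str] = set()
        for rxn in retained[side].values():
            out.update(rxn.products)
        return frozenset(out)

    changed = True
    while changed:
        changed = False
        prod = {side: products_of(side) for side in ("a", "b")}
        for side, partner in (("a", "b"), ("b", "a")):
            own_available = declared | prod[side]
            partner_pool = prod[partner] | declared
            to_remove: list[str] = []
            for rid, rxn in retained[side].items():
                if any(s in own_available for s in rxn.substrates):
                    continue
                # partner safeguard: keep if any metabolite of the reaction
                # is a product or declared source of the partner metabolism
                if any(m in partner_pool for m in rxn.metabolite_ids):
                    if rid not in log.retained_by_partner_check:
                        log.retained_by_partner_check.append(rid)
                    continue
                to_remove.append(rid)
            for rid in to_remove:
                del retained[side][rid]
                log.record_removal(
                    rid,
                    "disconnected",
                    f"{'net_a' if side == 'a' else 'net_b'}: no substrate is a "
                    "declared source or a product of either network's retained reactions",
                )
                changed = True
    # drop safeguard entries for reactions that were removed in a later round
    log.retained_by_partner_check = [
        rid
        for rid in log.retained_by_partner_check
        if rid in retained["a"] or rid in retained["b"]
    ]
    return _rebuild(net_a, retained["a"]), _rebuild(net_b, retained["b"]), log


# ---------------------------------------------------------------------------
# Single-network rules
# ---------------------------------------------------------------------------


def filter_spontaneous(network: MetabolicNetwork) -> tuple[MetabolicNetwork, CurationLog]:
    """Keep a spontaneous reaction only if it shares at least one metabolite
    with a non-spontaneous reaction of the same network."""
    log = CurationLog()
    enzymatic_mets: set[str] = set()
    for rxn in network.reactions.values():
        if not rxn.spontaneous:
            enzymatic_mets.update(rxn.metabolite_ids)
    kept: dict[str, Reaction] = {}
    for rid, rxn in network.reactions.items():
        if rxn.spontaneous and not (rxn.metabolite_ids & enzymatic_mets):
            log.record_removal(
                rid,
                "spontaneous_unconnected",
                "spontaneous reaction shares no metabolite with any enzymatic reaction",
            )
        else:
            kept[rid] = rxn
    return _rebuild(network, kept), log


def instantiate_generic_metabolites(
    network: MetabolicNetwork,
    generic_map: dict[str, list[str]],
    declared_sources: set[str] | frozenset[str] = frozenset(),
) -> tuple[MetabolicNetwork, CurationLog]:
    """Replace compound-class placeholders ("a sugar") by specific compounds.

    Each reaction touching generic metabolites is expanded into one copy per
    combination of mapped specifics. Copies that remain disconnected — no
    substrate produced elsewhere in the network and none a declared source —
    are dropped. Reactions touching a generic id absent from ``generic_map``
    are removed under rule ``generic_unresolvable``.
    """
    for gid, specifics in generic_map.items():
        if not specifics:
            raise CurationConfigError(f"generic map entry {gid!r} maps to an empty list")
    log = CurationLog()
    generic_ids = network.generic_metabolite_ids()
    declared = frozenset(declared_sources)

    kept: dict[str, Reaction] = {}
    candidates: list[Reaction] = []  # instantiated copies pending connectivity check
    for rid, rxn in network.reactions.items():
        touched = sorted(rxn.metabolite_ids & generic_ids)
        if not touched:
            kept[rid] = rxn
            continue
        unresolved = [g for g in touched if g not in generic_map]
        if unresolved:
            log.record_removal(
                rid,
                "generic_unresolvable",
                f"generic metabolite(s) {unresolved} have no specific mapping",
            )
            continue
        combos: list[dict[str, str]] = [{}]
        for g in touched:
            combos = [dict(c, **{g: s}) for c in combos for s in generic_map[g]]
        for combo in combos:
            suffix = "__" + "_".join(combo[g] for g in touched)
            copy = replace(
                rxn,
                id=rid + suffix,
                substrates=tuple(combo.get(m, m) for m in rxn.substrates),
                products=tuple(combo.get(m, m) for m in rxn.products),
            )
            candidates.append(copy)
            for g in touched:
                log.replaced_metabolites.append((g, combo[g]))

    # connectivity check for instantiated copies: a copy stays if at least
    # one substrate is produced by a retained/other reaction or declared
    produced: set[str] = set()
    for rxn in list(kept.values()) + candidates:
        produced.update(rxn.products)
    for copy in candidates:
        if any(s in produced or s in declared for s in copy.substrates):
            kept[copy.id] = copy
        else:
            log.record_removal(
                copy.id,
                "disconnected",
                "instantiated copy has no substrate produced elsewhere and none declared a source",
            )
    net = _rebuild(network, kept)
    # carry over specific-metabolite metadata where the input declared any
    for mid in net.metabolites:
        if mid in network.metabolites:
            net.metabolites[mid] = network.metabolites[mid]
    return net, log


def apply_taxon_blocklist(
    network: MetabolicNetwork, blocklist: set[str] | frozenset[str]
) -> tuple[MetabolicNetwork, CurationLog]:
    """Remove reactions whose id or any EC number is blocklisted (reactions
    not assumed to occur in the taxon under study)."""
    block = frozenset(blocklist)
    log = CurationLog()
    kept: dict[str, Reaction] = {}
    matched: set[str] = set()
    for rid, rxn in network.reactions.items():
        hits = ({rid} | set(rxn.ec_numbers)) & block
        if hits:
            matched.update(hits)
            log.record_removal(
                rid, "taxon_blocklist", f"matched blocklist entries {sorted(hits)}"
            )
        else:
            kept[rid] = rxn
    for entry in sorted(block - matched):
        log.notices.append(f"blocklist entry {entry!r} matched no reaction")
    return _rebuild(network, kept), log


def prune_multifunctional(network: MetabolicNetwork) -> tuple[MetabolicNetwork, CurationLog]:
    """Among reactions sharing an identical (non-empty) EC set — one enzyme
    mapped to several reactions — drop those sharing no metabolite with any
    differently-labelled reaction. If every copy is disconnected, all go."""
    log = CurationLog()
    groups: dict[frozenset[str], list[str]] = {}
    for rid, rxn in network.reactions.items():
        key = frozenset(rxn.ec_numbers)
        if key:
            groups.setdefault(key, []).append(rid)

    kept = dict(network.reactions)
    for ec_set, members in groups.items():
        if len(members) < 2:
            continue
        member_set = set(members)
        other_mets: set[str] = set()
        for rid, rxn in network.reactions.items():
            if rid not in member_set:
                other_mets.update(rxn.metabolite_ids)
        for rid in members:
            rxn = network.reactions[rid]
            if not (rxn.metabolite_ids & other_mets):
                del kept[rid]
                log.record_removal(
                    rid,
                    "multifunctional_unconnected",
                    f"shares EC set {sorted(ec_set)} with {len(members) - 1} other "
                    "reaction(s) but no metabolite with the rest of the network",
                )
    return _rebuild(network, kept), log


# ---------------------------------------------------------------------------
# Full curation pass
# ---------------------------------------------------------------------------


def curate_pair(
    net_a: MetabolicNetwork,
    net_b: MetabolicNetwork,
    declared_sources: set[str] | frozenset[str] = frozenset(),
    generic_map: dict[str, list[str]] | None = None,
    blocklist: set[str] | frozenset[str] = frozenset(),
) -> tuple[MetabolicNetwork, MetabolicNetwork, CurationLog]:
    """Run the full curation pipeline on a symbiont pair.

    Stage order: reversibility split → taxon blocklist → generic
    instantiation → spontaneous filter → multifunctional pruning → joint
    disconnection fixpoint. The final disconnection pass re-establishes
    connectivity after all other removals.
    """
    from .network_io import split_reversible

    log = CurationLog()
    nets = [split_reversible(net_a), split_reversible(net_b)]
    for i in range(2):
        nets[i], sub = apply_taxon_blocklist(nets[i], blocklist)
        log.merge(sub)
        nets[i], sub = instantiate_generic_metabolites(
            nets[i], generic_map or {}, declared_sources
        )
        log.merge(sub)
        nets[i], sub = filter_spontaneous(nets[i])
        log.merge(sub)
        nets[i], sub = prune_multifunctional(nets[i])
        log.merge(sub)
    net_a2, net_b2, sub = remove_disconnected_reactions(nets[0], nets[1], declared_sources)
    log.merge(sub)
    leftover = net_a2.generic_metabolite_ids() | net_b2.generic_metabolite_ids()
    if leftover:
        raise NetworkValidationError(
            f"curated networks still contain generic metabolites: {sorted(leftover)}"
        )
    return net_a2, net_b2, log
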