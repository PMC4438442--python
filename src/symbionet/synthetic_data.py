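"""Synthetic inputs with planted, independently-computed ground truth.

Every pipeline stage gets a generator producing desk-scale data whose true
answer is known by construction, not by running the algorithm under test:

* :func:`generate_network` builds a positionally-layered reaction network.
  The first positions form the source layer — never produced by any reaction
  — so the planted seed set is exactly the set of unproduced metabolites.
  Optional extra and reversible reactions add cycles among produced
  metabolites, but never an edge into the source layer, which keeps the
  planted truth exact.
* :func:`split_holobiont` distributes one network's reactions over two
  co-resident organisms and forces a chosen number of metabolites to be
  synthesizable by exactly one organism while required by the other —
  planted cross-feeding.
* :func:`generate_pathway_case` emits gene-status matrices guaranteed to
  classify as a requested complementation kind.
* :func:`generate_feature_table` plants genome summary statistics.

The truths carried in :class:`SyntheticTruth` are computed by naive
constructions local to this module (hand-rolled reachability and
repeated-scan expansion), deliberately independent of the analysis modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .complementation import CLASSIFICATIONS
from .genome_summary import (
    Feature,
    FeatureTable,
    STANDARD_AMINO_ACIDS,
    SummaryStats,
    percent_assigned,
)
from .network_io import (
    MetabolicNetwork,
    Metabolite,
    Reaction,
    network_from_reactions,
)


class SyntheticConfigError(ValueError):
    """Requested synthetic-data parameters are infeasible."""


@dataclass
class SyntheticTruth:
    """Planted ground truth emitted alongside generated data."""

    planted_seeds: frozenset[str] = frozenset()
    planted_scope: frozenset[str] = frozenset()
    cross_fed: list[tuple[str, str, str]] = field(default_factory=list)
    pathway_classification: dict[str, str] = field(default_factory=dict)
    feature_stats: SummaryStats | None = None

    def to_dict(self) -> dict:
        return {
            "planted_seeds": sorted(self.planted_seeds),
            "planted_scope": sorted(self.planted_scope),
            "cross_fed": [list(t) for t in self.cross_fed],
            "pathway_classification": dict(self.pathway_classification),
            "feature_stats": vars(self.feature_stats) if self.feature_stats else None,
        }


# ---------------------------------------------------------------------------
# Independent naive oracles (kept free of seed_scope / networkx on purpose)
# ---------------------------------------------------------------------------


def naive_scope(reactions: list[Reaction], sources: frozenset[str]) -> frozenset[str]:
    """Repeated full re-scan network expansion (AND firing semantics).
    Reversible reactions are scanned in both directions."""
    directed: list[tuple[tuple[str, ...], tuple[str, ...]]] = []
    for r in reactions:
        directed.append((r.substrates, r.products))
        if r.reversible:
            directed.append((r.products, r.substrates))
    producible = set(sources)
    changed = True
    while changed:
        changed = False
        for subs, prods in directed:
            if all(s in producible for s in subs) and not set(prods) <= producible:
                producible.update(prods)
                changed = True
    return frozenset(producible)


def naive_seed_members(reactions: list[Reaction], metabolites: frozenset[str]) -> frozenset[str]:
    """Brute-force seed detection on the compound graph by transitive
    closure: a metabolite is a seed member iff every node that reaches it is
    also reached by it (no strictly-upstream producer)."""
    adj: dict[str, set[str]] = {m: set() for m in metabolites}
    for r in reactions:
        pairs = [(r.substrates, r.products)]
        if r.reversible:
            pairs.append((r.products, r.substrates))
        for subs, prods in pairs:
            for s in subs:
                adj[s].update(prods)

    def reachable(start: str) -> set[str]:
        seen = {start}
        stack = [start]
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        return seen

    reach = {m: reachable(m) for m in metabolites}
    seeds = set()
    for m in metabolites:
        upstream = [u for u in metabolites if u != m and m in reach[u]]
        if all(u in reach[m] for u in upstream):
            seeds.add(m)
    return frozenset(seeds)


# ---------------------------------------------------------------------------
# Network generator
# ---------------------------------------------------------------------------


def _met_id(i: int) -> str:
    return f"M{i:03d}"


def generate_network(
    n_metabolites: int,
    n_reactions: int,
    max_substrates: int = 2,
    max_products: int = 2,
    p_reversible: float = 0.0,
    rng_seed: int = 0,
    n_sources: int | None = None,
) -> tuple[MetabolicNetwork, SyntheticTruth]:
    """Generate a reaction network with an exactly known seed set.

    Metabolites occupy positions 0..n-1; the first ``n_sources`` positions
    are the source layer. Each remaining metabolite, while reactions last,
    receives a backbone producing reaction whose substrates sit at strictly
    lower positions; surplus reactions connect arbitrary substrates to
    non-source products. Reactions are flagged reversible (probability
    ``p_reversible``) only when no substrate is a source, so no construction
    step ever directs an edge into the source layer. The planted seed set is
    therefore exactly the set of never-produced metabolites; the planted
    scope is computed by the naive re-scan oracle.
    """
    if n_metabolites <= 0 or n_reactions < 0:
        raise SyntheticConfigError("counts must be positive")
    if max_substrates < 1 or max_products < 1:
        raise SyntheticConfigError("max_substrates and max_products must be >= 1")
    if n_metabolites < max_substrates + max_products:
        raise SyntheticConfigError(
            "need n_metabolites >= max_substrates + max_products"
        )
    rng = np.random.default_rng(rng_seed)
    if n_sources is None:
        n_sources = max(max_substrates, -(-n_metabolites // 5))
    if not 1 <= n_sources < n_metabolites and n_reactions > 0:
        raise SyntheticConfigError("n_sources must be in [1, n_metabolites)")

    mets = [_met_id(i) for i in range(n_metabolites)]
    source_set = frozenset(mets[:n_sources])
    reactions: list[Reaction] = []

    # backbone: one producing reaction per non-source metabolite
    n_backbone = min(n_reactions, n_metabolites - n_sources)
    for j in range(n_backbone):
        k = n_sources + j
        n_sub = int(rng.integers(1, min(max_substrates, k) + 1))
        subs = rng.choice(k, size=n_sub, replace=False)
        if j < n_sources:
            # make sure every source is consumed somewhere, so the network
            # has no isolated nodes once the backbone is complete
            subs = np.unique(np.append(subs[: n_sub - 1], j))
        reactions.append(
            Reaction(
                id=f"R{len(reactions):03d}",
                substrates=tuple(mets[i] for i in sorted(subs)),
                products=(mets[k],),
                ec_numbers=(f"1.1.1.{len(reactions) + 1}",),
            )
        )

    # surplus reactions: arbitrary substrates, non-source products
    produced_positions = list(range(n_sources, n_sources + n_backbone))
    while len(reactions) < n_reactions and produced_positions:
        n_sub = int(rng.integers(1, max_substrates + 1))
        subs = set(int(x) for x in rng.choice(n_sources + n_backbone, size=n_sub, replace=False))
        n_prod = int(rng.integers(1, max_products + 1))
        prod_pool = [p for p in produced_positions if p not in subs]
        if not prod_pool:
            continue
        prods = rng.choice(len(prod_pool), size=min(n_prod, len(prod_pool)), replace=False)
        reactions.append(
            Reaction(
                id=f"R{len(reactions):03d}",
                substrates=tuple(mets[i] for i in sorted(subs)),
                products=tuple(mets[prod_pool[i]] for i in sorted(int(p) for p in prods)),
                ec_numbers=(f"1.1.1.{len(reactions) + 1}",),
            )
        )

    # reversibility: only where no substrate is a source
    if p_reversible > 0:
        flips = rng.random(len(reactions))
        for i, rxn in enumerate(reactions):
            if flips[i] < p_reversible and not (set(rxn.substrates) & source_set):
                reactions[i] = Reaction(
                    id=rxn.id,
                    substrates=rxn.substrates,
                    products=rxn.products,
                    ec_numbers=rxn.ec_numbers,
                    reversible=True,
                )

    net = network_from_reactions("synthetic", reactions)
    for mid in mets:
        net.metabolites.setdefault(mid, Metabolite(mid, mid))

    produced: set[str] = set()
    for r in reactions:
        produced.update(r.products)
        if r.reversible:
            produced.update(r.substrates)
    planted_seeds = frozenset(m for m in mets if m not in produced)
    planted_scope = naive_scope(reactions, planted_seeds)
    truth = SyntheticTruth(planted_seeds=planted_seeds, planted_scope=planted_scope)
    return net, truth


# ---------------------------------------------------------------------------
# Holobiont split with planted cross-feeding
# ---------------------------------------------------------------------------


def _produced_by(reactions: list[Reaction]) -> frozenset[str]:
    out: set[str] = set()
    for r in reactions:
        out.update(r.products)
        if r.reversible:
            out.update(r.substrates)
    return frozenset(out)


def split_holobiont(
    network: MetabolicNetwork,
    p_assign_a: float,
    n_forced_crossfeed: int,
    rng_seed: int = 0,
    organism_a: str = "A",
    organism_b: str = "B",
) -> tuple[MetabolicNetwork, MetabolicNetwork, SyntheticTruth]:
    """Split one network's reactions over two organisms with planted
    cross-feeding.

    Each reaction goes to organism A with probability ``p_assign_a``. Then
    ``n_forced_crossfeed`` metabolites are enforced to be synthesizable by
    exactly one organism (all reactions touching them as a product pinned to
    the provider, with one producer whose substrates are global seeds) while
    an irreversible consumer is pinned to the other. The emitted truth lists
    *every* actually cross-fed metabolite — computed by the naive oracles —
    in both directions, so recovery tests can demand exact set equality.
    """
    rng = np.random.default_rng(rng_seed)
    rxns = [network.reactions[rid] for rid in sorted(network.reactions)]
    draws = rng.random(len(rxns))
    assign: dict[str, str] = {
        r.id: (organism_a if draws[i] < p_assign_a else organism_b)
        for i, r in enumerate(rxns)
    }
    pinned: set[str] = set()

    global_produced = _produced_by(rxns)
    global_seeds = frozenset(network.metabolites) - global_produced

    def producers_of(m: str) -> list[Reaction]:
        # any reaction able to emit m in some direction
        return [
            r
            for r in rxns
            if m in r.products or (r.reversible and m in r.substrates)
        ]

    def irreversible_consumers_of(m: str) -> list[Reaction]:
        return [r for r in rxns if not r.reversible and m in r.substrates]

    # eligible: produced, with a producer fed purely by global seeds, and an
    # irreversible consumer distinct from every producer
    eligible: list[str] = []
    for m in sorted(global_produced):
        prods = producers_of(m)
        if not any(set(p.substrates) <= global_seeds and m in p.products for p in prods):
            continue
        prod_ids = {p.id for p in prods}
        if any(c.id not in prod_ids for c in irreversible_consumers_of(m)):
            eligible.append(m)
    if n_forced_crossfeed > len(eligible):
        raise SyntheticConfigError(
            f"cannot force {n_forced_crossfeed} cross-fed metabolites; "
            f"only {len(eligible)} eligible"
        )

    order = [eligible[i] for i in rng.permutation(len(eligible))]
    forced: list[tuple[str, str, str]] = []
    for m in order:
        if len(forced) == n_forced_crossfeed:
            break
        first = (
            (organism_a, organism_b) if rng.random() < 0.5 else (organism_b, organism_a)
        )
        prods = producers_of(m)
        prod_ids = {p.id for p in prods}
        all_consumers = [
            c for c in irreversible_consumers_of(m) if c.id not in prod_ids
        ]
        # an earlier pin is a conflict only if it points the wrong way
        for provider, needer in (first, first[::-1]):
            if any(p.id in pinned and assign[p.id] != provider for p in prods):
                continue
            consumers = [
                c
                for c in all_consumers
                if not (c.id in pinned and assign[c.id] != needer)
            ]
            if not consumers:
                continue
            for p in prods:
                assign[p.id] = provider
                pinned.add(p.id)
            assign[consumers[0].id] = needer
            pinned.add(consumers[0].id)
            forced.append((m, needer, provider))
            break
    if len(forced) < n_forced_crossfeed:
        raise SyntheticConfigError(
            "pinning conflicts prevented forcing the requested cross-feeding"
        )

    def subnet(org: str) -> MetabolicNetwork:
        sub = [r for r in rxns if assign[r.id] == org]
        net = network_from_reactions(org, sub)
        for mid in net.metabolites:
            if mid in network.metabolites:
                net.metabolites[mid] = network.metabolites[mid]
        return net

    net_a, net_b = subnet(organism_a), subnet(organism_b)

    # truth: all actual cross-feeding, by the independent naive oracles
    cross_fed: list[tuple[str, str, str]] = []
    for needer_net, provider_net in ((net_a, net_b), (net_b, net_a)):
        needer_rxns = list(needer_net.reactions.values())
        provider_rxns = list(provider_net.reactions.values())
        needer_seeds = naive_seed_members(needer_rxns, frozenset(needer_net.metabolites))
        provider_seeds = naive_seed_members(
            provider_rxns, frozenset(provider_net.metabolites)
        )
        provider_synth = (
            naive_scope(provider_rxns, provider_seeds) - provider_seeds
        )
        for m in sorted(needer_seeds & provider_synth):
            cross_fed.append((m, needer_net.organism, provider_net.organism))

    missing = {(m, n, p) for m, n, p in forced} - set(cross_fed)
    if missing:  # should be impossible by construction
        raise SyntheticConfigError(f"forced cross-feeding not realised: {missing}")
    return net_a, net_b, SyntheticTruth(cross_fed=cross_fed)


# ---------------------------------------------------------------------------
# Pathway-case generator
# ---------------------------------------------------------------------------


def generate_pathway_case(
    kind: str, n_genes: int, rng_seed: int = 0
) -> tuple[list[str], dict[str, str], dict[str, str], frozenset[str], str]:
    """Emit (genes, statuses_A, statuses_B, host_evidence, expected_label)
    guaranteed to classify as ``kind`` under the pathway decision table."""
    if kind not in CLASSIFICATIONS:
        raise SyntheticConfigError(f"unknown pathway classification {kind!r}")
    if n_genes < 2:
        raise SyntheticConfigError("n_genes must be >= 2")
    rng = np.random.default_rng(rng_seed)
    genes = [f"g{i:02d}" for i in range(n_genes)]

    def broken() -> str:
        return "pseudogene" if rng.random() < 0.3 else "absent"

    a = {g: "intact" for g in genes}
    b = {g: "intact" for g in genes}
    host: frozenset[str] = frozenset()

    if kind == "redundant":
        pass
    elif kind == "complete_in_A":
        b = {g: broken() for g in genes}
    elif kind == "complete_in_B":
        a = {g: broken() for g in genes}
    elif kind == "one_way_complementation":
        k = int(rng.integers(1, n_genes))  # proper nonempty subset
        idx = rng.choice(n_genes, size=k, replace=False)
        target = a if rng.random() < 0.5 else b
        for i in idx:
            target[genes[int(i)]] = broken()
    elif kind == "reciprocal_complementation":
        perm = rng.permutation(n_genes)
        ka = int(rng.integers(1, n_genes))
        kb = int(rng.integers(1, n_genes - ka + 1))
        for i in perm[:ka]:
            a[genes[int(i)]] = broken()
        for i in perm[ka : ka + kb]:
            b[genes[int(i)]] = broken()
    elif kind in ("host_complemented", "holobiont_gap"):
        k = int(rng.integers(1, n_genes + 1))
        idx = rng.choice(n_genes, size=k, replace=False)
        for i in idx:
            a[genes[int(i)]] = broken()
            b[genes[int(i)]] = broken()
        if kind == "host_complemented":
            host = frozenset(genes[int(i)] for i in idx)
    return genes, a, b, host, kind


# ---------------------------------------------------------------------------
# Feature-table generator
# ---------------------------------------------------------------------------


def generate_feature_table(
    n_cds: int,
    n_trna_per_aa: dict[str, int],
    genome_length: int,
    rng_seed: int = 0,
    p_assigned: float = 0.85,
    genome: str = "synthetic",
) -> tuple[FeatureTable, SyntheticTruth]:
    """Place non-overlapping CDS and tRNA features and record the exact
    summary statistics as truth (density is analytic because nothing
    overlaps)."""
    rng = np.random.default_rng(rng_seed)
    cds_lengths = [int(x) for x in rng.integers(300, 1500, size=n_cds)]
    trna_specs: list[tuple[str, str]] = []
    anticodon_pool = ["TGC", "GCA", "GTT", "CAT", "TGA", "GAA", "TTT", "GTG"]
    for aa, count in sorted(n_trna_per_aa.items()):
        for _ in range(count):
            trna_specs.append((aa, anticodon_pool[int(rng.integers(0, len(anticodon_pool)))]))
    lengths = cds_lengths + [75] * len(trna_specs)
    if sum(lengths) + len(lengths) > genome_length:
        raise SyntheticConfigError("features do not fit within genome_length")

    slack = genome_length - sum(lengths)
    n_feat = len(lengths)
    gaps = rng.multinomial(slack, np.ones(n_feat + 1) / (n_feat + 1)) if n_feat else [0]
    features: list[Feature] = []
    pos = 1
    assigned_draws = rng.random(n_cds)
    for i, length in enumerate(lengths):
        pos += int(gaps[i])
        start, end = pos, pos + length - 1
        if i < n_cds:
            features.append(
                Feature(
                    id=f"F{i:04d}",
                    type="CDS",
                    start=start,
                    end=end,
                    strand="+" if rng.random() < 0.5 else "-",
                    assigned_function=bool(assigned_draws[i] < p_assigned),
                )
            )
        else:
            aa, anticodon = trna_specs[i - n_cds]
            features.append(
                Feature(
                    id=f"F{i:04d}",
                    type="tRNA",
                    start=start,
                    end=end,
                    amino_acid=aa,
                    anticodon=anticodon,
                )
            )
        pos = end + 1

    table = FeatureTable(genome=genome, features=features, genome_length=genome_length)
    n_assigned = sum(1 for f in features if f.type == "CDS" and f.assigned_function)
    from decimal import ROUND_HALF_UP, Decimal

    mean_len = (
        float(
            (Decimal(sum(cds_lengths)) / Decimal(n_cds)).quantize(
                Decimal(1), rounding=ROUND_HALF_UP
            )
        )
        if n_cds
        else 0.0
    )
    stats = SummaryStats(
        n_genes=n_cds,
        n_assigned=n_assigned,
        pct_assigned=percent_assigned(n_cds, n_assigned, 2, "half_up") if n_cds else 0.0,
        coding_density_pct=100.0 * sum(cds_lengths) / genome_length,
        mean_gene_length=mean_len,
        n_trna=len(trna_specs),
        n_rrna=0,
    )
    return table, SyntheticTruth(feature_stats=stats)
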