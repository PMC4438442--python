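"""Seed-metabolite detection and producibility scopes.

Two complementary producibility semantics live here, and they are kept
strictly apart:

* **Seed detection** works on the *compound graph* — a directed graph with an
  edge from every reaction substrate to every product — and asks which
  metabolites must be acquired from the environment. A metabolite is a seed
  member iff its strongly connected component has no incoming edge in the SCC
  condensation; every member of such a source component receives confidence
  ``1/|component|`` (any one member would make the rest reachable). This is
  single-substrate (OR) reachability.

* **Scope / network expansion** asks what a given source set can actually
  make: a reaction fires only when *all* of its substrates are available
  (AND semantics), and firing adds its products; iterate to a fixpoint.

Seeds answer "what must come in"; scope answers "what comes out". The two
are never conflated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

from .network_io import MetabolicNetwork

logger = logging.getLogger(__name__)

#: Optional currency-metabolite blocklist for compound-graph construction.
#: Disabled by default: bicarbonate (HCO3) is a genuine environmental source
#: in reduced endosymbiont metabolisms, so excluding currency compounds must
#: be an explicit opt-in.
DEFAULT_CURRENCY_METABOLITES = frozenset(
    {
        "WATER",
        "PROTON",
        "ATP",
        "ADP",
        "Pi",
        "PPi",
        "NAD",
        "NADH",
        "NADP",
        "NADPH",
        "CO2",
    }
)


@dataclass
class CompoundGraph:
    """Directed metabolite graph: substrate → product, one edge per distinct
    (substrate, product) pair carrying the ids of all originating reactions."""

    graph: nx.DiGraph
    excluded: frozenset[str] = frozenset()

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_reactions(self, substrate: str, product: str) -> frozenset[str]:
        return frozenset(self.graph.edges[substrate, product]["reactions"])


@dataclass
class SeedReport:
    """Detected source metabolites with SCC-derived confidences.

    Each seed belongs to a source component (an SCC with no incoming
    condensation edge); its confidence is ``1/|component|``, so confidences
    within one component are equal and sum to 1.
    """

    organism: str
    seeds: list[tuple[str, int, float]] = field(default_factory=list)
    components: dict[int, frozenset[str]] = field(default_factory=dict)

    @property
    def seed_ids(self) -> frozenset[str]:
        return frozenset(mid for mid, _, _ in self.seeds)

    def filtered(self, min_confidence: float) -> "SeedReport":
        keep = [(m, c, conf) for m, c, conf in self.seeds if conf >= min_confidence]
        comp_ids = {c for _, c, _ in keep}
        return SeedReport(
            organism=self.organism,
            seeds=keep,
            components={c: v for c, v in self.components.items() if c in comp_ids},
        )


@dataclass
class ScopeResult:
    """Fixpoint of network expansion from a source set."""

    sources: frozenset[str]
    producible: frozenset[str]
    fired_reactions: list[str] = field(default_factory=list)

    @property
    def synthesized(self) -> frozenset[str]:
        """Metabolites actually made by the network (producible minus the
        sources themselves)."""
        return self.producible - self.sources


def build_compound_graph(
    network: MetabolicNetwork,
    currency_blocklist: set[str] | frozenset[str] = frozenset(),
) -> CompoundGraph:
    """Build the substrate→product graph of a (reversibility-split, curated)
    network. Blocklisted currency metabolites contribute neither nodes nor
    edges; parallel edges from distinct reactions collapse into one edge
    annotated with every originating reaction id."""
    block = frozenset(currency_blocklist)
    g = nx.DiGraph()
    for mid in network.metabolites:
        if mid not in block:
            g.add_node(mid)
    for rxn in network.reactions.values():
        for s in rxn.substrates:
            if s in block:
                continue
            for p in rxn.products:
                if p in block:
                    continue
                if g.has_edge(s, p):
                    g.edges[s, p]["reactions"].add(rxn.id)
                else:
                    g.add_edge(s, p, reactions={rxn.id})
    return CompoundGraph(graph=g, excluded=block & frozenset(network.metabolites))


def detect_seeds(graph: CompoundGraph, organism: str = "") -> SeedReport:
    """Detect seed metabolites by SCC condensation.

    Every metabolite in a strongly connected component with zero incoming
    condensation edges is a seed with confidence ``1/|component|``. Isolated
    nodes form size-1 source components with confidence 1. Output ordering is
    deterministic: confidence descending, then metabolite id ascending.
    """
    g = graph.graph
    if g.number_of_nodes() == 0:
        return SeedReport(organism=organism)
    condensation = nx.condensation(g)
    seeds: list[tuple[str, int, float]] = []
    components: dict[int, frozenset[str]] = {}
    for comp_id in condensation.nodes:
        if condensation.in_degree(comp_id) > 0:
            continue
        members = frozenset(condensation.nodes[comp_id]["members"])
        components[comp_id] = members
        conf = 1.0 / len(members)
        for mid in members:
            seeds.append((mid, comp_id, conf))
    seeds.sort(key=lambda t: (-t[2], t[0]))
    return SeedReport(organism=organism, seeds=seeds, components=components)


def scope(
    network: MetabolicNetwork, sources: set[str] | frozenset[str]
) -> ScopeResult:
    """Network expansion: iterate "fire every reaction whose substrates are
    all available" to a fixpoint. Deterministic regardless of iteration
    order; source ids absent from the network are logged and ignored."""
    known = frozenset(network.metabolites)
    src = frozenset(sources)
    unknown = src - known
    if unknown:
        logger.warning(
            "scope: ignoring %d source id(s) not in network %s: %s",
            len(unknown),
            network.organism,
            sorted(unknown)[:10],
        )
    src &= known

    producible: set[str] = set(src)
    fired: list[str] = []
    unfired = dict(network.reactions)
    changed = True
    while changed:
        changed = False
        # scan in sorted id order so fired_reactions is deterministic
        for rid in sorted(unfired):
            rxn = unfired[rid]
            if all(s in producible for s in rxn.substrates):
                producible.update(rxn.products)
                fired.append(rid)
                del unfired[rid]
                changed = True
    return ScopeResult(sources=src, producible=frozenset(producible), fired_reactions=fired)


def producible_count(result: ScopeResult, include_sources: bool = True) -> int:
    """Size of the producible set, with or without the sources themselves —
    both conventions are reported because published counts rarely say which
    they use."""
    if include_sources:
        return len(result.producible)
    return len(result.producible - result.sources)


def write_seed_report(report: SeedReport, path) -> None:
    """SeedReport as TSV: metabolite_id, component_id, component_size,
    confidence."""
    with open(str(path), "w", encoding="utf-8") as fh:
        fh.write("metabolite_id\tcomponent_id\tcomponent_size\tconfidence\n")
        for mid, comp, conf in report.seeds:
            size = len(report.components[comp])
            fh.write(f"{mid}\t{comp}\t{size}\t{conf:.6g}\n")


def read_seed_ids(path) -> frozenset[str]:
    """Read metabolite ids from a seed-report TSV or a one-id-per-line list."""
    ids: set[str] = set()
    with open(str(path), encoding="utf-8") as fh:
        first = True
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tok = line.split("\t")[0]
            if first and tok == "metabolite_id":
                first = False
                continue
            first = False
            ids.add(tok)
    return frozenset(ids)


def write_scope_result(result: ScopeResult, path) -> None:
    with open(str(path), "w", encoding="utf-8") as fh:
        fh.write("metabolite_id\tis_source\n")
        for mid in sorted(result.producible):
            fh.write(f"{mid}\t{1 if mid in result.sources else 0}\n")
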