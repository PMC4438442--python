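"""Domain types for metabolites, reactions and metabolic networks, plus
readers/writers for the tabular exchange formats the pipeline consumes.

A :class:`MetabolicNetwork` is the substrate of every downstream stage:
curation, seed (source) detection, and producibility-scope computation.
Metabolite identity is exact, case-sensitive string match — the identifiers
come from a curated reconstruction, and silent synonym merging would be worse
than an occasional duplicate node.

Reversible reactions are handled by explicit splitting
(:func:`split_reversible`) before any graph construction, because both the
seed-detection and scope algorithms are defined on directed structures.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

logger = logging.getLogger(__name__)

TSV_COLUMNS = [
    "reaction_id",
    "ec",
    "substrates",
    "products",
    "reversible",
    "spontaneous",
    "generic_metabolites",
]

LIST_SEP = ";"


class NetworkFormatError(ValueError):
    """A reaction table violates the exchange-format contract."""


class NetworkValidationError(ValueError):
    """A network object violates a structural invariant."""


@dataclass(frozen=True)
class Metabolite:
    """A compound node. ``is_generic`` marks compound-class placeholders
    such as "a sugar" that curation must instantiate or remove."""

    id: str
    name: str = ""
    is_generic: bool = False
    compound_class: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise NetworkValidationError("metabolite id must be non-empty")


@dataclass(frozen=True)
class Reaction:
    """A directed (or reversible) transformation of substrates to products.

    Substrate and product lists are metabolite ids; both must be non-empty,
    and no id may appear on both sides of one directed reaction.
    """

    id: str
    substrates: tuple[str, ...]
    products: tuple[str, ...]
    ec_numbers: tuple[str, ...] = ()
    reversible: bool = False
    spontaneous: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise NetworkValidationError("reaction id must be non-empty")
        if not self.substrates:
            raise NetworkValidationError(f"reaction {self.id}: empty substrate list")
        if not self.products:
            raise NetworkValidationError(f"reaction {self.id}: empty product list")
        overlap = set(self.substrates) & set(self.products)
        if overlap:
            raise NetworkValidationError(
                f"reaction {self.id}: metabolites on both sides: {sorted(overlap)}"
            )

    @property
    def metabolite_ids(self) -> frozenset[str]:
        return frozenset(self.substrates) | frozenset(self.products)


@dataclass
class MetabolicNetwork:
    """An organism's reaction set with a metabolite index keyed by id."""

    organism: str
    reactions: dict[str, Reaction] = field(default_factory=dict)
    metabolites: dict[str, Metabolite] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for rid, rxn in self.reactions.items():
            if rid != rxn.id:
                raise NetworkValidationError(
                    f"reaction keyed as {rid!r} but carries id {rxn.id!r}"
                )
            missing = rxn.metabolite_ids - self.metabolites.keys()
            if missing:
                raise NetworkValidationError(
                    f"reaction {rid} references unindexed metabolites: {sorted(missing)}"
                )

    # -- convenience views ------------------------------------------------

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def metabolite_ids(self) -> frozenset[str]:
        return frozenset(self.metabolites)

    def produced_metabolites(self) -> frozenset[str]:
        """Ids appearing as a product of at least one reaction (reversible
        reactions contribute both sides)."""
        out: set[str] = set()
        for rxn in self.reactions.values():
            out.update(rxn.products)
            if rxn.reversible:
                out.update(rxn.substrates)
        return frozenset(out)

    def generic_metabolite_ids(self) -> frozenset[str]:
        return frozenset(m.id for m in self.metabolites.values() if m.is_generic)

    def copy(self) -> "MetabolicNetwork":
        return MetabolicNetwork(
            organism=self.organism,
            reactions=dict(self.reactions),
            metabolites=dict(self.metabolites),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MetabolicNetwork):
            return NotImplemented
        return (
            self.organism == other.organism
            and self.reactions == other.reactions
            and self.metabolites == other.metabolites
        )


def network_from_reactions(
    organism: str,
    reactions: list[Reaction] | tuple[Reaction, ...],
    metabolites: dict[str, Metabolite] | None = None,
) -> MetabolicNetwork:
    """Build a network, synthesising index entries for any referenced
    metabolite id that has no explicit :class:`Metabolite` record."""
    rxn_index: dict[str, Reaction] = {}
    for rxn in reactions:
        if rxn.id in rxn_index:
            raise NetworkValidationError(f"duplicate reaction id {rxn.id!r}")
        rxn_index[rxn.id] = rxn
    met_index: dict[str, Metabolite] = dict(metabolites or {})
    for rxn in rxn_index.values():
        for mid in rxn.metabolite_ids:
            met_index.setdefault(mid, Metabolite(id=mid, name=mid))
    return MetabolicNetwork(organism=organism, reactions=rxn_index, metabolites=met_index)


# ---------------------------------------------------------------------------
# Tabular I/O
#
# TSV dialect: tab-separated, UTF-8, "#" comment lines skipped, ";" separates
# items inside a list cell. Rows are sorted by reaction id on output so diffs
# are reproducible.
# ---------------------------------------------------------------------------


def _parse_list_cell(cell: str, *, field_name: str, line_no: int) -> tuple[str, ...]:
    cell = cell.strip()
    if not cell:
        return ()
    items = cell.split(LIST_SEP)
    for tok in items:
        if not tok.strip():
            raise NetworkFormatError(
                f"line {line_no}: empty token in {field_name} cell {cell!r}"
            )
    return tuple(tok.strip() for tok in items)


def _parse_bool(cell: str, *, field_name: str, line_no: int) -> bool:
    val = cell.strip().lower()
    if val in {"1", "true", "yes"}:
        return True
    if val in {"0", "false", "no", ""}:
        return False
    raise NetworkFormatError(f"line {line_no}: bad boolean {cell!r} in {field_name}")


def read_reaction_table(path, format: str = "tsv", organism: str | None = None) -> MetabolicNetwork:
    """Parse a reaction table into a validated :class:`MetabolicNetwork`.

    Unknown columns are ignored with a logged warning; a missing required
    column, an empty substrate/product cell or a duplicate reaction id is an
    error naming the offender.
    """
    path = str(path)
    if organism is None:
        import os

        organism = os.path.splitext(os.path.basename(path))[0]
    if format == "json":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        return _network_from_dict(doc, default_organism=organism)
    if format != "tsv":
        raise ValueError(f"unknown format {format!r}")

    reactions: list[Reaction] = []
    generic_ids: set[str] = set()
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        header: list[str] | None = None
        n_data = 0
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cells = line.split("\t")
            if header is None:
                header = [c.strip() for c in cells]
                missing = [c for c in TSV_COLUMNS if c not in header]
                if missing:
                    raise NetworkFormatError(
                        f"{path}: missing required column(s): {', '.join(missing)}"
                    )
                extra = [c for c in header if c not in TSV_COLUMNS]
                if extra:
                    logger.warning("%s: ignoring unknown column(s): %s", path, extra)
                continue
            row = dict(zip(header, cells))
            rid = row.get("reaction_id", "").strip()
            if not rid:
                raise NetworkFormatError(f"line {line_no}: empty reaction_id")
            if rid in seen:
                raise NetworkFormatError(f"line {line_no}: duplicate reaction_id {rid!r}")
            seen.add(rid)
            substrates = _parse_list_cell(
                row.get("substrates", ""), field_name="substrates", line_no=line_no
            )
            products = _parse_list_cell(
                row.get("products", ""), field_name="products", line_no=line_no
            )
            if not substrates:
                raise NetworkFormatError(f"line {line_no}: empty substrates cell")
            if not products:
                raise NetworkFormatError(f"line {line_no}: empty products cell")
            ec = _parse_list_cell(row.get("ec", ""), field_name="ec", line_no=line_no)
            reactions.append(
                Reaction(
                    id=rid,
                    substrates=substrates,
                    products=products,
                    ec_numbers=ec,
                    reversible=_parse_bool(
                        row.get("reversible", ""), field_name="reversible", line_no=line_no
                    ),
                    spontaneous=_parse_bool(
                        row.get("spontaneous", ""), field_name="spontaneous", line_no=line_no
                    ),
                )
            )
            generic_ids.update(
                _parse_list_cell(
                    row.get("generic_metabolites", ""),
                    field_name="generic_metabolites",
                    line_no=line_no,
                )
            )
            n_data += 1
    if header is None:
        raise NetworkFormatError(f"{path}: no header line found")
    if n_data == 0:
        logger.warning("%s: reaction table has no data rows", path)
    metabolites = {
        mid: Metabolite(id=mid, name=mid, is_generic=mid in generic_ids)
        for rxn in reactions
        for mid in rxn.metabolite_ids
    }
    return MetabolicNetwork(
        organism=organism,
        reactions={r.id: r for r in reactions},
        metabolites=metabolites,
    )


def _network_from_dict(doc: dict, default_organism: str) -> MetabolicNetwork:
    mets = {
        m["id"]: Metabolite(
            id=m["id"],
            name=m.get("name", m["id"]),
            is_generic=bool(m.get("is_generic", False)),
            compound_class=m.get("compound_class"),
        )
        for m in doc.get("metabolites", [])
    }
    rxns: list[Reaction] = []
    for r in doc.get("reactions", []):
        rxns.append(
            Reaction(
                id=r["id"],
                substrates=tuple(r["substrates"]),
                products=tuple(r["products"]),
                ec_numbers=tuple(r.get("ec_numbers", ())),
                reversible=bool(r.get("reversible", False)),
                spontaneous=bool(r.get("spontaneous", False)),
            )
        )
    return network_from_reactions(doc.get("organism", default_organism), rxns, mets)


def _network_to_dict(network: MetabolicNetwork) -> dict:
    return {
        "organism": network.organism,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "is_generic": m.is_generic,
                "compound_class": m.compound_class,
            }
            for m in sorted(network.metabolites.values(), key=lambda m: m.id)
        ],
        "reactions": [
            {
                "id": r.id,
                "substrates": list(r.substrates),
                "products": list(r.products),
                "ec_numbers": list(r.ec_numbers),
                "reversible": r.reversible,
                "spontaneous": r.spontaneous,
            }
            for r in sorted(network.reactions.values(), key=lambda r: r.id)
        ],
    }


def write_network(network: MetabolicNetwork, path, format: str = "tsv") -> None:
    """Emit a reaction table that :func:`read_reaction_table` parses back to
    an equal network. Rows sorted by reaction id for reproducible diffs."""
    path = str(path)
    if format == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(_network_to_dict(network), fh, indent=1, sort_keys=True)
            fh.write("\n")
        return
    if format != "tsv":
        raise ValueError(f"unknown format {format!r}")
    generic = network.generic_metabolite_ids()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for rxn in sorted(network.reactions.values(), key=lambda r: r.id):
            row_generic = sorted(rxn.metabolite_ids & generic)
            fh.write(
                "\t".join(
                    [
                        rxn.id,
                        LIST_SEP.join(rxn.ec_numbers),
                        LIST_SEP.join(rxn.substrates),
                        LIST_SEP.join(rxn.products),
                        "1" if rxn.reversible else "0",
                        "1" if rxn.spontaneous else "0",
                        LIST_SEP.join(row_generic),
                    ]
                )
                + "\n"
            )


def write_edge_list(network: MetabolicNetwork, path) -> None:
    """Export substrate→product pairs (one row per pair per reaction) for
    external graph viewers."""
    with open(str(path), "w", encoding="utf-8") as fh:
        fh.write("substrate\tproduct\treaction_id\n")
        for rxn in sorted(network.reactions.values(), key=lambda r: r.id):
            for s in rxn.substrates:
                for p in rxn.products:
                    fh.write(f"{s}\t{p}\t{rxn.id}\n")


# ---------------------------------------------------------------------------
# Reversibility splitting
# ---------------------------------------------------------------------------


def split_reversible(network: MetabolicNetwork) -> MetabolicNetwork:
    """Replace every reversible reaction by two irreversible ones suffixed
    ``_fwd``/``_rev``. Idempotent; irreversible reactions pass through
    untouched and the input network is never modified."""
    out: dict[str, Reaction] = {}
    for rxn in network.reactions.values():
        if not rxn.reversible:
            out[rxn.id] = rxn
            continue
        fwd = replace(rxn, id=rxn.id + "_fwd", reversible=False)
        rev = replace(
            rxn,
            id=rxn.id + "_rev",
            substrates=rxn.products,
            products=rxn.substrates,
            reversible=False,
        )
        out[fwd.id] = fwd
        out[rev.id] = rev
    return MetabolicNetwork(
        organism=network.organism, reactions=out, metabolites=dict(network.metabolites)
    )
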