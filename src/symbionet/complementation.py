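"""Metabolic complementation inference at two levels.

**Source level** — each seed metabolite an organism must import is assigned a
provenance in strict priority order: *partner* (the co-resident symbiont
synthesizes it from its own seeds), *host* (on a user-supplied whitelist of
host-provided compounds, with a compartment tag such as "mitochondria"), or
*diet_or_unknown*. The priority resolves ties toward partner, surfacing
candidate cross-feeding for review.

**Pathway level** — a biosynthetic pathway's genes are scored intact /
pseudogene / absent in each of two genomes; a deterministic decision table
classifies the pathway as complete in one genome, redundant, reciprocally or
one-way complemented between the genomes, complemented by the host (gene
missing in both genomes but present in host transcriptome evidence), or a
holobiont-level gap. A gene reduced by more than 20% in length relative to
its orthologs is called a pseudogene and treated as non-functional.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from statistics import median

from .network_io import MetabolicNetwork
from .seed_scope import ScopeResult, SeedReport, scope

PROVENANCES = ("partner", "host", "diet_or_unknown")

CLASSIFICATIONS = (
    "complete_in_A",
    "complete_in_B",
    "redundant",
    "reciprocal_complementation",
    "one_way_complementation",
    "host_complemented",
    "holobiont_gap",
)

GENE_STATUSES = ("intact", "pseudogene", "absent")


class ComplementationInputError(ValueError):
    """Gene-status or source inputs are incomplete or malformed."""


# ---------------------------------------------------------------------------
# Pseudogene calling
# ---------------------------------------------------------------------------


def call_pseudogene(length: int, ortholog_lengths: list[int] | tuple[int, ...]) -> str:
    """Call pseudogene status from length reduction relative to orthologs.

    The reference is the median ortholog length; the gene is a pseudogene iff
    its reduction ``1 - length/reference`` strictly exceeds 20%. A reduction
    of exactly 20% is intact ("more than 20%" is a strict bound). The call is
    scale-invariant.
    """
    if not ortholog_lengths:
        raise ComplementationInputError("ortholog length list must be non-empty")
    if length <= 0 or any(x <= 0 for x in ortholog_lengths):
        raise ComplementationInputError("gene and ortholog lengths must be positive")
    reference = median(ortholog_lengths)
    reduction = 1.0 - length / reference
    return "pseudogene" if reduction > 0.20 else "intact"


@dataclass(frozen=True)
class GeneStatus:
    """Status of one gene in one genome. If ``length`` and
    ``ortholog_lengths`` are given and the recorded status is not ``absent``,
    the status is re-derived by the length-reduction rule."""

    gene: str
    genome: str
    status: str
    length: int | None = None
    ortholog_lengths: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.status not in GENE_STATUSES:
            raise ComplementationInputError(
                f"gene {self.gene}: unknown status {self.status!r}"
            )

    @property
    def functional(self) -> bool:
        return self.status == "intact"


def status_from_lengths(
    gene: str, genome: str, length: int | None, ortholog_lengths: tuple[int, ...]
) -> GeneStatus:
    """Build a GeneStatus from observed lengths: no length means absent."""
    if length is None:
        return GeneStatus(gene=gene, genome=genome, status="absent")
    status = call_pseudogene(length, list(ortholog_lengths)) if ortholog_lengths else "intact"
    return GeneStatus(
        gene=gene,
        genome=genome,
        status=status,
        length=length,
        ortholog_lengths=ortholog_lengths,
    )


# ---------------------------------------------------------------------------
# Source-level classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SourceClassification:
    """Provenance call for one required source of one organism."""

    metabolite_id: str
    organism: str
    provenance: str
    provider: str = ""
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.provenance not in PROVENANCES:
            raise ComplementationInputError(f"unknown provenance {self.provenance!r}")


def classify_sources(
    seed_report: SeedReport,
    partner_scope: ScopeResult,
    host_whitelist: dict[str, str],
    partner_name: str,
) -> list[SourceClassification]:
    """Assign a provenance to every seed of an organism.

    Priority is strict: a seed the partner *synthesizes* (present in the
    partner's scope beyond the partner's own sources) is ``partner``;
    otherwise a whitelisted metabolite is ``host`` with the whitelist's
    compartment tag; everything else is ``diet_or_unknown``. Output sorted by
    provenance (partner, host, diet) then metabolite id.
    """
    partner_makes = partner_scope.synthesized
    out: list[SourceClassification] = []
    for mid in sorted(seed_report.seed_ids):
        if mid in partner_makes:
            out.append(
                SourceClassification(
                    metabolite_id=mid,
                    organism=seed_report.organism,
                    provenance="partner",
                    provider=partner_name,
                    evidence="producible by partner scope",
                )
            )
        elif mid in host_whitelist:
            out.append(
                SourceClassification(
                    metabolite_id=mid,
                    organism=seed_report.organism,
                    provenance="host",
                    provider=host_whitelist[mid],
                    evidence="host whitelist",
                )
            )
        else:
            out.append(
                SourceClassification(
                    metabolite_id=mid,
                    organism=seed_report.organism,
                    provenance="diet_or_unknown",
                )
            )
    rank = {p: i for i, p in enumerate(PROVENANCES)}
    out.sort(key=lambda c: (rank[c.provenance], c.metabolite_id))
    return out


def augment_sources_with_cofactors(
    network: MetabolicNetwork,
    enzyme_cofactor_map: dict[str, list[str]],
    base_sources: set[str] | frozenset[str],
) -> frozenset[str]:
    """Add enzyme cofactors as extra sources.

    Reduced endosymbiont genomes often retain enzymes whose cofactors they
    cannot make; those cofactors must be imported. For every EC number
    present in the network, its mapped cofactors are added to the source set
    unless already producible from ``base_sources``.
    """
    base = frozenset(base_sources)
    if not enzyme_cofactor_map:
        return base
    present_ecs = {ec for rxn in network.reactions.values() for ec in rxn.ec_numbers}
    needed: set[str] = set()
    for ec in present_ecs & enzyme_cofactor_map.keys():
        needed.update(enzyme_cofactor_map[ec])
    if not needed:
        return base
    producible = scope(network, base).producible
    return base | frozenset(c for c in needed if c not in producible)


# ---------------------------------------------------------------------------
# Pathway-level complementation
# ---------------------------------------------------------------------------


@dataclass
class PathwayProfile:
    """Per-pathway gene-status matrix for a genome pair and its
    complementation classification."""

    pathway: str
    genes: tuple[str, ...]
    status_a: dict[str, str]
    status_b: dict[str, str]
    genome_a: str
    genome_b: str
    host_evidence: frozenset[str]
    classification: str
    missing_in_a_covered_by_b: int
    missing_in_b_covered_by_a: int
    missing_in_both: int


def _nonfunctional(statuses: dict[str, str], genes: tuple[str, ...]) -> frozenset[str]:
    return frozenset(g for g in genes if statuses[g] in ("pseudogene", "absent"))


def pathway_complementation(
    pathway: str,
    genes: list[str] | tuple[str, ...],
    statuses_a: dict[str, str],
    statuses_b: dict[str, str],
    host_evidence: set[str] | frozenset[str] = frozenset(),
    genome_a: str = "A",
    genome_b: str = "B",
) -> PathwayProfile:
    """Classify a pathway's split between two genomes.

    A gene is non-functional when pseudogenized or absent. Decision table,
    in order:

    * some gene non-functional in both genomes → ``host_complemented`` if
      every such gene has host-side evidence, else ``holobiont_gap``;
    * no gene missing anywhere → ``redundant``;
    * one genome intact throughout while the other lacks the *entire*
      pathway → ``complete_in_<intact genome>``;
    * both genomes have gaps (necessarily disjoint here) →
      ``reciprocal_complementation``;
    * only one genome has gaps, all covered by the other →
      ``one_way_complementation``.

    Swapping the genomes swaps ``complete_in_A``/``complete_in_B`` and leaves
    every other label unchanged.
    """
    genes = tuple(genes)
    for label, statuses in ((genome_a, statuses_a), (genome_b, statuses_b)):
        missing = [g for g in genes if g not in statuses]
        if missing:
            raise ComplementationInputError(
                f"pathway {pathway}: genome {label} reports no status for "
                f"gene(s) {missing}"
            )
        bad = [g for g in genes if statuses[g] not in GENE_STATUSES]
        if bad:
            raise ComplementationInputError(
                f"pathway {pathway}: genome {label}: invalid status for {bad}"
            )
    host_ev = frozenset(host_evidence)
    miss_a = _nonfunctional(statuses_a, genes)
    miss_b = _nonfunctional(statuses_b, genes)
    both = miss_a & miss_b

    if both:
        classification = "host_complemented" if both <= host_ev else "holobiont_gap"
    elif not miss_a and not miss_b:
        classification = "redundant"
    elif not miss_a and miss_b == frozenset(genes):
        classification = "complete_in_A"
    elif not miss_b and miss_a == frozenset(genes):
        classification = "complete_in_B"
    elif miss_a and miss_b:
        classification = "reciprocal_complementation"
    else:
        classification = "one_way_complementation"

    return PathwayProfile(
        pathway=pathway,
        genes=genes,
        status_a=dict(statuses_a),
        status_b=dict(statuses_b),
        genome_a=genome_a,
        genome_b=genome_b,
        host_evidence=host_ev,
        classification=classification,
        missing_in_a_covered_by_b=len(miss_a - miss_b),
        missing_in_b_covered_by_a=len(miss_b - miss_a),
        missing_in_both=len(both),
    )


# ---------------------------------------------------------------------------
# Report bundle
# ---------------------------------------------------------------------------


def complementation_report(
    profiles: list[PathwayProfile],
    classifications: list[SourceClassification],
) -> dict:
    """Merge the two analysis levels into one serialisable report with
    summary counts per provenance and per pathway classification."""
    prov_counts = {p: 0 for p in PROVENANCES}
    for c in classifications:
        prov_counts[c.provenance] += 1
    class_counts = {k: 0 for k in CLASSIFICATIONS}
    for p in profiles:
        class_counts[p.classification] += 1
    return {
        "sources": [
            {
                "metabolite_id": c.metabolite_id,
                "organism": c.organism,
                "provenance": c.provenance,
                "provider": c.provider,
                "evidence": c.evidence,
            }
            for c in classifications
        ],
        "pathways": [
            {
                "pathway": p.pathway,
                "genes": list(p.genes),
                "genome_a": p.genome_a,
                "genome_b": p.genome_b,
                "status_a": p.status_a,
                "status_b": p.status_b,
                "classification": p.classification,
                "missing_in_a_covered_by_b": p.missing_in_a_covered_by_b,
                "missing_in_b_covered_by_a": p.missing_in_b_covered_by_a,
                "missing_in_both": p.missing_in_both,
            }
            for p in profiles
        ],
        "summary": {
            "n_sources": len(classifications),
            "sources_by_provenance": prov_counts,
            "n_pathways": len(profiles),
            "pathways_by_classification": class_counts,
        },
    }


def write_report(report: dict, out_dir) -> None:
    """Write the merged report as JSON plus one TSV sheet per level."""
    import os

    os.makedirs(str(out_dir), exist_ok=True)
    with open(os.path.join(str(out_dir), "report.json"), "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    with open(os.path.join(str(out_dir), "sources.tsv"), "w", encoding="utf-8") as fh:
        fh.write("metabolite_id\torganism\tprovenance\tprovider\tevidence\n")
        for row in report["sources"]:
            fh.write(
                "\t".join(
                    [
                        row["metabolite_id"],
                        row["organism"],
                        row["provenance"],
                        row["provider"],
                        row["evidence"],
                    ]
                )
                + "\n"
            )
    with open(os.path.join(str(out_dir), "pathways.tsv"), "w", encoding="utf-8") as fh:
        fh.write(
            "pathway\tclassification\tmissing_in_a_covered_by_b\t"
            "missing_in_b_covered_by_a\tmissing_in_both\n"
        )
        for row in report["pathways"]:
            fh.write(
                f"{row['pathway']}\t{row['classification']}\t"
                f"{row['missing_in_a_covered_by_b']}\t"
                f"{row['missing_in_b_covered_by_a']}\t{row['missing_in_both']}\n"
            )


# ---------------------------------------------------------------------------
# Gene-status table I/O
# ---------------------------------------------------------------------------


def read_gene_status_table(path) -> dict[str, dict[str, dict[str, str]]]:
    """Read a gene-status TSV (pathway, gene, genome, status, length,
    ortholog_lengths) into {pathway: {genome: {gene: status}}}.

    When length and ortholog_lengths are present and status is blank, the
    status is derived by the length-reduction rule.
    """
    out: dict[str, dict[str, dict[str, str]]] = {}
    with open(str(path), encoding="utf-8") as fh:
        header: list[str] | None = None
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cells = line.split("\t")
            if header is None:
                header = cells
                for col in ("pathway", "gene", "genome", "status"):
                    if col not in header:
                        raise ComplementationInputError(
                            f"{path}: missing required column {col!r}"
                        )
                continue
            row = dict(zip(header, cells))
            status = row.get("status", "").strip()
            if not status:
                length = row.get("length", "").strip()
                orth = row.get("ortholog_lengths", "").strip()
                if not length:
                    status = "absent"
                else:
                    orths = tuple(int(x) for x in orth.split(";") if x.strip())
                    status = status_from_lengths(
                        row["gene"], row["genome"], int(length), orths
                    ).status
            if status not in GENE_STATUSES:
                raise ComplementationInputError(
                    f"{path}: gene {row['gene']}: invalid status {status!r}"
                )
            out.setdefault(row["pathway"], {}).setdefault(row["genome"], {})[
                row["gene"]
            ] = status
    return out
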