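"""Descriptive genome statistics from annotation feature tables.

Computes the per-genome numbers an annotation report prints: predicted gene
counts, the percentage with an assigned function, coding density (fraction
of genome positions covered by at least one CDS, overlaps counted once),
mean gene length, and tRNA anticodon inventories with 20-amino-acid coverage.

Coordinates are 1-based inclusive (GenBank convention). tRNAs with the CAT
anticodon come pre-discriminated in the input labels as initiator methionine
(iMet), elongator methionine (Met) or lysidine-modified isoleucine (kIle);
they are counted as distinct inventory rows but map to Met/Ile for
amino-acid coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_DOWN, ROUND_HALF_UP, Decimal

STANDARD_AMINO_ACIDS = frozenset(
    {
        "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
        "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
    }
)

#: CAT-anticodon variants mapped to the amino acid they actually deliver.
COVERAGE_ALIASES = {"iMet": "Met", "kIle": "Ile"}

FEATURE_TYPES = ("CDS", "tRNA", "rRNA", "ncRNA")


class FeatureTableError(ValueError):
    """A genome feature table violates its format contract."""


@dataclass(frozen=True)
class Feature:
    id: str
    type: str
    start: int
    end: int
    strand: str = "+"
    assigned_function: bool = False
    amino_acid: str | None = None
    anticodon: str | None = None

    def __post_init__(self) -> None:
        if self.type not in FEATURE_TYPES:
            raise FeatureTableError(f"feature {self.id}: unknown type {self.type!r}")
        if self.start > self.end:
            raise FeatureTableError(f"feature {self.id}: start > end")
        if self.start < 1:
            raise FeatureTableError(f"feature {self.id}: coordinates are 1-based")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class FeatureTable:
    genome: str
    features: list[Feature] = field(default_factory=list)
    genome_length: int | None = None


@dataclass
class SummaryStats:
    n_genes: int
    n_assigned: int
    pct_assigned: float
    coding_density_pct: float | None
    mean_gene_length: float
    n_trna: int
    n_rrna: int


# ---------------------------------------------------------------------------
# Percentages
# ---------------------------------------------------------------------------


def percent_assigned(
    total: int, assigned: int, decimals: int = 1, mode: str = "half_up"
) -> float:
    """Percentage of features with an assigned function, rounded per mode.

    Both half-up rounding and truncation are provided because published
    reports mix the two conventions.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= assigned <= total:
        raise ValueError("assigned must lie in [0, total]")
    pct = Decimal(100) * Decimal(assigned) / Decimal(total)
    quantum = Decimal(1).scaleb(-decimals)
    rounding = {"half_up": ROUND_HALF_UP, "truncate": ROUND_DOWN}.get(mode)
    if rounding is None:
        raise ValueError(f"unknown rounding mode {mode!r}")
    return float(pct.quantize(quantum, rounding=rounding))


# ---------------------------------------------------------------------------
# Coding density
# ---------------------------------------------------------------------------


def _union_length(intervals: list[tuple[int, int]]) -> int:
    """Total positions covered by ≥1 interval (1-based inclusive)."""
    if not intervals:
        return 0
    intervals = sorted(intervals)
    covered = 0
    cur_start, cur_end = intervals[0]
    for s, e in intervals[1:]:
        if s > cur_end + 1:
            covered += cur_end - cur_start + 1
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    covered += cur_end - cur_start + 1
    return covered


def coding_density(table: FeatureTable, union: bool = True) -> float:
    """Percent of genome positions covered by at least one CDS.

    With ``union=True`` (default) overlapping CDS count once; ``union=False``
    sums raw CDS lengths instead, for comparison with reports that do."""
    if not table.genome_length or table.genome_length <= 0:
        raise ValueError("coding_density requires a positive genome_length")
    cds = [(f.start, f.end) for f in table.features if f.type == "CDS"]
    covered = _union_length(cds) if union else sum(e - s + 1 for s, e in cds)
    return 100.0 * covered / table.genome_length


# ---------------------------------------------------------------------------
# tRNA inventory
# ---------------------------------------------------------------------------


@dataclass
class TrnaInventory:
    """Per-amino-acid anticodon multiset with coverage over the 20 standard
    amino acids."""

    anticodons: dict[str, list[str]]
    total: int
    covered_amino_acids: frozenset[str]
    full_coverage: bool


def trna_inventory(table: FeatureTable) -> TrnaInventory:
    anticodons: dict[str, list[str]] = {}
    covered: set[str] = set()
    total = 0
    for f in table.features:
        if f.type != "tRNA":
            continue
        if not f.anticodon:
            raise FeatureTableError(f"tRNA feature {f.id} lacks an anticodon")
        if not f.amino_acid:
            raise FeatureTableError(f"tRNA feature {f.id} lacks an amino acid label")
        anticodons.setdefault(f.amino_acid, []).append(f.anticodon)
        covered.add(COVERAGE_ALIASES.get(f.amino_acid, f.amino_acid))
        total += 1
    covered &= STANDARD_AMINO_ACIDS | set()
    covered_std = frozenset(covered & STANDARD_AMINO_ACIDS)
    return TrnaInventory(
        anticodons={aa: sorted(v) for aa, v in sorted(anticodons.items())},
        total=total,
        covered_amino_acids=covered_std,
        full_coverage=covered_std == STANDARD_AMINO_ACIDS,
    )


# ---------------------------------------------------------------------------
# Summary
# ---------------------------------------------------------------------------


def summarize(
    table: FeatureTable,
    assigned_counts: tuple[int, int] | None = None,
    pct_decimals: int = 2,
    pct_mode: str = "half_up",
) -> SummaryStats:
    """Fill SummaryStats from a feature table.

    ``assigned_counts`` overrides (total, assigned) when the annotation's
    assignment tally is external to the feature table; otherwise the table's
    ``assigned_function`` flags are counted. Mean gene length is the
    arithmetic mean of CDS lengths, reported to 0 decimals half-up.
    """
    cds = [f for f in table.features if f.type == "CDS"]
    n_genes = len(cds)
    if assigned_counts is not None:
        total, assigned = assigned_counts
    else:
        total, assigned = n_genes, sum(1 for f in cds if f.assigned_function)
    pct = percent_assigned(total, assigned, pct_decimals, pct_mode) if total else 0.0
    mean_len = (
        float(
            Decimal(sum(f.length for f in cds))
            / Decimal(n_genes)
        )
        if n_genes
        else 0.0
    )
    mean_len = float(Decimal(mean_len).quantize(Decimal(1), rounding=ROUND_HALF_UP))
    density = coding_density(table) if table.genome_length else None
    return SummaryStats(
        n_genes=total if assigned_counts is not None else n_genes,
        n_assigned=assigned,
        pct_assigned=pct,
        coding_density_pct=density,
        mean_gene_length=mean_len,
        n_trna=sum(1 for f in table.features if f.type == "tRNA"),
        n_rrna=sum(1 for f in table.features if f.type == "rRNA"),
    )


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

TSV_COLUMNS = [
    "genome",
    "feature_id",
    "type",
    "start",
    "end",
    "strand",
    "assigned",
    "amino_acid",
    "anticodon",
]


def read_feature_table(path, genome_length: int | None = None) -> FeatureTable:
    """Read a feature TSV (columns: genome, feature_id, type, start, end,
    strand, assigned, amino_acid, anticodon)."""
    features: list[Feature] = []
    genome = ""
    with open(str(path), encoding="utf-8") as fh:
        header: list[str] | None = None
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cells = line.split("\t")
            if header is None:
                header = [c.strip() for c in cells]
                missing = [c for c in TSV_COLUMNS[:5] if c not in header]
                if missing:
                    raise FeatureTableError(f"{path}: missing column(s) {missing}")
                continue
            row = dict(zip(header, cells))
            genome = row["genome"] or genome
            features.append(
                Feature(
                    id=row["feature_id"],
                    type=row["type"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    strand=row.get("strand", "+") or "+",
                    assigned_function=row.get("assigned", "0").strip() == "1",
                    amino_acid=row.get("amino_acid") or None,
                    anticodon=row.get("anticodon") or None,
                )
            )
    return FeatureTable(genome=genome, features=features, genome_length=genome_length)


def write_feature_table(table: FeatureTable, path) -> None:
    with open(str(path), "w", encoding="utf-8") as fh:
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for f in table.features:
            fh.write(
                "\t".join(
                    [
                        table.genome,
                        f.id,
                        f.type,
                        str(f.start),
                        str(f.end),
                        f.strand,
                        "1" if f.assigned_function else "0",
                        f.amino_acid or "",
                        f.anticodon or "",
                    ]
                )
                + "\n"
            )
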