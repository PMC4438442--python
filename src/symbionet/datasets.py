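"""Loaders for the small reference tables shipped with the package.

These transcribe published per-genome inventories for the *Bemisia tabaci*
MED dual-symbiont system (*Portiera* + *Hamiltonella*): the required-source
tables of each symbiont's reconstructed metabolism, the tRNA anticodon
inventories, and a miniature two-network demo reproducing the headline
cross-feeding pattern (chorismate, lysine and phenylalanine intermediates
supplied by the primary symbiont).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .genome_summary import Feature, FeatureTable
from .network_io import MetabolicNetwork, read_reaction_table

ORGANISMS = ("portiera", "hamiltonella")


def _data_path(name: str):
    return resources.files("symbionet").joinpath("data").joinpath(name)


def load_required_sources(organism: str) -> pd.DataFrame:
    """Required-source table for one symbiont: one row per metabolite the
    organism must import, with the assessed provider."""
    organism = organism.lower()
    if organism not in ORGANISMS:
        raise ValueError(f"unknown organism {organism!r}; expected one of {ORGANISMS}")
    with resources.as_file(_data_path(f"required_sources_{organism}.tsv")) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def load_trna_features(organism: str) -> FeatureTable:
    """tRNA inventory for one symbiont genome as a FeatureTable.

    Coordinates are synthetic placeholders (sequential 75 bp slots); only the
    amino-acid and anticodon labels carry information.
    """
    organism = organism.lower()
    if organism not in ORGANISMS:
        raise ValueError(f"unknown organism {organism!r}; expected one of {ORGANISMS}")
    with resources.as_file(_data_path(f"trna_{organism}.tsv")) as p:
        df = pd.read_csv(p, sep="\t", comment="#")
    features: list[Feature] = []
    pos = 1
    for _, row in df.iterrows():
        for anticodon in str(row["anticodons"]).split(";"):
            features.append(
                Feature(
                    id=f"trna_{len(features):03d}",
                    type="tRNA",
                    start=pos,
                    end=pos + 74,
                    amino_acid=row["amino_acid"],
                    anticodon=anticodon,
                )
            )
            pos += 100
    return FeatureTable(genome=organism, features=features)


def demo_path(name: str):
    """Path-like handle to a demo fixture file."""
    return _data_path(f"demo/{name}")


def load_demo_networks() -> tuple[MetabolicNetwork, MetabolicNetwork]:
    """The miniature Portiera/Hamiltonella network pair."""
    with resources.as_file(demo_path("net_portiera.tsv")) as p:
        net_p = read_reaction_table(p, organism="Portiera")
    with resources.as_file(demo_path("net_hamiltonella.tsv")) as p:
        net_h = read_reaction_table(p, organism="Hamiltonella")
    return net_p, net_h


def load_host_whitelist(path=None) -> dict[str, str]:
    """Host whitelist TSV (metabolite_id, compartment) → mapping."""
    if path is None:
        ctx = resources.as_file(demo_path("host_whitelist.tsv"))
        with ctx as p:
            df = pd.read_csv(p, sep="\t", comment="#")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    return dict(zip(df["metabolite_id"], df["compartment"]))


def load_gene_list(path) -> frozenset[str]:
    """One gene symbol per line; '#' comments skipped."""
    out: set[str] = set()
    with open(str(path), encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line)
    return frozenset(out)


def lysine_pathway_case() -> tuple[list[str], dict[str, str], dict[str, str]]:
    """The lysine (diaminopimelate) pathway worked example: the primary
    symbiont lacks dapF and lysA and carries a pseudogenized dapB, while the
    secondary symbiont lacks only argD."""
    genes = ["lysC", "asd", "dapA", "dapB", "dapD", "argD", "dapE", "dapF", "lysA"]
    portiera = {g: "intact" for g in genes}
    portiera.update({"dapB": "pseudogene", "dapF": "absent", "lysA": "absent"})
    hamiltonella = {g: "intact" for g in genes}
    hamiltonella["argD"] = "absent"
    return genes, portiera, hamiltonella
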