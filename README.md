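# symbionet

Metabolic complementation analysis for co-resident insect endosymbionts.

Sap-feeding insects such as the whitefly *Bemisia tabaci* host a highly
reduced primary endosymbiont (*Candidatus* Portiera aleyrodidarum) together
with secondary symbionts (here *Hamiltonella*) inside the same bacteriocytes.
Each bacterium's genome has lost so many genes that neither metabolism is
self-sufficient: each needs **seed metabolites** (sources) imported from its
environment — the insect host, the diet, or the partner bacterium — and some
biosynthetic pathways only work because their genes are split across the two
genomes. `symbionet` takes per-organism reaction tables and gene
presence/absence matrices and infers this cross-feeding structure.

## What it computes

Given a directed metabolic network, the **compound graph** G places an edge
`s → p` for every substrate–product pair of every reaction. Working on G:

- **Seed detection.** Condense G into its strongly connected components
  (SCCs). Every metabolite in an SCC *C* with no incoming condensation edge
  is a seed, with confidence `1/|C|` (any single member of *C* would render
  the rest reachable, so each is equally plausible as the true import).
- **Scope (network expansion).** From a source set *S*, repeatedly fire
  every reaction whose substrates are **all** available and add its
  products, until fixpoint. The result is the set of metabolites the
  organism can actually synthesize from *S*.
- **Source provenance.** Each seed of organism X is classified in strict
  priority order: `partner` if the co-resident symbiont synthesizes it
  (it lies in the partner's scope beyond the partner's own sources), else
  `host` if whitelisted as host-provided (with a compartment tag), else
  `diet_or_unknown`.
- **Within-pathway complementation.** Pathway genes are scored
  intact / pseudogene / absent per genome (a gene reduced by **more than
  20 %** in length relative to the median of its orthologs is called a
  pseudogene). A decision table labels each pathway: `redundant`,
  `complete_in_A/B`, `one_way_complementation`,
  `reciprocal_complementation`, `host_complemented` (shared gaps backed by
  host-transcriptome evidence) or `holobiont_gap`.
- **Curation.** Before any of the above, reconstruction artifacts are
  removed jointly over the symbiont pair: unfed isolated reactions,
  unconnected spontaneous reactions, unresolvable generic metabolites
  ("a sugar"), blocklisted non-prokaryotic reactions and disconnected
  multifunctional-enzyme copies — with a safeguard that retains any reaction
  touching a metabolite the partner produces, and an auditable log.
- **Genome summaries.** Gene counts, assignment percentages (half-up or
  truncating rounding), coding density (union of CDS intervals), and tRNA
  anticodon inventories with 20-amino-acid coverage.

A synthetic-data module generates networks with *planted* seed sets,
holobiont splits with planted cross-feeding, pathway matrices with planted
classifications and feature tables with planted statistics, so every stage
is verifiable against ground truth computed independently of the code under
test.

## Worked example

The packaged demo is a miniature version of the dual-symbiont system: a
primary-symbiont network that builds chorismate-pathway and
diaminopimelate-pathway intermediates from host-supplied precursors, and a
secondary-symbiont network that finishes lysine and phenylalanine synthesis
from those intermediates.

```sh
symbionet demo --out results/demo
```

prints

```json
{
 "n_pathways": 4,
 "n_sources": 11,
 "pathways_by_classification": {
  "complete_in_A": 0,
  "complete_in_B": 0,
  "holobiont_gap": 1,
  "host_complemented": 1,
  "one_way_complementation": 1,
  "reciprocal_complementation": 1,
  "redundant": 0
 },
 "sources_by_provenance": {
  "diet_or_unknown": 0,
  "host": 8,
  "partner": 3
 }
}
```

The 3 `partner` sources are the secondary symbiont's seeds that only the
primary symbiont synthesizes — 5-enolpyruvyl-shikimate-3-phosphate,
N-succinyl-LL-2,6-diaminopimelate and phenylpyruvate — i.e. predicted
cross-feeding. The pathway sheet shows the lysine pathway as
`reciprocal_complementation` (three primary-genome gaps covered by the
secondary genome, one secondary-genome gap covered by the primary) and the
histidine pathway as a `holobiont_gap` (both genomes lack *hisB*/*hisD*, so
the amino acid must come from the diet).

The same analyses are available as library calls:

```python
from symbionet import build_compound_graph, detect_seeds, scope
from symbionet.datasets import load_demo_networks

net_p, net_h = load_demo_networks()
seeds_h = detect_seeds(build_compound_graph(net_h), "Hamiltonella")
print(sorted(seeds_h.seed_ids))
# ['5-ES-3P', 'Fe2+', 'H2S', 'L-Glutamine', 'N-S-LL-2,6-D',
#  'Phenyl-pyruvate', 'Protoporphyrin', 'Serine']
```

Subcommands `curate`, `seeds`, `scope`, `complement`, `pathways`,
`summarize` and `simulate` expose the individual stages; `symbionet run
--config config.yaml --out results/` runs the whole pipeline from a YAML
configuration.

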