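# Methods

This note documents the models and procedures implemented in `symbionet`,
the assumptions behind them, the choices made where the design was genuinely
open, and what the synthetic-data suites do and do not establish.

## The setting

Two bacteria co-resident in the same insect cells are analysed as a pair.
Each is represented by a `MetabolicNetwork`: a set of reactions over
string-identified metabolites. Metabolite identity is exact, case-sensitive
string match — the identifiers come from a curated reconstruction, and
attempting synonym resolution would risk silent wrong merges, which are far
more damaging downstream than an occasional duplicate node. Reversible
reactions are split into explicit `_fwd`/`_rev` irreversible pairs before
any graph is built, because both core algorithms are defined on directed
structures; the splitting is idempotent and the reader/writer round-trips
networks field-for-field.

## Curation

Automatic reconstructions from enzyme annotations carry systematic
artifacts. Five rules remove them, each recording every removal in a
`CurationLog` (reaction id, rule, justification) so that the reaction-count
difference between input and output is fully accounted for:

1. **Taxon blocklist** — reactions whose id or EC number the user has
   declared not to occur in the taxon. The blocklist is configuration, not a
   shipped list: which reactions are implausible is a judgment about the
   organisms at hand.
2. **Generic-metabolite instantiation** — a reaction touching a compound
   class placeholder ("a sugar") is expanded into one copy per mapped
   specific compound; copies whose substrates are neither produced elsewhere
   nor declared sources are dropped; placeholders with no mapping remove the
   reaction. The mapping is configuration for the same reason as above.
3. **Spontaneous filter** — a spontaneous (non-enzymatic) reaction is kept
   only if it shares a metabolite with an enzymatic reaction of the same
   network; spontaneous chemistry connected only to itself is reconstruction
   noise.
4. **Multifunctional pruning** — among reactions carrying an identical
   (non-empty) EC set — one enzyme annotated with several activities — the
   copies sharing no metabolite with any differently-labelled reaction are
   dropped.
5. **Joint disconnection fixpoint** — a reaction is a removal candidate when
   none of its substrates is a declared source or a product of a retained
   reaction of its own network; before removal, a safeguard checks the
   *partner* network, retaining (and logging) the reaction if any of its
   metabolites is a partner product or a declared source. This is the one
   rule that is inherently pairwise: a reaction that looks dead in isolation
   may be fed by cross-feeding, and ties resolve toward retention.

The disconnection rule is specified as a fixpoint rather than a scan because
a scan's outcome would depend on removal order. Removals only shrink the
product pools, so candidacy is monotone and the fixpoint is unique; the test
suite verifies this against exhaustive exploration of all one-at-a-time
removal orders on random ≤6-reaction two-network instances.

The pipeline applies the rules in the order 1→2→3→4→5 after reversibility
splitting. No published convention fixes this order; the final disconnection
pass re-establishes connectivity after all other removals, which is the only
ordering constraint that matters. Each rule is idempotent. Currency
metabolites (water, ATP, protons …) are *not* removed during curation —
curation stays purely structural; currency handling is a graph-construction
option (below).

## Seed detection

The compound graph has one node per metabolite and an edge from every
substrate to every product of each reaction, with parallel edges collapsed
and annotated with all originating reaction ids. An optional currency
blocklist excludes ubiquitous cofactors from nodes and edges; it is **off by
default** because genuine environmental sources can be currency-like
(bicarbonate is a real imported source in reduced endosymbiont metabolisms),
so hiding them must be a deliberate choice.

Seeds are the strongly connected components with no incoming edge in the SCC
condensation. Every member of such a source component is reported with
confidence `1/|component|`: within the component each member reaches all
others, so any one of them would explain the rest, and the shares sum to 1.
No minimum-size or confidence threshold is applied by default (a
`min_confidence` filter exists for reporting). Output order is deterministic:
confidence descending, then id ascending. Isolated nodes are size-1 source
components with confidence 1.

Seed detection deliberately uses single-substrate (OR) reachability — an
edge means "contributes to" — while scope uses all-substrate (AND) firing.
The two semantics answer different questions ("what must come in" vs "what
can be made") and are never conflated; the suite tests them separately.

## Scope

`scope(network, sources)` iterates network expansion to a fixpoint: a
reaction fires when all of its substrates are producible, adding its
products. The result is independent of iteration order (the producible set
grows monotonically), and the implementation is verified against a naive
repeated-rescan oracle. `producible_count` exposes both the
sources-included and sources-excluded conventions, because published counts
rarely state which they use. Source ids absent from the network are logged
and ignored rather than raised: seed lists are routinely computed on a
*different* curation state of the same organism.

## Source provenance

For organism X with partner Y, each seed of X is classified with strict
priority:

1. `partner` if the seed lies in Y's scope **excluding Y's own sources** —
   i.e. Y actually synthesizes it. Using the full scope would mark any
   compound both organisms import as partner-provided, which conflates
   sharing a diet with cross-feeding.
2. `host` if on the user-supplied host whitelist (with its compartment tag,
   e.g. mitochondria for heme intermediates). Host attributions rest on
   transcriptome evidence and literature, not on network computation, so
   they are configuration.
3. `diet_or_unknown` otherwise.

Ties resolve toward `partner` (priority 1 first) to surface candidate
cross-feeding for review. Cofactor augmentation adds, for every EC number
present in a network, the enzyme's known cofactors to the source set when
they are not already producible — reduced genomes routinely retain enzymes
whose cofactors they cannot make, and treating those cofactors as imports is
required for the scope to be biologically meaningful.

## Pathway-level complementation

A gene is non-functional when `absent` or `pseudogene`. The pseudogene rule:
reference length = median of ortholog lengths (the median resists outlier
orthologs; no aggregator is canonical), and the call is `pseudogene` iff the
reduction `1 − length/reference` strictly exceeds 0.20 — a reduction of
exactly 20 % is intact. The call is scale-invariant.

With `miss_A`, `miss_B` the non-functional gene sets of a pathway:

| condition | label |
|---|---|
| `miss_A ∩ miss_B ≠ ∅`, all shared gaps host-evidenced | `host_complemented` |
| `miss_A ∩ miss_B ≠ ∅`, otherwise | `holobiont_gap` |
| both empty | `redundant` |
| one genome intact throughout, the other lacking the **entire** pathway | `complete_in_A` / `complete_in_B` |
| both non-empty (necessarily disjoint here) | `reciprocal_complementation` |
| exactly one non-empty, a proper subset | `one_way_complementation` |

The distinction between `complete_in_X` and `one_way_complementation` was a
genuinely open design point: both describe a pathway fully functional in one
genome. We reserve `complete_in_X` for the case where the other genome
contributes *nothing* (the pathway simply resides in X), and
`one_way_complementation` for a partial gap covered by the partner — the
latter is the evolutionarily informative signal of recent loss against a
redundant background. Swapping the genomes swaps `complete_in_A/B` and fixes
every other label, which the suite checks for all seven classes.

Two deliberate non-rescues: genes whose function might be covered by other
aminotransferases are not auto-rescued (an explicit analog map can declare
substitutions), and annotation caveats such as possible transcriptional
slippage through a homopolymer tract are handled by a per-gene
treat-as-intact override rather than modeled.

## Genome summaries

Coordinates are 1-based inclusive (GenBank convention). Coding density is
the union of CDS intervals over genome length — overlapping genes count
once; a summed-length variant exists behind a flag for comparison with
reports that double-count. Assignment percentages are computed with
`decimal` arithmetic under both half-up rounding and truncation, because
published tables mix the two conventions. tRNA inventories count
CAT-anticodon variants (iMet, Met, kIle) as distinct rows but map them to
Met/Ile for the 20-amino-acid coverage flag; the labels are trusted as
input — discriminating them requires sequence analysis out of scope here.

The package ships small transcribed reference tables for the *B. tabaci*
MED system (required-source tables and tRNA inventories of both symbiont
genomes, and the lysine-pathway gene statuses) used by the worked examples.
The secondary symbiont's transcribed tRNA table sums to 39 anticodons while
its source publication's text says 40; the table is shipped as transcribed
and no check depends on that total.

## Synthetic data and what passing tests mean

`generate_network` builds a positionally-ordered network: the first
positions form a source layer; every later metabolite gets a backbone
producing reaction whose substrates sit at strictly lower positions; surplus
reactions and reversibility add arbitrary edges and cycles **among produced
metabolites only** — no construction step ever directs an edge into the
source layer (reactions with a source substrate are never made reversible).
By induction on the minimum position in any SCC, every produced metabolite's
component has an external in-edge, so the planted seed set — exactly the
never-produced metabolites — is analytically correct, not computed by the
algorithm under test. The planted scope is computed at generation time by a
naive re-scan oracle local to the module.

`split_holobiont` assigns reactions to two organisms (probability
`p_assign_a`), then pins reactions so that a requested number of metabolites
are synthesizable by exactly one organism while consumed by the other. The
emitted truth lists *every* actually cross-fed metabolite in both
directions, found by hand-rolled transitive-closure seed detection plus the
naive scope oracle, so recovery tests can demand exact set equality — not
merely containment of the forced ones. Default study conditions in the
recovery suites: 30 metabolites, 50 reactions, 20 % reversibility, an even
split with 3 forced cross-fed metabolites; suites run 20–100 replicates.

`generate_pathway_case` constructs status matrices that classify as a
requested label by construction; `generate_feature_table` places
non-overlapping features so density and length statistics are analytic. All
generators are pure functions of their parameters and seed.

What these suites show: the algorithms are correct on networks whose
structure matches their assumptions (exact identifiers, boolean
presence/absence, AND-stoichiometry without quantities). What they do not
show: robustness to annotation noise, identifier mismatch between
reconstructions, stoichiometric or thermodynamic infeasibility, or enzyme
promiscuity — real reconstructions fail in those ways, and the curation log
plus configuration surfaces (blocklists, generic maps, whitelists, analog
maps) exist precisely because those failure modes need human judgment.

## Numerical and degenerate-input choices

- Percentages use `decimal` quantization (no binary-float rounding
  surprises); the pseudogene threshold is a strict `>` on a float ratio,
  safe because a reduction of exactly 0.20 computed from integer lengths is
  representable below the threshold.
- Empty networks, empty reports and empty reaction tables are valid inputs
  everywhere (a warning, never an error); a zero-length genome or an empty
  ortholog list is a domain error.
- All analysis stages are deterministic; randomness exists only in
  `synthetic_data` and flows from explicit integer seeds. Reports and
  on-disk artifacts are byte-stable across reruns (no timestamps), and the
  run manifest's configuration hash changes iff an input file or option
  changes.

## Known limitations

- Seed confidence `1/|SCC|` treats all members of a source cycle as
  exchangeable; it cannot prefer the biologically plausible import within a
  cycle.
- The scope's AND semantics ignores stoichiometric coefficients and
  quantities; a reaction needing two units of a substrate fires like one
  needing one.
- Provenance classification is qualitative: it predicts *who can* supply a
  metabolite, not fluxes or transporter capacity. Transporter inference
  beyond cofactor augmentation is out of scope.
- Pathway classification treats pseudogenes as fully non-functional;
  partially active truncated proteins would be misclassified.
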