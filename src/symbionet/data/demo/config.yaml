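# End-to-end demo configuration: miniature dual-symbiont analysis.
net_a: net_portiera.tsv
net_b: net_hamiltonella.tsv
organism_a: Portiera
organism_b: Hamiltonella
declared_sources: declared_sources.txt
host_whitelist: host_whitelist.tsv
host_evidence: host_evidence.txt
pathway_statuses: pathway_statuses.tsv
use_currency_blocklist: false
include_sources: true
min_confidence: 0.0
rounding_mode: half_up
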