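# Gene presence/absence/pseudogene matrix for the amino-acid pathways split
# between the two symbiont genomes.
pathway	gene	genome	status	length	ortholog_lengths
lysine	lysC	Portiera	intact
lysine	asd	Portiera	intact
lysine	dapA	Portiera	intact
lysine	dapB	Portiera	pseudogene
lysine	dapD	Portiera	intact
lysine	argD	Portiera	intact
lysine	dapE	Portiera	intact
lysine	dapF	Portiera	absent
lysine	lysA	Portiera	absent
lysine	lysC	Hamiltonella	intact
lysine	asd	Hamiltonella	intact
lysine	dapA	Hamiltonella	intact
lysine	dapB	Hamiltonella	intact
lysine	dapD	Hamiltonella	intact
lysine	argD	Hamiltonella	absent
lysine	dapE	Hamiltonella	intact
lysine	dapF	Hamiltonella	intact
lysine	lysA	Hamiltonella	intact
phenylalanine	pheA	Portiera	intact
phenylalanine	aspC	Portiera	absent
phenylalanine	pheA	Hamiltonella	intact
phenylalanine	aspC	Hamiltonella	intact
histidine	hisG	Portiera	intact
histidine	hisB	Portiera	absent
histidine	hisD	Portiera	absent
histidine	hisG	Hamiltonella	intact
histidine	hisB	Hamiltonella	absent
histidine	hisD	Hamiltonella	absent
branched_chain	ilvC	Portiera	intact
branched_chain	ilvD	Portiera	intact
branched_chain	ilvE	Portiera	absent
branched_chain	ilvC	Hamiltonella	intact
branched_chain	ilvD	Hamiltonella	intact
branched_chain	ilvE	Hamiltonella	absent
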