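# Miniature Hamiltonella-like network: completes lysine and phenylalanine
# synthesis from partner-supplied intermediates, plus heme and cysteine
# assembly from host-supplied compounds.
reaction_id	ec	substrates	products	reversible	spontaneous	generic_metabolites
H01	4.2.3.5	5-ES-3P	Chorismate	0	0
H02	3.5.1.18	N-S-LL-2,6-D	LL-DAP	0	0
H03	5.1.1.7	LL-DAP	meso-DAP	0	0
H04	4.1.1.20	meso-DAP	L-Lysine	0	0
H05	2.6.1.1	Phenyl-pyruvate;L-Glutamate	L-Phenylalanine;2-oxoglutarate	0	0
H06	4.99.1.1	Protoporphyrin;Fe2+	Heme	0	0
H07	2.5.1.47	Serine;H2S	L-Cysteine	0	0
H08	4.1.3.27	Chorismate;L-Glutamine	Anthranilate;L-Glutamate	0	0
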