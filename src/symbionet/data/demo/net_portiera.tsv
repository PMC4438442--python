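# Miniature Portiera-like network: chorismate backbone to phenylpyruvate and
# the aspartate branch up to N-succinyl-LL-2,6-diaminopimelate.
reaction_id	ec	substrates	products	reversible	spontaneous	generic_metabolites
P01	2.5.1.54	E4P;PEP	DAHP	0	0
P02	4.2.3.4	DAHP	S3P	0	0
P03	2.5.1.19	S3P;PEP	5-ES-3P	0	0
P04	4.2.3.5	5-ES-3P	Chorismate	0	0
P05	5.4.99.5	Chorismate	Prephenate	0	0
P06	4.2.1.51	Prephenate	Phenyl-pyruvate	0	0
P07	1.2.1.11	L-Aspartate	ASA	0	0
P08	4.3.3.7	ASA	THDP	0	0
P09	2.3.1.117	THDP	N-S-AKP	0	0
P10	2.6.1.17	N-S-AKP	N-S-LL-2,6-D	0	0
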