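# Required metabolic sources of Hamiltonella (B. tabaci MED dual-symbiont system),
# with the putative provider assessed from the published reconstruction.
metabolite_id	product_or_pathway	putative_source	compound_class
H2S	(Seleno)Cysteine	B. tabaci	anion
Pantothenate	Co-enzyme A	B. tabaci	vitamin
HCO3	Fatty acids, nucleic acids etc.	B. tabaci	anion
Dihydroneopterin	Folate	B. tabaci	pterin
P-Amino-Benzoate	Folate	B. tabaci	aromatic acid
Glucose	Glycolysis	B. tabaci	sugar
Serine	Glycine, Cysteine etc.	B. tabaci	amino acid
Fe2+	Heme o, general cofactor	B. tabaci	cation
Proline	Glutamate	B. tabaci	amino acid
E4P	Pyridoxine	B. tabaci	sugar phosphate
SAM	Methionine	B. tabaci	cofactor
Protoporphyrin	Heme o	Mitochondria	heme
5-ES-3P	Chorismate	Portiera	aromatic intermediate
N-S-LL-2,6-D	Lysine	Portiera	amino acid intermediate
Phenyl-pyruvate	Phenylalanine	Portiera	keto acid
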