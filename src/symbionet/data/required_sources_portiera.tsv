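# Required metabolic sources of Portiera (B. tabaci MED dual-symbiont system),
# with the putative provider assessed from the published reconstruction.
metabolite_id	product_or_pathway	putative_source	compound_class
(Seleno-)Homocysteine	Methionine	B. tabaci	amino acid
Geranylgeranyl-diphosphate	Carotenoids	B. tabaci	isoprenoid
HCO3	Carboxylation reactions	B. tabaci	anion
L-Ornithine	Arginine	B. tabaci	amino acid
L-Aspartate	Aspartate family	B. tabaci and Hamiltonella	amino acid
Erythrose-4-phosphate	Aromatic amino acids	B. tabaci and Hamiltonella	sugar phosphate
Phosphoenol-pyruvate	Glycolysis	B. tabaci and Hamiltonella	carboxylic acid
Farnesyl-diphosphate	Isoprenoids	B. tabaci and Hamiltonella	isoprenoid
Ribose-5-phosphate	Nucleotides	B. tabaci and Hamiltonella	sugar phosphate
Protoheme	Heme	Mitochondria	heme
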