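# tRNA anticodon inventory of the Portiera genome (B. tabaci MED line).
# CAT anticodons come pre-discriminated as iMet / Met / kIle.
amino_acid	anticodons
Ala	TGC
Arg	TCT;ACG;CCG
Asn	GTT
Asp	GTC
Cys	GCA
Gln	TTG
Glu	TTC
Gly	GCC;TCC
His	GTG
Ile	GAT
kIle	CAT
Leu	TAG;GAG;TAA
Lys	TTT
iMet	CAT
Met	CAT
Phe	GAA
Pro	TGG
Ser	TGA;GCT;GGA;CGA
Thr	CGT;TGT;AGT
Trp	CCA
Tyr	GTA
Val	GAC;TAC
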