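# tRNA anticodon inventory of the Hamiltonella genome (B. tabaci MED line),
# as transcribed from the published annotation table (39 rows; the published
# text counts 40 tRNA genes).
amino_acid	anticodons
Ala	TGC;GGC
Arg	TCT;CCT;CCG;ACG;TCT
Asn	GTT
Asp	GTC
Cys	GCA
Gln	CTG;TTG
Glu	TTC
Gly	TCC;GCC
His	GTG
Ile	GAT
kIle	CAT
Leu	CAG;GAG;TAG;TAA;CAA
Lys	TTT;CTT
iMet	CAT
Met	CAT
Phe	GAA
Pro	TGG;GGG
Ser	GCT;GGA;TGA
Thr	TGT;GGT
Trp	CCA
Tyr	GTA
Val	TAC;GAC
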