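# Environmental inputs declared before curation.
E4P
PEP
L-Aspartate
5-ES-3P
N-S-LL-2,6-D
Phenyl-pyruvate
Protoporphyrin
Fe2+
Serine
H2S
L-Glutamine
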