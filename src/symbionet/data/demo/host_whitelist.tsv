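# Host-provided compounds with the compartment or evidence tag.
metabolite_id	compartment
Protoporphyrin	Mitochondria
Fe2+	B. tabaci
Serine	B. tabaci
H2S	B. tabaci
L-Glutamine	B. tabaci
E4P	B. tabaci
PEP	B. tabaci
L-Aspartate	B. tabaci
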