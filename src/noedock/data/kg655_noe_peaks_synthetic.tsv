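# Synthetic NOE peak table for KG-655 / ARNT PAS-B (reconstructed stand-in).
# 12 classified peaks; 7 involve the degenerate aromatic proton pair K_HAR,
# whose two distinct ring carbons yield 19 heavy-atom distances on expansion.
ligand_group	receptor_group	class
K_HAR	M396D1	strong
K_HF	M396G2	medium
K_HAR	M408D1	medium
K_HAR	M415G1	strong
K_HAR	M418D1	medium
K_HF	M418D2	weak
K_HAR	M423D1	weak
K_HAR	M425G1	medium
K_HO	M425G2	weak
K_HAR	M457D1	strong
K_HF	M458D1	weak
K_HO	M381G1	weak
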