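# Synthetic NOE peak table for KG-279 / ARNT PAS-B (reconstructed stand-in).
# 28 classified peaks; 3 involve the degenerate aromatic pair Q_HAR, whose
# two distinct ring carbons yield 31 heavy-atom distances on expansion.
ligand_group	receptor_group	class
Q_HAR	M396D1	strong
Q_H3	M396D1	medium
Q_H4	M396G2	medium
Q_ME1	M396G2	weak
Q_HAR	M408D1	medium
Q_H3	M408D1	weak
Q_ME1	M408D2	medium
Q_H8	M408D2	weak
Q_H4	M415G1	strong
Q_ME2	M415G1	weak
Q_HN	M415G2	medium
Q_HO	M415G2	weak
Q_HAR	M423D1	weak
Q_H8	M423D1	medium
Q_ME1	M423D2	weak
Q_H3	M423D2	weak
Q_H4	M425G1	medium
Q_ME2	M425G1	strong
Q_HN	M425G2	weak
Q_H8	M425G2	medium
Q_H3	M457D1	strong
Q_ME1	M457D1	weak
Q_HO	M457G2	medium
Q_H4	M457G2	weak
Q_ME2	M458D1	weak
Q_HN	M458D1	weak
Q_H8	M381G1	weak
Q_HO	M381G1	weak
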