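# Synthetic proton-group definitions (ARNT PAS-B methyl probes + example ligands).
# Reconstructed stand-in, not an experimental assignment table.
id	owner	residue	protons	heavy_atoms
K_HAR	ligand		H2',H6'	C2',C6'
K_HF	ligand		H7	C7
K_HO	ligand		HO1	O1
Q_HAR	ligand		H2",H6"	C2",C6"
Q_H3	ligand		H3"	C3"
Q_H4	ligand		H4"	C4"
Q_ME1	ligand		HM11,HM12,HM13	CM1,CM1,CM1
Q_ME2	ligand		HM21,HM22,HM23	CM2,CM2,CM2
Q_HN	ligand		HN	N1
Q_HO	ligand		HO2	O2
Q_H8	ligand		H8	C8
M381G1	receptor	381	HG11,HG12,HG13	CG1,CG1,CG1
M396D1	receptor	396	HD11,HD12,HD13	CD1,CD1,CD1
M396G2	receptor	396	HG21,HG22,HG23	CG2,CG2,CG2
M408D1	receptor	408	HD11,HD12,HD13	CD1,CD1,CD1
M408D2	receptor	408	HD21,HD22,HD23	CD2,CD2,CD2
M415G1	receptor	415	HG11,HG12,HG13	CG1,CG1,CG1
M415G2	receptor	415	HG21,HG22,HG23	CG2,CG2,CG2
M418D1	receptor	418	HD11,HD12,HD13	CD1,CD1,CD1
M418D2	receptor	418	HD21,HD22,HD23	CD2,CD2,CD2
M423D1	receptor	423	HD11,HD12,HD13	CD1,CD1,CD1
M423D2	receptor	423	HD21,HD22,HD23	CD2,CD2,CD2
M425G1	receptor	425	HG11,HG12,HG13	CG1,CG1,CG1
M425G2	receptor	425	HG21,HG22,HG23	CG2,CG2,CG2
M457D1	receptor	457	HD11,HD12,HD13	CD1,CD1,CD1
M457G2	receptor	457	HG21,HG22,HG23	CG2,CG2,CG2
M458D1	receptor	458	HD11,HD12,HD13	CD1,CD1,CD1
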