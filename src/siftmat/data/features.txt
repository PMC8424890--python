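# Pharmacophore feature definitions used to assign ligand feature rows.
#
# Format: one pattern per non-comment line,
#     <feature letter> <TAB> <pattern name> <TAB> <SMARTS>
# Feature letters: A acceptor, D donor, H hydrophobic, N negatively
# charged/ionizable, P positively charged/ionizable, R aromatic ring.
# The vdW ("any atom") row is implicit: every ligand heavy atom is
# vdW-capable and is not listed here.
#
# Post-processing applied by the matcher (see pharmacophore module):
#   * matches with identical atom sets are merged into one feature,
#   * H matches are merged into maximal bonded components (one feature
#     per contiguous hydrophobic patch),
#   * R matches are deduplicated per ring atom set (fused systems give
#     one feature per smallest ring).

A	acceptor.divalent_oxygen	[OX2;+0]
A	acceptor.carbonyl_oxygen	[$([OX1]=[#6,#7,#15,#16])]
A	acceptor.oxyanion	[OX1-]
A	acceptor.amine_nitrogen	[NX3;+0;!$([NX3]-[#6]=[O,S,N]);!$([NX3]-a);!$([NX3]~[OX1])]
A	acceptor.aromatic_nitrogen	[nX2;+0]

D	donor.hydroxyl	[OX2H1;+0]
D	donor.amine	[NX3;H1,H2;+0]
D	donor.ammonium	[NX4;H1,H2,H3;+1]
D	donor.aromatic_nh	[nH1;+0]
D	donor.thiol	[SX2H1]

H	hydrophobe.carbon	[#6;+0;!$([#6]~[#7,#8,#9,#15,#16,Cl,Br,I])]
H	hydrophobe.thioether	[SX2;H0;$([SX2]([#6])[#6])]
H	hydrophobe.halogen	[Cl,Br,I;$([*]-[#6])]

N	neg.carboxylate	[CX3](=O)[OX1H0-,OX2H1]
N	neg.sulfonate	[SX4](=O)(=O)[OX1H0-,OX2H1]
N	neg.phosphate	[PX4](=O)[OX1H0-,OX2H1]

P	pos.quaternary_n	[NX4+;!$([NX4+]~[OX1])]
P	pos.guanidinium	[NX3][CX3](=[NX3+])[NX3]
P	pos.basic_amine	[NX3;H2,H1;+0;$([NX3][CX4]);!$([NX3][#6]=[O,S,N]);!$([NX3]-a)]

R	ring.six_membered	a1aaaaa1
R	ring.five_membered	a1aaaa1
R	ring.seven_membered	a1aaaaaa1
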