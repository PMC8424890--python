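# Incrementable cells of the per-residue 7x9 block.
# Rows are ligand pharmacophore features (A acceptor, D donor,
# H hydrophobic, N negative, P positive, R aromatic, vdW any atom);
# listed values are the interaction-type columns that the row may
# increment.  Cells not listed here are structurally zero.
#
# Column letters: Any, BB backbone, SC sidechain, P polar,
# H hydrophobic, A residue-as-acceptor, D residue-as-donor,
# C charged, R aromatic.
A: [Any, BB, SC, P, D]
D: [Any, BB, SC, P, A]
H: [Any, BB, SC, H]
N: [Any, SC, C]
P: [Any, SC, C, R]
R: [Any, BB, SC, H, R]
vdW: [Any, BB, SC]
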