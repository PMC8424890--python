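# Residue-side knowledge tables: physicochemical classes and the named
# sidechain atoms participating in each interaction type.  Backbone
# hydrogen bonding (N as donor, O/OXT as acceptor) is handled in code
# for every residue and is not listed here.
#
# Users may override any of these tables through a config file.

classes:
  aromatic: [PHE, TYR, TRP, HIS]
  hydrophobic: [ALA, VAL, LEU, ILE, MET, PHE, TRP, PRO, CYS]
  polar: [SER, THR, ASN, GLN, TYR, HIS, CYS, TRP]
  negatively_charged: [ASP, GLU]
  positively_charged: [LYS, ARG, HIS]

# Common alternate residue names (protonation / disulfide variants)
# mapped back to the parent code before any table lookup.
aliases:
  HID: HIS
  HIE: HIS
  HIP: HIS
  HSD: HIS
  HSE: HIS
  HSP: HIS
  CYX: CYS
  CYM: CYS
  ASH: ASP
  GLH: GLU
  LYN: LYS
  ARN: ARG
  MSE: MET

# Sidechain heavy atoms that can donate a hydrogen bond (require an
# attached hydrogen at run time unless degraded mode is active).
donors:
  SER: [OG]
  THR: [OG1]
  TYR: [OH]
  CYS: [SG]
  ASN: [ND2]
  GLN: [NE2]
  LYS: [NZ]
  ARG: [NE, NH1, NH2]
  HIS: [ND1, NE2]
  TRP: [NE1]

# Sidechain heavy atoms that can accept a hydrogen bond.
acceptors:
  SER: [OG]
  THR: [OG1]
  TYR: [OH]
  ASN: [OD1]
  GLN: [OE1]
  ASP: [OD1, OD2]
  GLU: [OE1, OE2]
  HIS: [ND1, NE2]
  MET: [SD]

# Atoms of the formally charged sidechain group (used for the charged
# and pi-cation criteria; the group centroid is their unweighted mean).
charged_group:
  ASP: [CG, OD1, OD2]
  GLU: [CD, OE1, OE2]
  LYS: [NZ]
  ARG: [CZ, NE, NH1, NH2]
  HIS: [ND1, CE1, NE2]

# Aromatic ring atom sets (TRP has two rings).
aromatic_rings:
  PHE: [[CG, CD1, CD2, CE1, CE2, CZ]]
  TYR: [[CG, CD1, CD2, CE1, CE2, CZ]]
  HIS: [[CG, ND1, CD2, CE1, NE2]]
  TRP: [[CG, CD1, NE1, CE2, CD2], [CE2, CD2, CE3, CZ3, CH2, CZ2]]

# Polar sidechain heavy atoms (targets of the distance-only polar
# contact for polar-class residues).
polar_sidechain:
  SER: [OG]
  THR: [OG1]
  ASN: [OD1, ND2]
  GLN: [OE1, NE2]
  TYR: [OH]
  HIS: [ND1, NE2]
  CYS: [SG]
  TRP: [NE1]
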