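# Methods

This note records the scientific conventions behind `siftmat`: what is
computed, which choices were genuinely open, and what the synthetic
test bed does and does not demonstrate.

## Descriptor model

Each residue of a protein–ligand complex contributes a 7×9 block of
non-negative counts; blocks concatenate in residue order
(chain, sequence number, insertion code) into a 7 × (9·N) matrix.
Rows are ligand pharmacophore feature types (acceptor, donor,
hydrophobic, negative, positive, aromatic, any-atom wildcard);
columns are interaction types (any, backbone, sidechain, polar,
hydrophobic, residue-as-acceptor, residue-as-donor, charged,
aromatic).  A cell counts *feature instances*, not atom pairs: one
hydroxyl donating to a residue increments (D, A) by one regardless of
how many acceptor atoms it reaches, while two distinct rings stacking
on the same residue increment (R, R) twice.

Not every row/column combination is chemically meaningful.  The
incrementable cells are fixed by a mask shipped as data
(`data/increment_mask.yaml`): A {Any,BB,SC,P,D}, D {Any,BB,SC,P,A},
H {Any,BB,SC,H}, N {Any,SC,C}, P {Any,SC,C,R}, R {Any,BB,SC,H,R},
vdW {Any,BB,SC}.  Charged interactions are restricted to sidechains
(a backbone is not formally charged away from the termini).  Cells
outside the mask are structurally zero, and the 1D linearization
enumerates only masked cells (29 per residue), in (residue, row,
column) order.

## Ligand feature perception

Features are assigned by SMARTS matching (RDKit) against patterns in
an editable text file (`data/features.txt`).  Conventions:

* matches with identical heavy-atom sets merge into one feature;
* hydrophobic matches merge into maximal bonded components — a hexyl
  chain is one hydrophobic patch, not six atomic features — which
  keeps the H row from dominating counts;
* each smallest aromatic ring is one R feature (naphthalene → 2),
  with centroid and best-fit-plane normal (total least squares via
  SVD; the normal's sign is arbitrary and all angle comparisons fold
  to [0°, 90°]);
* charged-group features span the whole group (both carboxylate
  oxygens plus the carbon; the guanidinium CZ and nitrogens), and
  centroids are unweighted means over member heavy atoms;
* hydrogens are never feature members; they enter only through donor
  geometry;
* the wildcard (vdW) row is not materialised as a feature: every
  ligand heavy atom is contact-capable, and the row increments each
  region column at most once per residue however many atoms touch.

## Residue-side model

Residues are classified by a fixed membership table
(`data/residues.yaml`): aromatic {PHE, TYR, TRP, HIS}, hydrophobic
{ALA, VAL, LEU, ILE, MET, PHE, TRP, PRO, CYS}, polar {SER, THR, ASN,
GLN, TYR, HIS, CYS, TRP}, negative {ASP, GLU}, positive {LYS, ARG,
HIS}.  Classes are not exclusive.  Two table choices were genuinely
open and are deliberate: GLY carries no class (its sidechain is a
hydrogen), and HIS is treated as aromatic + polar + positively
charged, reflecting its frequent protonation in binding sites; both
are overridable, as are the per-residue donor/acceptor/charged/
aromatic/polar atom name tables in the same file.  ASP and GLU are
classed as charged only (not additionally polar), so carboxylate
contacts are reported through the charged column rather than doubled
into the polar column.

The backbone/sidechain partition is N, CA, C, O, OXT plus hydrogens
covalently attached to them; everything else is sidechain.  Residue
covalent topology is not stored: donor hydrogens are the H atoms
within 1.3 Å of the donor heavy atom, and an acceptor's antecedent is
any heavy atom within 1.8 Å (2.1 Å when sulfur is involved).  On
idealized and well-refined geometry these reproduce the chemical
bonding exactly; on pathological coordinates (overlapping atoms) they
degrade gracefully rather than fail.

## Geometric criteria

All cutoffs are inclusive, guarded by a 1e-9 numerical epsilon so
that rigid-body motion of a complex cannot flip a boundary case.
Defaults (every one overridable through `GeometryParams` / config):

| criterion | default |
|---|---|
| contact (vdW / hydrophobic / charged / polar) | min heavy-atom distance ≤ 3.5 Å |
| hydrogen bond, distance | d(H···X) ≤ 2.8 Å |
| hydrogen bond, donor | 180° − ∠(Y–H···X) ≤ 120° |
| hydrogen bond, acceptor | 180° − ∠(antecedent–X···H) ≤ 90° |
| face-to-face stacking | centroid ≤ 4.4 Å and interplanar ≤ 30° |
| edge-to-face stacking | centroid ≤ 5.5 Å and interplanar ≥ 60° |
| π–cation | centroid ≤ 6.6 Å, no angle criterion |

Conventions that needed fixing beyond the numbers themselves:

* The hydrogen-bond distance is measured hydrogen-to-acceptor (the
  angle notation Y–H···X places the contact at H···X).  A
  heavy–heavy mode (`hbond_distance_mode="heavy_heavy"`) is provided
  for users whose structures lack reliable hydrogens.
* Both angle criteria are read as *maximum deviations from ideal
  geometry* — this is the only reading under which both printed
  values act as upper bounds.  The acceptor axis is approximated by
  the mean direction of the acceptor's bonded heavy atoms (lone-pair
  directions are not modelled); acceptors with no antecedent skip
  the acceptor-angle test.
* Hydrogens are expected on polar atoms.  When a donor has no
  resolvable hydrogen the bond is tested distance-only against
  heavy–heavy ≤ 2.8 + 1.0 Å; a complex parsed without any protein
  hydrogens is flagged (`degraded_hbond_mode` in the matrix
  metadata) so downstream users know the H-bond columns are
  approximate.
* Hydrophobic contacts target carbon/sulfur *sidechain* atoms of
  hydrophobic-class residues; aromatic features also qualify as
  hydrophobic contacts (mask cell (R, H)).
* Face-to-face takes precedence when a geometry satisfies both
  stacking windows; π–cation is evaluated in both directions (ligand
  ring ↔ residue cation, ligand cation ↔ residue ring).

Redundancy rules keep the counts interpretable: one feature instance
increments a cell at most once per residue; an established hydrogen
bond suppresses the additional polar increment for the same
feature–residue pair; the wildcard row is capped at one per region
column.  The Any column is set whenever any detector fires for the
feature, so within each row, Any is nonzero iff some specific column
is.

## Profiles, frequencies, hotspots

A profile is the cellwise mean of an aligned collection, followed by
silencing: values strictly lower than the threshold (default 0.3)
become exactly 0, so a cell present in 3 of 10 complexes (mean 0.3)
survives and 2 of 10 (0.2) does not.  Alignment onto generic residue
numbers (GPCRdb "3x32" primary; Ballesteros–Weinstein "3.32" accepted
and normalized textually — bulge positions such as 5x461 shift
between schemes, so no arithmetic conversion is ever attempted)
introduces an explicit *absent* flag distinct from observed-zero;
averaging and frequencies can divide either by all complexes
(default — an absent position counts as non-interacting) or by
present-only complexes.  Contact frequency marks a position
interacting when any cell of its block is nonzero; hotspots are
positions with frequency strictly greater than the cutoff (default
0.30 — exactly 30 % is excluded), sorted by descending frequency.
Differential profiles classify positions into common/unique by
nonzero support after silencing and report signed per-cell
differences; outlier ranking orders complexes by Euclidean distance
between their count-valued linearization and the profile's.

Tanimoto similarity is defined for binary fingerprints with the
empty∩empty case fixed at 1.0 (two complexes in which nothing is
detected are indistinguishable, hence maximally similar); Euclidean
distance serves count-valued fingerprints.

## Synthetic test bed

`siftmat.fixtures` builds single-residue probe fixtures (methane,
benzene, methylammonium, acetate, methanol, acetone against idealized
amino-acid templates) whose expected blocks are computed by a plain,
independent application of the rules to the constructed coordinates;
seeded collections with exactly known cellwise means; random
≤5-residue complexes for brute-force equivalence testing; and a
three-residue showcase pocket.  Fixtures are built in memory at full
float precision — the boundary sweeps distinguish 0.01 Å steps,
beyond PDB/MOL text precision — while a separate writer emits
standard PDB+MOL files to exercise the real parsers at safe margins.

What passing tests show: the implementation applies the stated
criteria exactly (boundary sweeps recover every printed cutoff at
0.01 Å / 0.1° resolution), agrees with an independent brute-force
oracle on randomized geometry, and is rigid-motion invariant.  What
they do not show: anything about crystal-structure preparation.  Real
inputs bring protonation/tautomer ambiguity, missing atoms, altLocs
(resolved here by highest occupancy), and waters/ions (excluded);
fixture templates use idealized sidechain geometry, not rotamer
statistics.  Conclusions about real receptors still depend on the
quality of structure preparation, which is intentionally outside this
package: inputs are expected pre-protonated.

## Problem sizes

The default test suite runs in well under a minute on one CPU: 200
random complexes for oracle equivalence, 10-matrix collections for
profile exactness, and ~1 800 fixture evaluations across the nine
boundary sweeps (the same sweeps the acceptance script reruns).
These sizes were chosen as the smallest that exercise every rule and
boundary; all generators scale up by argument if heavier
randomization is wanted.

## Known limitations

* No halogen bonds, metal coordination, water-mediated bridges, or
  salt-bridge strength scoring; no mmCIF input; single-ligand
  complexes only; nucleic acids unsupported.
* PDB-only ligands get bonds and charges perceived from geometry
  (RDKit `DetermineBonds`, neutral-charge first attempt); a supplied
  MOL/SDF block is always the better route.
* Acceptor directionality uses the antecedent-axis proxy, which is
  permissive for sp³ oxygens (it cannot distinguish the two lone
  pairs).
* Formal charges are taken from the input; neutral amines are treated
  as positively ionizable by pattern, but no pKa reasoning is done.
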