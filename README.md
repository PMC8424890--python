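# siftmat

Structural interaction fingerprint **matrices** for protein–ligand
complexes: per binding-site residue, a 7×9 count matrix whose rows are
the ligand's pharmacophore feature types and whose columns are the
interaction types formed with that residue.

Classical structural interaction fingerprints (SIFts) are
protein-centric bit strings — they record *that* a residue is
contacted, but treat the ligand as a featureless blob.  `siftmat`
keeps the residue-wise layout while splitting every contact by the
ligand chemistry behind it, so a single descriptor answers both
"which residues bind?" and "with which ligand features?".  It is
aimed at structure-based drug-design work: binding-site hotspot
mapping across crystal structures, consensus binding-mode profiles,
agonist-vs-antagonist comparisons on GPCRs via generic residue
numbers, and docking-pose post-processing through 1D fingerprints.

## The descriptor

For a complex with N residues the descriptor is a 7 × (9·N) matrix of
non-negative integers.  Within each residue block:

* rows (ligand pharmacophore features, SMARTS-assigned): **A**
  H-bond acceptor, **D** H-bond donor, **H** hydrophobic, **N**
  negatively charged, **P** positively charged, **R** aromatic ring,
  **vdW** any heavy atom;
* columns (interaction types): **Any**, **BB** backbone, **SC**
  sidechain, **P** polar, **H** hydrophobic, **A** residue acts as
  H-bond acceptor, **D** residue acts as H-bond donor, **C** charged,
  **R** aromatic.

A cell counts how many distinct feature instances of that type form
that interaction with the residue (two rings stacked on one
phenylalanine give (R,R) = 2).  Geometric criteria (all inclusive):
contacts at min heavy-atom distance ≤ 3.5 Å with class
complementarity; hydrogen bonds at d(H···X) ≤ 2.8 Å with donor
deviation 180° − ∠(Y–H···X) ≤ 120° and acceptor deviation ≤ 90°;
ring stacking at centroid separation ≤ 4.4 Å (interplanar angle
≤ 30°, face-to-face) or ≤ 5.5 Å (≥ 60°, edge-to-face); π–cation at
centroid separation ≤ 6.6 Å.

Collections of matrices can be aligned on GPCRdb generic residue
numbers ("3x32"), averaged into real-valued profiles (cells below a
silencing threshold, default 0.3, are zeroed), reduced to contact
frequencies and hotspot lists (positions contacted in more than 30 %
of structures), differenced between two collections, and linearized
into binary or count fingerprints compared with Tanimoto similarity
or Euclidean distance.

## Worked example

No downloads are needed: the `siftmat.fixtures` module builds toy
complexes with exact geometry.  The showcase below is a three-residue
miniature of an aminergic binding pocket holding an
aryloxy-alkylamine ligand (protonated amine + ether + phenyl ring):

```python
import numpy as np
from siftmat import build_matrix, to_linear, FEATURE_ROWS, INTERACTION_COLS
from siftmat.fixtures import make_showcase_complex

cx, _ = make_showcase_complex()
m = build_matrix(cx)
print("residues:", m.n_residues, "| matrix shape:", m.stacked().shape)
for b in m.blocks:
    cells = ", ".join(
        f"({FEATURE_ROWS[r]},{INTERACTION_COLS[c]})={b.counts[r, c]}"
        for r, c in zip(*np.nonzero(b.counts)))
    print(f"{b.label:<10s} {cells}")
fp = to_linear(m, binary=True)
print("fingerprint length:", len(fp), "| bits set:", int(fp.values.sum()))
```

prints

```
residues: 3 | matrix shape: (7, 27)
A/ASP10    (D,Any)=1, (D,SC)=1, (D,A)=1, (P,Any)=1, (P,SC)=1, (P,C)=1, (vdW,Any)=1, (vdW,SC)=1
A/SER20    (A,Any)=1, (A,SC)=1, (A,D)=1, (vdW,Any)=1, (vdW,SC)=1
A/PHE30    (R,Any)=1, (R,SC)=1, (R,R)=1
fingerprint length: 87 | bits set: 16
```

Reading the blocks: the aspartate holds the ligand's protonated amine
by a charged contact *and* receives its hydrogen bond (rows P and D);
the serine donates a hydrogen bond to the ether oxygen (row A, column
D — the residue is the donor); the phenylalanine stacks face-to-face
with the ligand ring (row R, column R).  The vdW row marks plain
steric contact wherever any ligand heavy atom is within 3.5 Å.

The same pipeline runs from the shell on standard files:

```bash
siftmat compute complex.pdb --ligand-file ligand.mol \
        --annotation generic_numbers.csv -o matrix.json
siftmat profile m1.json m2.json m3.json --threshold 0.3 -o profile.json
siftmat frequency *.json -o freq.csv --html freq.html
siftmat hotspots *.json --min-fraction 0.30
siftmat compare a.json b.json --metric tanimoto
siftmat heatmap matrix.json -o matrix.png
```

`scripts/demo_binding_site.py` sketches the full receptor-collection
workflow (hotspots + differential profile) for users who have their
own prepared, protonated structures; it is a documentation aid, not
part of the test suite.

## Layout

* `siftmat.structure` — PDB/MOL parsing, residue classes,
  backbone/sidechain partition, generic-number annotation
* `siftmat.pharmacophore` — SMARTS feature assignment, ring geometry
* `siftmat.engine` — geometric detectors and block/matrix construction
* `siftmat.matrix` — data model, JSON/CSV serialization, alignment,
  linearization, Tanimoto/Euclidean metrics
* `siftmat.profiles` — averaging, silencing, frequencies, hotspots,
  differential profiles, outlier ranking
* `siftmat.fixtures` — synthetic complexes with analytically known
  descriptors
* `siftmat.viz` / `siftmat.cli` — heat maps and the `siftmat` command

Defaults (SMARTS patterns, residue tables, the incrementable-cell
mask) live in `src/siftmat/data/` as editable text and can be
overridden per run; see `docs/methods.md` for the scientific
conventions and their rationale.
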