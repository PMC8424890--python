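"""Canonical row/column orders of the per-residue interaction block.

Rows are ligand pharmacophore feature types, columns are residue
interaction types.  Both orders are fixed so that serialized matrices
and linear fingerprints are bit-comparable across runs and machines.
"""

from __future__ import annotations

#: Ligand pharmacophore feature rows, in canonical order:
#: A hydrogen-bond acceptor, D hydrogen-bond donor, H hydrophobic,
#: N negatively charged group, P positively charged group, R aromatic
#: ring, vdW any heavy atom.
FEATURE_ROWS: tuple[str, ...] = ("A", "D", "H", "N", "P", "R", "vdW")

#: Residue interaction-type columns, in canonical order:
#: Any (any interaction), BB backbone, SC sidechain, P polar,
#: H hydrophobic, A residue acts as hydrogen-bond acceptor,
#: D residue acts as hydrogen-bond donor, C charged, R aromatic.
INTERACTION_COLS: tuple[str, ...] = ("Any", "BB", "SC", "P", "H", "A", "D", "C", "R")

N_ROWS = len(FEATURE_ROWS)
N_COLS = len(INTERACTION_COLS)

ROW_INDEX = {name: i for i, name in enumerate(FEATURE_ROWS)}
COL_INDEX = {name: i for i, name in enumerate(INTERACTION_COLS)}

#: Residue classes recognised by the engine.
RESIDUE_CLASSES: tuple[str, ...] = (
    "aromatic",
    "hydrophobic",
    "polar",
    "negatively_charged",
    "positively_charged",
)

#: Backbone heavy-atom names (OXT covers C-terminal residues).
BACKBONE_HEAVY = {"N", "CA", "C", "O", "OXT"}

#: The three standard water residue names and common monoatomic ions,
#: excluded from both protein and ligand on parsing.
WATER_NAMES = {"HOH", "WAT", "H2O", "DOD"}
ION_NAMES = {"NA", "K", "CL", "CA", "MG", "ZN", "MN", "FE", "BR", "IOD", "CD", "NI", "CU", "HG", "SO4", "PO4"}
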