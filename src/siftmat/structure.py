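"""Parsing of protein–ligand complexes.

The protein side is read from PDB text (via gemmi); the ligand either
from a separate SDF/MOL block (via RDKit, preserving bond orders) or
from a named HETATM residue in the PDB, in which case bonds are
perceived from the 3D coordinates.  Waters and common ions are dropped.
Residues are classified into physicochemical classes and partitioned
into backbone/sidechain atoms; generic residue numbers (GPCRdb-style
``3x32`` labels) can be attached from an annotation table.

Explicit hydrogens are expected on polar atoms for full hydrogen-bond
geometry; when absent the complex is flagged and hydrogen bonds are
detected in a distance-only degraded mode downstream.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import gemmi
import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdDetermineBonds

from ._tables import residue_tables
from .constants import BACKBONE_HEAVY, ION_NAMES, WATER_NAMES

logger = logging.getLogger(__name__)

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

#: maximum H—heavy distance treated as a covalent bond when assigning
#: hydrogens to backbone/sidechain or to donor heavy atoms
H_BOND_LENGTH_MAX = 1.3


class ComplexError(Exception):
    """Base class for complex-parsing errors."""


class LigandMissingError(ComplexError):
    pass


class LigandAmbiguousError(ComplexError):
    pass


class FormatError(ComplexError):
    pass


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coords: np.ndarray  # (3,) float, Å
    is_hydrogen: bool

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")
        object.__setattr__(self, "coords", c)


@dataclass
class Residue:
    chain: str
    seqnum: int
    insertion_code: str
    name: str
    atoms: list[Atom]
    generic_number: str | None = None
    classes: frozenset[str] = field(default_factory=frozenset)
    backbone_atoms: list[Atom] = field(default_factory=list)
    sidechain_atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chain, self.seqnum, self.insertion_code, self.name)

    @property
    def label(self) -> str:
        return f"{self.chain}/{self.name}{self.seqnum}{self.insertion_code}"

    def heavy_coords(self, region: str = "all") -> np.ndarray:
        atoms = {"all": self.atoms, "backbone": self.backbone_atoms,
                 "sidechain": self.sidechain_atoms}[region]
        pts = [a.coords for a in atoms if not a.is_hydrogen]
        return np.array(pts) if pts else np.empty((0, 3))

    def find_atoms(self, names) -> list[Atom]:
        wanted = set(names)
        return [a for a in self.atoms if a.name in wanted]

    def hydrogens_bonded_to(self, heavy: Atom) -> list[Atom]:
        """Hydrogens within covalent range of ``heavy`` (geometric bond
        assignment; residue connectivity is not stored explicitly)."""
        return [a for a in self.atoms if a.is_hydrogen
                and np.linalg.norm(a.coords - heavy.coords) <= H_BOND_LENGTH_MAX]


@dataclass
class Ligand:
    atoms: list[Atom]
    bonds: list[tuple[int, int, float]]  # (i, j, bond order)
    source_format: str  # pdb_het | sdf | mol
    mol: Chem.Mol | None = None  # RDKit molecule with a 3D conformer

    def __post_init__(self):
        n = len(self.atoms)
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"ligand bond ({i},{j}) out of range for {n} atoms")

    def heavy_indices(self) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if not a.is_hydrogen]

    def coords(self, indices) -> np.ndarray:
        return np.array([self.atoms[i].coords for i in indices])

    def hydrogens_bonded_to(self, index: int) -> list[int]:
        out = []
        for i, j, _ in self.bonds:
            if i == index and self.atoms[j].is_hydrogen:
                out.append(j)
            elif j == index and self.atoms[i].is_hydrogen:
                out.append(i)
        return out

    def heavy_neighbors(self, index: int) -> list[int]:
        out = []
        for i, j, _ in self.bonds:
            if i == index and not self.atoms[j].is_hydrogen:
                out.append(j)
            elif j == index and not self.atoms[i].is_hydrogen:
                out.append(i)
        return out


@dataclass
class Complex:
    residues: list[Residue]
    ligand: Ligand
    identifier: str = ""
    has_polar_hydrogens: bool = True


# ---------------------------------------------------------------------------
# residue classification and backbone/sidechain partition

def classify_residue(name: str, tables: dict | None = None) -> frozenset[str]:
    """Physicochemical class set for a 3-letter residue code.

    Classes are not mutually exclusive (TYR is aromatic and polar).
    Unknown codes yield an empty set with a logged warning; such
    residues still contribute to plain-contact (vdW) detection.
    """
    tables = tables or residue_tables()
    canonical = tables["aliases"].get(name, name)
    classes = frozenset(cls for cls, members in tables["classes"].items()
                        if canonical in members)
    if canonical not in STANDARD_AA and not classes:
        logger.warning("unknown residue name %r: no interaction classes assigned", name)
    return classes


def split_backbone_sidechain(residue: Residue) -> Residue:
    """Fill the backbone/sidechain partition in place and return it.

    Backbone = N, CA, C, O, OXT plus hydrogens covalently attached to
    them (assigned geometrically); everything else is sidechain.  For
    GLY the CA hydrogens therefore land on the backbone side.
    """
    bb_heavy = [a for a in residue.atoms if not a.is_hydrogen and a.name in BACKBONE_HEAVY]
    bb_pts = np.array([a.coords for a in bb_heavy]) if bb_heavy else np.empty((0, 3))
    backbone, sidechain = [], []
    for a in residue.atoms:
        if a.is_hydrogen:
            if bb_pts.size and np.min(np.linalg.norm(bb_pts - a.coords, axis=1)) <= H_BOND_LENGTH_MAX:
                backbone.append(a)
            else:
                sidechain.append(a)
        elif a.name in BACKBONE_HEAVY:
            backbone.append(a)
        else:
            sidechain.append(a)
    residue.backbone_atoms = backbone
    residue.sidechain_atoms = sidechain
    return residue


# ---------------------------------------------------------------------------
# PDB / ligand parsing

def _keep_best_altloc(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Single-conformer view of a residue: per atom name, keep the
    highest-occupancy alternate location (ties: first encountered)."""
    best: dict[str, gemmi.Atom] = {}
    order: list[str] = []
    for atom in res:
        prev = best.get(atom.name)
        if prev is None:
            best[atom.name] = atom
            order.append(atom.name)
        elif atom.occ > prev.occ:
            best[atom.name] = atom
    return [best[name] for name in order]


def _gemmi_atom(a: gemmi.Atom) -> Atom:
    el = a.element.name
    return Atom(name=a.name, element=el,
                coords=np.array([a.pos.x, a.pos.y, a.pos.z]),
                is_hydrogen=el in ("H", "D"))


def _ligand_from_rdkit(mol: Chem.Mol, source_format: str) -> Ligand:
    if mol.GetNumConformers() == 0:
        raise FormatError("ligand has no 3D coordinates")
    conf = mol.GetConformer()
    atoms = []
    for i, a in enumerate(mol.GetAtoms()):
        p = conf.GetAtomPosition(i)
        sym = a.GetSymbol()
        atoms.append(Atom(name=f"{sym}{i + 1}", element=sym,
                          coords=np.array([p.x, p.y, p.z]),
                          is_hydrogen=sym == "H"))
    bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
             for b in mol.GetBonds()]
    return Ligand(atoms=atoms, bonds=bonds, source_format=source_format, mol=mol)


def ligand_from_mol_block(block: str) -> Ligand:
    """Ligand from an SDF/MOL V2000 block with 3D coordinates."""
    mol = Chem.MolFromMolBlock(block, removeHs=False, sanitize=True)
    if mol is None:
        raise FormatError("could not parse the ligand SDF/MOL block")
    fmt = "sdf" if "$$$$" in block else "mol"
    return _ligand_from_rdkit(mol, fmt)


def _ligand_from_het_atoms(atoms: list[Atom]) -> Ligand:
    """Ligand from bare HETATM coordinates: bonds (and, when possible,
    bond orders and aromaticity) perceived from interatomic distances."""
    xyz = io.StringIO()
    xyz.write(f"{len(atoms)}\nligand\n")
    for a in atoms:
        x, y, z = a.coords
        xyz.write(f"{a.element} {x:.4f} {y:.4f} {z:.4f}\n")
    mol = Chem.MolFromXYZBlock(xyz.getvalue())
    if mol is None:
        raise FormatError("could not build the ligand from HETATM records")
    try:
        rdDetermineBonds.DetermineBonds(mol, charge=0)
    except Exception:
        # fall back to connectivity only (covalent-radius criteria)
        rdDetermineBonds.DetermineConnectivity(mol)
        try:
            Chem.SanitizeMol(mol, Chem.SanitizeFlags.SANITIZE_FINDRADICALS
                             | Chem.SanitizeFlags.SANITIZE_SETAROMATICITY)
        except Exception:
            logger.warning("ligand aromaticity perception failed; "
                           "aromatic features may be missed")
    lig = _ligand_from_rdkit(mol, "pdb_het")
    # keep the PDB atom names
    lig.atoms = [Atom(name=src.name, element=la.element, coords=la.coords,
                      is_hydrogen=la.is_hydrogen)
                 for src, la in zip(atoms, lig.atoms)]
    return lig


def parse_complex(pdb_text: str,
                  ligand_block: str | None = None,
                  ligand_selector: str | None = None,
                  identifier: str = "",
                  tables: dict | None = None) -> Complex:
    """Parse a protein–ligand complex.

    Parameters
    ----------
    pdb_text:
        PDB-format text with at least one chain of standard amino
        acids.  AltLocs are reduced to the highest-occupancy conformer;
        waters and common ions are discarded.
    ligand_block:
        Optional SDF/MOL V2000 text for the ligand (takes precedence).
    ligand_selector:
        Residue name of the HETATM ligand when no block is given.
    """
    tables = tables or residue_tables()
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"unparseable PDB text: {exc}") from exc
    if len(st) == 0:
        raise FormatError("PDB text contains no model")
    model = st[0]

    residues: list[Residue] = []
    het_groups: dict[tuple[str, str, int, str], list[Atom]] = {}
    for chain in model:
        for gres in chain:
            name = gres.name.strip()
            if name in WATER_NAMES or name in ION_NAMES:
                continue
            atoms = [_gemmi_atom(a) for a in _keep_best_altloc(gres)]
            icode = (gres.seqid.icode or "").strip()
            canonical = tables["aliases"].get(name, name)
            if canonical in STANDARD_AA:
                res = Residue(chain=chain.name, seqnum=gres.seqid.num,
                              insertion_code=icode, name=name, atoms=atoms,
                              classes=classify_residue(name, tables))
                residues.append(split_backbone_sidechain(res))
            else:
                het_groups[(chain.name, name, gres.seqid.num, icode)] = atoms

    if not residues:
        raise FormatError("PDB text contains no standard amino-acid residues")
    residues.sort(key=lambda r: (r.chain, r.seqnum, r.insertion_code))

    if ligand_block is not None:
        ligand = ligand_from_mol_block(ligand_block)
    else:
        if ligand_selector is None:
            raise LigandMissingError(
                "no ligand block given and no ligand_selector specified")
        matches = [(k, v) for k, v in het_groups.items() if k[1] == ligand_selector]
        if not matches:
            raise LigandMissingError(
                f"ligand-missing: no HETATM residue named {ligand_selector!r}")
        if len(matches) > 1:
            keys = sorted(f"{k[0]}/{k[1]}{k[2]}{k[3]}" for k, _ in matches)
            raise LigandAmbiguousError(
                f"ligand-ambiguous: selector {ligand_selector!r} matches {keys}")
        ligand = _ligand_from_het_atoms(matches[0][1])

    has_h = any(a.is_hydrogen for r in residues for a in r.atoms)
    if not has_h:
        logger.warning(
            "no hydrogens found on the protein: hydrogen bonds will be "
            "detected in distance-only degraded mode")
    return Complex(residues=residues, ligand=ligand, identifier=identifier,
                   has_polar_hydrogens=has_h)


# ---------------------------------------------------------------------------
# generic residue numbers

def normalize_generic_number(text: str) -> str:
    """Normalize a generic residue number to GPCRdb ``3x32`` form.

    Ballesteros–Weinstein dotted labels (``3.32``) are accepted and
    rewritten with an ``x``; the digits themselves are taken from the
    annotation table as-is (bulge positions such as ``5x461`` shift
    between the two schemes, so no arithmetic conversion is attempted).
    """
    t = text.strip()
    if "." in t and "x" not in t:
        t = t.replace(".", "x", 1)
    return t


def read_annotation_csv(path_or_buffer) -> dict[tuple[str, int], str]:
    """Read a 3-column CSV (chain, seqnum, generic_number) annotation."""
    df = pd.read_csv(path_or_buffer, dtype={0: str}, comment="#")
    cols = [c.strip().lower() for c in df.columns]
    try:
        ci = cols.index("chain")
        si = cols.index("seqnum")
        gi = cols.index("generic_number")
    except ValueError as exc:
        raise FormatError(
            "annotation CSV must have columns chain,seqnum,generic_number") from exc
    out: dict[tuple[str, int], str] = {}
    for _, row in df.iterrows():
        key = (str(row.iloc[ci]).strip(), int(row.iloc[si]))
        if key in out:
            raise FormatError(f"duplicate annotation key {key}")
        out[key] = normalize_generic_number(str(row.iloc[gi]))
    return out


def attach_generic_numbers(cx: Complex,
                           annotation: dict[tuple[str, int], str]) -> Complex:
    """Attach generic numbers to matching residues, in place.

    Annotation keys are (chain, seqnum); residues without a matching
    key keep ``generic_number = None``.  Stale keys are logged and
    ignored; no residue is ever dropped.
    """
    index = {(r.chain, r.seqnum): r for r in cx.residues}
    for key, generic in annotation.items():
        res = index.get((str(key[0]), int(key[1])))
        if res is None:
            logger.warning("annotation key %s does not match any residue; ignored", key)
            continue
        res.generic_number = normalize_generic_number(generic)
    return cx
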