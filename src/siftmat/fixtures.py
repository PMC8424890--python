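"""Synthetic toy complexes with analytically known interaction blocks.

Every module of the package is testable offline: this module builds
single-residue "pair fixtures" that place a small chemical probe
(methane, benzene, methylammonium, acetate, methanol, acetone) at an
exact, user-chosen geometry against an idealized amino-acid template,
and returns both the resulting :class:`~siftmat.structure.Complex` and
the 7×9 block expected under the default geometric criteria.  The
expected block is computed here by a deliberately plain, straight-line
application of the published rules to the constructed coordinates —
independent of the interaction engine — so fixtures double as an
oracle for it.

Residue templates use idealized internal coordinates (standard-ish
bond lengths, sidechain extended along −x, backbone near the origin),
so probe placements along the sidechain axis have exact distances by
construction.  Fixtures can also be written out as standard PDB + MOL
files to exercise the real parsers end to end, jittered into seeded
collections with known cellwise means, or randomized into ≤5-residue
complexes for brute-force equivalence testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from rdkit import Chem
from rdkit.Geometry import Point3D

from ._tables import residue_tables
from .constants import COL_INDEX, N_COLS, N_ROWS, ROW_INDEX
from .engine import GeometryParams, build_matrix
from .matrix import InteractionMatrix, ResidueBlock
from .structure import (Atom, Complex, Ligand, Residue, _ligand_from_rdkit,
                        classify_residue, split_backbone_sidechain)


class FixtureError(Exception):
    pass


# ---------------------------------------------------------------------------
# idealized residue templates
#
# Backbone near the origin (N-H pointing +y, carbonyl toward -y), the
# sidechain extended along -x.  "tip" names the sidechain anchor atom
# that probes are placed against.

_BACKBONE = [
    ("N", "N", (1.20, 0.90, 0.00)),
    ("H", "H", (1.20, 1.90, 0.00)),
    ("CA", "C", (0.00, 0.00, 0.00)),
    ("HA", "H", (-0.30, -0.50, 0.95)),
    ("C", "C", (1.00, -1.10, 0.00)),
    ("O", "O", (0.80, -2.31, 0.00)),
]

_PHE_RING_CENTER = np.array([-2.90, -0.09, 0.00])
_PHE_RING = [
    ("CG", (-2.90, 1.30, 0.00)),
    ("CD1", (-2.90, 0.605, 1.2037)),
    ("CE1", (-2.90, -0.785, 1.2037)),
    ("CZ", (-2.90, -1.48, 0.00)),
    ("CE2", (-2.90, -0.785, -1.2037)),
    ("CD2", (-2.90, 0.605, -1.2037)),
]

TEMPLATES: dict[str, dict] = {
    "GLY": {"atoms": [], "tip": "CA"},
    "ALA": {"atoms": [("CB", "C", (-1.40, 0.55, 0.00))], "tip": "CB"},
    "VAL": {"atoms": [("CB", "C", (-1.40, 0.55, 0.00)),
                      ("CG1", "C", (-2.80, 0.00, 0.00)),
                      ("CG2", "C", (-1.50, 1.30, 1.25))], "tip": "CG1"},
    "LEU": {"atoms": [("CB", "C", (-1.40, 0.55, 0.00)),
                      ("CG", "C", (-2.80, 0.00, 0.00)),
                      ("CD1", "C", (-4.20, 0.55, 0.00)),
                      ("CD2", "C", (-2.90, -0.80, 1.20))], "tip": "CD1"},
    "SER": {"atoms": [("CB", "C", (-1.40, 0.55, 0.00)),
                      ("OG", "O", (-2.68, -0.03, 0.00)),
                      ("HG", "H", (-2.68, -0.03, 0.97))], "tip": "OG"},
    "ASN": {"atoms": [("CB", "C", (-1.40, 0.55, 0.00)),
                      ("CG", "C", (-2.80, 0.00, 0.00)),
                      ("OD1", "O", (-4.02, 0.55, 0.00)),
                      ("ND2", "N", (-3.00, -1.30, 0.30)),
                      ("HD21", "H", (-3.80, -1.85, 0.50)),
                      ("HD22", "H", (-2.90, -2.15, 0.85))], "tip": "OD1"},
    "ASP": {"atoms": [("CB", "C", (-1.40, 0.55, 0.00)),
                      ("CG", "C", (-2.80, 0.00, 0.00)),
                      ("OD1", "O", (-3.95, 0.70, 0.00)),
                      ("OD2", "O", (-3.00, -1.28, 0.25))], "tip": "OD1"},
    "GLU": {"atoms": [("CB", "C", (-1.40, 0.55, 0.00)),
                      ("CG", "C", (-2.80, 0.00, 0.00)),
                      ("CD", "C", (-4.20, 0.55, 0.00)),
                      ("OE1", "O", (-5.42, 0.85, 0.00)),
                      ("OE2", "O", (-4.40, -0.73, 0.25))], "tip": "OE1"},
    "LYS": {"atoms": [("CB", "C", (-1.40, 0.55, 0.00)),
                      ("CG", "C", (-2.80, 0.00, 0.00)),
                      ("CD", "C", (-4.20, 0.55, 0.00)),
                      ("CE", "C", (-5.60, 0.00, 0.00)),
                      ("NZ", "N", (-7.00, 0.55, 0.00)),
                      ("HZ1", "H", (-7.31, 0.67, 0.94)),
                      ("HZ2", "H", (-7.61, -0.09, -0.47)),
                      ("HZ3", "H", (-7.01, 1.43, -0.47))], "tip": "NZ"},
    "ARG": {"atoms": [("CB", "C", (-1.40, 0.55, 0.00)),
                      ("CG", "C", (-2.80, 0.00, 0.00)),
                      ("CD", "C", (-4.20, 0.55, 0.00)),
                      ("NE", "N", (-5.55, 0.05, 0.00)),
                      ("HE", "H", (-5.55, -0.95, 0.10)),
                      ("CZ", "C", (-6.95, 0.50, 0.00)),
                      ("NH1", "N", (-8.20, -0.05, 0.00)),
                      ("HH11", "H", (-9.10, -0.35, 0.00)),
                      ("HH12", "H", (-8.30, -0.65, 0.75)),
                      ("NH2", "N", (-7.10, 1.83, 0.00)),
                      ("HH21", "H", (-7.95, 2.35, 0.00)),
                      ("HH22", "H", (-6.45, 2.55, 0.00))], "tip": "NH1"},
    "PHE": {"atoms": [("CB", "C", (-1.40, 0.55, 0.00))]
            + [(n, "C", xyz) for n, xyz in _PHE_RING],
            "tip": "CG", "ring_center": _PHE_RING_CENTER,
            "ring_normal": np.array([1.0, 0.0, 0.0])},
}

PROBE_NAMES = ("methane", "benzene", "ammonium", "carboxylate",
               "hydroxyl_donor", "carbonyl_acceptor")
_PROBE_ALIASES = {"methyl": "methane", "aromatic_ring": "benzene"}


def make_residue(template: str, chain: str = "A", seqnum: int = 1,
                 rotation: np.ndarray | None = None,
                 translation: np.ndarray | None = None) -> Residue:
    """Instantiate a residue template, optionally rigidly transformed."""
    if template not in TEMPLATES:
        raise FixtureError(f"no template for residue {template!r} "
                           f"(have {sorted(TEMPLATES)})")
    R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
    t = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
    atoms = []
    for name, element, xyz in _BACKBONE + TEMPLATES[template]["atoms"]:
        atoms.append(Atom(name=name, element=element,
                          coords=R @ np.asarray(xyz, dtype=float) + t,
                          is_hydrogen=element == "H"))
    res = Residue(chain=chain, seqnum=seqnum, insertion_code="", name=template,
                  atoms=atoms, classes=classify_residue(template))
    return split_backbone_sidechain(res)


# ---------------------------------------------------------------------------
# probe molecules (built in a local frame, rigidly placed)

def _rotation_from_to(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix taking unit vector a onto unit vector b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180 deg about any perpendicular axis
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-6:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return _axis_rotation(axis, 180.0)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def _axis_rotation(axis: np.ndarray, degrees: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    th = math.radians(degrees)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(th) * K + (1 - math.cos(th)) * K @ K


def _perp_axis(v: np.ndarray) -> np.ndarray:
    """Any unit vector perpendicular to v."""
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, v) / np.linalg.norm(v)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    axis = np.cross(v, ref)
    return axis / np.linalg.norm(axis)


def _tetrahedral_dirs(u: np.ndarray) -> list[np.ndarray]:
    """Three unit vectors at ~109.47 deg from -u (substituent directions
    around a center whose fourth neighbour lies along u)."""
    u = u / np.linalg.norm(u)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, u)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    p1 = np.cross(u, ref)
    p1 /= np.linalg.norm(p1)
    p2 = np.cross(u, p1)
    out = []
    for phi in (90.0, 210.0, 330.0):
        r = math.radians(phi)
        out.append(-u / 3.0 + math.sqrt(8.0) / 3.0
                   * (math.cos(r) * p1 + math.sin(r) * p2))
    return out


def _build_mol(elements, coords, bonds, charges=None) -> Chem.Mol:
    mol = Chem.RWMol()
    for i, el in enumerate(elements):
        a = Chem.Atom(el)
        if charges and charges.get(i):
            a.SetFormalCharge(charges[i])
        mol.AddAtom(a)
    order = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
             3: Chem.BondType.TRIPLE}
    for i, j, o in bonds:
        mol.AddBond(i, j, order[o])
    m = mol.GetMol()
    Chem.SanitizeMol(m)
    conf = Chem.Conformer(m.GetNumAtoms())
    for i, xyz in enumerate(coords):
        conf.SetAtomPosition(i, Point3D(*map(float, xyz)))
    m.AddConformer(conf)
    return m


def _probe_methane(R: np.ndarray, t: np.ndarray) -> Chem.Mol:
    coords = [np.zeros(3)]
    base = np.array([1.0, 1.0, 1.0]) / math.sqrt(3.0)
    coords.append(1.09 * base)
    coords += [1.09 * d for d in _tetrahedral_dirs(base)]
    coords = [R @ c + t for c in coords]
    return _build_mol(["C", "H", "H", "H", "H"], coords,
                      [(0, i, 1) for i in range(1, 5)])


def _probe_benzene(R: np.ndarray, t: np.ndarray) -> Chem.Mol:
    # local frame: ring in the z=0 plane centered at the origin
    elements, coords, bonds = [], [], []
    for k in range(6):
        a = math.radians(60.0 * k)
        radial = np.array([math.cos(a), math.sin(a), 0.0])
        elements.append("C")
        coords.append(1.39 * radial)
    for k in range(6):
        elements.append("H")
        coords.append(2.47 * coords[k] / 1.39)
    for k in range(6):
        bonds.append((k, (k + 1) % 6, 2 if k % 2 == 0 else 1))
        bonds.append((k, k + 6, 1))
    return _build_mol(elements, [R @ c + t for c in coords], bonds)


def _probe_ammonium(R: np.ndarray, t: np.ndarray) -> Chem.Mol:
    # methylammonium; N at the local origin, methyl along -z
    coords = [np.zeros(3), np.array([0.0, 0.0, -1.49])]
    coords += [1.02 * d for d in _tetrahedral_dirs(np.array([0.0, 0.0, -1.0]))]
    coords = [R @ c + t for c in coords]
    return _build_mol(["N", "C", "H", "H", "H"], coords,
                      [(0, 1, 1), (0, 2, 1), (0, 3, 1), (0, 4, 1)],
                      charges={0: 1})


def _probe_carboxylate(R: np.ndarray, t: np.ndarray) -> Chem.Mol:
    # acetate; charged oxygen O1 at the local origin, body along -z
    coords = [np.zeros(3),                       # O1 (-)
              np.array([0.63, 0.0, -1.09]),      # C
              np.array([1.87, 0.0, -1.31]),      # O2 (=O)
              np.array([-0.02, 0.0, -2.44])]     # CH3
    coords = [R @ c + t for c in coords]
    return _build_mol(["O", "C", "O", "C"], coords,
                      [(0, 1, 1), (1, 2, 2), (1, 3, 1)], charges={0: -1})


def _clearest_perp(b: np.ndarray, placer, obstacle_pts: np.ndarray) -> np.ndarray:
    """Among unit vectors perpendicular to ``b``, the one whose placed
    atoms (``placer(p)`` -> coordinate list) clear the obstacles best."""
    p0 = _perp_axis(b)
    p1 = np.cross(b / np.linalg.norm(b), p0)
    best, best_gap = None, -1.0
    for deg in range(0, 360, 15):
        r = math.radians(deg)
        p = math.cos(r) * p0 + math.sin(r) * p1
        gap = min(float(np.linalg.norm(q - x))
                  for q in placer(p) for x in obstacle_pts)
        if gap > best_gap:
            best, best_gap = p, gap
    return best


def _probe_methanol(R: np.ndarray, t: np.ndarray) -> Chem.Mol:
    # hydroxyl donor; H at the local origin, O-H along +z
    h = np.zeros(3)
    o = np.array([0.0, 0.0, -0.97])
    c = o + 1.43 * np.array([math.sin(math.radians(108.5)), 0.0,
                             -math.cos(math.radians(108.5))])
    coords = [R @ p + t for p in (o, c, h)]
    return _build_mol(["O", "C", "H"], coords, [(0, 1, 1), (0, 2, 1)])


def _methanol_at(y: np.ndarray, h: np.ndarray,
                 obstacle_pts: np.ndarray) -> Chem.Mol:
    """Methanol with O at ``y`` and hydroxyl H at ``h``; the methyl
    orientation (free about the O-H axis) maximizes clearance."""
    b = (h - y) / np.linalg.norm(h - y)
    cosg, sing = math.cos(math.radians(108.5)), math.sin(math.radians(108.5))
    p = _clearest_perp(b, lambda p: [y + 1.43 * (cosg * b + sing * p)],
                       obstacle_pts)
    c = y + 1.43 * (cosg * b + sing * p)
    return _build_mol(["O", "C", "H"], [y, c, h], [(0, 1, 1), (0, 2, 1)])


def _probe_acetone(R: np.ndarray, t: np.ndarray) -> Chem.Mol:
    # carbonyl acceptor; O at the local origin, C=O along +z
    o = np.zeros(3)
    c = np.array([0.0, 0.0, -1.22])
    m1 = c + np.array([1.30, 0.0, -0.76])
    m2 = c + np.array([-1.30, 0.0, -0.76])
    coords = [R @ p + t for p in (o, c, m1, m2)]
    return _build_mol(["O", "C", "C", "C"], coords,
                      [(0, 1, 2), (1, 2, 1), (1, 3, 1)])


def _acetone_at(x: np.ndarray, axis: np.ndarray,
                obstacle_pts: np.ndarray) -> Chem.Mol:
    """Acetone with carbonyl O at ``x`` and the O→C direction along
    ``axis``; methyl orientation maximizes clearance."""
    axis = axis / np.linalg.norm(axis)
    c = x + 1.22 * axis

    def methyls(p):
        return [c + 1.30 * p + 0.76 * axis, c - 1.30 * p + 0.76 * axis]

    p = _clearest_perp(axis, methyls, obstacle_pts)
    m1, m2 = methyls(p)
    return _build_mol(["O", "C", "C", "C"], [x, c, m1, m2],
                      [(0, 1, 2), (1, 2, 1), (1, 3, 1)])


_PROBE_BUILDERS = {
    "methane": _probe_methane,
    "benzene": _probe_benzene,
    "ammonium": _probe_ammonium,
    "carboxylate": _probe_carboxylate,
    "hydroxyl_donor": _probe_methanol,
    "carbonyl_acceptor": _probe_acetone,
}


# ---------------------------------------------------------------------------
# pair fixtures

@dataclass(frozen=True)
class FixtureSpec:
    """One probe placed against one residue template.

    ``distance`` is the probe anchor's distance to the residue anchor
    (sidechain tip, ring centroid, charged group or hydrogen-bond
    partner, depending on the probe).  ``angle`` is the interplanar
    angle for ring stacking; ``donor_dev``/``acceptor_dev`` are angular
    deviations from ideal hydrogen-bond geometry, in degrees.
    """

    probe: str
    residue: str
    distance: float
    angle: float = 0.0
    donor_dev: float = 0.0
    acceptor_dev: float = 0.0
    seed: int = 0

    def canonical_probe(self) -> str:
        name = _PROBE_ALIASES.get(self.probe, self.probe)
        if name not in _PROBE_BUILDERS:
            raise FixtureError(f"unknown probe {self.probe!r}")
        return name


@dataclass
class PairFixture:
    spec: FixtureSpec
    complex: Complex
    expected: ResidueBlock
    params: GeometryParams


_MINUS_X = np.array([-1.0, 0.0, 0.0])
_CLASH_DIST = 1.0


def _template_coord(template: str, atom: str) -> np.ndarray:
    for name, _, xyz in _BACKBONE + TEMPLATES[template]["atoms"]:
        if name == atom:
            return np.asarray(xyz, dtype=float)
    raise FixtureError(f"{template} has no atom {atom}")


def _acceptor_ideal_dir(template: str, acceptor: str, tables: dict) -> np.ndarray:
    """Unit direction of ideal hydrogen approach to a residue acceptor:
    opposite the mean direction of its covalently bonded heavy atoms."""
    x = _template_coord(template, acceptor)
    dirs = []
    for name, element, xyz in _BACKBONE + TEMPLATES[template]["atoms"]:
        if element == "H" or name == acceptor:
            continue
        v = np.asarray(xyz, dtype=float) - x
        cutoff = 2.1 if "S" in (element,) else 1.8
        if np.linalg.norm(v) <= cutoff:
            dirs.append(v / np.linalg.norm(v))
    if not dirs:
        raise FixtureError(f"{template}.{acceptor}: no antecedent found")
    mean = np.mean(dirs, axis=0)
    return -mean / np.linalg.norm(mean)


def _place_probe(spec: FixtureSpec, residue: Residue,
                 tables: dict) -> tuple[Chem.Mol, dict]:
    """Build the probe molecule at the requested geometry (in the
    residue template frame) and return geometry handles for the
    expected-block computation."""
    probe = spec.canonical_probe()
    template = spec.residue
    d = spec.distance
    info: dict = {}

    if probe == "methane":
        # C at the requested distance from the sidechain tip, one C-H
        # bond pointing away from the residue
        anchor = _template_coord(template, TEMPLATES[template]["tip"])
        mol = _probe_methane(_rotation_from_to(np.array([1.0, 1.0, 1.0]),
                                               _MINUS_X),
                             anchor + d * _MINUS_X)

    elif probe == "benzene":
        if "ring_center" in TEMPLATES[template]:
            # stacking against an aromatic residue: centroid along the
            # residue ring normal, probe plane tilted by spec.angle
            center = TEMPLATES[template]["ring_center"] + d * _MINUS_X
            normal = _axis_rotation([0.0, 1.0, 0.0], spec.angle) \
                @ np.array([1.0, 0.0, 0.0])
            mol = _probe_benzene(_rotation_from_to(np.array([0.0, 0.0, 1.0]),
                                                   normal), center)
            info["probe_ring"] = (center, normal)
        else:
            # pi-cation: centroid at distance d from the cation centroid
            group = _charged_group(template, tables)
            if group is None:
                raise FixtureError(
                    f"benzene probe needs an aromatic or charged residue, "
                    f"not {template}")
            cation = group.mean(axis=0)
            center = cation + d * _MINUS_X
            mol = _probe_benzene(_rotation_from_to([0.0, 0.0, 1.0],
                                                   [1.0, 0.0, 0.0]), center)
            info["probe_ring"] = (center, np.array([1.0, 0.0, 0.0]))

    elif probe == "ammonium":
        if "ring_center" in TEMPLATES[template]:
            anchor = TEMPLATES[template]["ring_center"]
        else:
            anchor = _template_coord(template, TEMPLATES[template]["tip"])
        mol = _probe_ammonium(_rotation_from_to([0.0, 0.0, 1.0],
                                                [1.0, 0.0, 0.0]),
                              anchor + d * _MINUS_X)

    elif probe == "carboxylate":
        anchor = _template_coord(template, TEMPLATES[template]["tip"])
        mol = _probe_carboxylate(_rotation_from_to([0.0, 0.0, 1.0],
                                                   [1.0, 0.0, 0.0]),
                                 anchor + d * _MINUS_X)

    elif probe == "hydroxyl_donor":
        acceptor = TEMPLATES[template]["tip"]
        x = _template_coord(template, acceptor)
        approach = _acceptor_ideal_dir(template, acceptor, tables)
        w = _axis_rotation(_perp_axis(approach), spec.acceptor_dev) @ approach
        h = x + d * w
        u = _axis_rotation(_perp_axis(w), spec.donor_dev) @ w
        y = h + 0.97 * u
        res_pts = np.array([a.coords for a in residue.atoms])
        mol = _methanol_at(y, h, res_pts)
        info["donor"] = (y, h)

    elif probe == "carbonyl_acceptor":
        pair = {"SER": ("OG", "HG"), "ASN": ("ND2", "HD21"),
                "LYS": ("NZ", "HZ1")}.get(template)
        if pair is None:
            raise FixtureError(
                f"carbonyl_acceptor probe supports SER/ASN/LYS, not {template}")
        yc = _template_coord(template, pair[0])
        hc = _template_coord(template, pair[1])
        w = (hc - yc) / np.linalg.norm(hc - yc)  # donor H direction
        x = hc + d * w
        # C=O axis anti-aligned with the incoming hydrogen (ideal when
        # acceptor_dev = 0)
        axis = _axis_rotation(_perp_axis(w), spec.acceptor_dev) @ w
        res_pts = np.array([a.coords for a in residue.atoms])
        mol = _acetone_at(x, axis, res_pts)
        info["acceptor_x"] = x

    else:  # pragma: no cover
        raise FixtureError(probe)
    return mol, info


def _charged_group(template: str, tables: dict) -> np.ndarray | None:
    names = tables["charged_group"].get(template, [])
    if not names:
        return None
    return np.array([_template_coord(template, n) for n in names])


# --- straight-line expected-block computation ------------------------------

def _mind(a: np.ndarray, b: np.ndarray) -> float:
    a, b = np.atleast_2d(a), np.atleast_2d(b)
    return min(float(np.linalg.norm(p - q)) for p in a for q in b)


def _ang(a, vertex, c) -> float:
    v1, v2 = np.asarray(a) - vertex, np.asarray(c) - vertex
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


@dataclass
class _RefFeature:
    type: str
    coords: np.ndarray                    # heavy member atoms
    centroid: np.ndarray | None = None
    normal: np.ndarray | None = None
    donor_hs: list | None = None          # H coords (D features)
    antecedents: dict | None = None       # member idx -> list of coords (A)


def _reference_features(probe: str, mol: Chem.Mol) -> list[_RefFeature]:
    """Feature content of each probe, known by construction (no SMARTS)."""
    conf = mol.GetConformer()
    pos = np.array([list(conf.GetAtomPosition(i))
                    for i in range(mol.GetNumAtoms())])
    feats: list[_RefFeature] = []
    if probe == "methane":
        feats.append(_RefFeature("H", pos[[0]]))
    elif probe == "benzene":
        ring = pos[:6]
        center = ring.mean(axis=0)
        normal = np.cross(ring[1] - ring[0], ring[2] - ring[0])
        normal /= np.linalg.norm(normal)
        feats.append(_RefFeature("R", ring, centroid=center, normal=normal))
        feats.append(_RefFeature("H", ring, centroid=center))
    elif probe == "ammonium":
        feats.append(_RefFeature("P", pos[[0]], centroid=pos[0]))
        feats.append(_RefFeature("D", pos[[0]], donor_hs=[pos[2], pos[3], pos[4]]))
    elif probe == "carboxylate":
        feats.append(_RefFeature("N", pos[[1, 0, 2]]))
        feats.append(_RefFeature("A", pos[[0]], antecedents={0: [pos[1]]}))
        feats.append(_RefFeature("A", pos[[2]], antecedents={0: [pos[1]]}))
        feats.append(_RefFeature("H", pos[[3]]))
    elif probe == "hydroxyl_donor":
        feats.append(_RefFeature("A", pos[[0]], antecedents={0: [pos[1]]}))
        feats.append(_RefFeature("D", pos[[0]], donor_hs=[pos[2]]))
    elif probe == "carbonyl_acceptor":
        feats.append(_RefFeature("A", pos[[0]], antecedents={0: [pos[1]]}))
        feats.append(_RefFeature("H", pos[[2]]))
        feats.append(_RefFeature("H", pos[[3]]))
    else:  # pragma: no cover
        raise FixtureError(probe)
    return feats


def _reference_block(features: list[_RefFeature], residue: Residue,
                     ligand_heavy: np.ndarray, params: GeometryParams,
                     tables: dict) -> np.ndarray:
    """Plain application of every published criterion; no masks, no
    shortcuts — cells are written directly per the incrementation rules."""
    eps = params.boundary_eps
    counts = np.zeros((N_ROWS, N_COLS), dtype=np.int64)
    cname = tables["aliases"].get(residue.name, residue.name)
    classes = residue.classes

    bb = residue.heavy_coords("backbone")
    sc = residue.heavy_coords("sidechain")
    cs_side = np.array([a.coords for a in residue.sidechain_atoms
                        if not a.is_hydrogen and a.element in ("C", "S")])
    polar_atoms = np.array([a.coords for a in residue.find_atoms(
        tables["polar_sidechain"].get(cname, [])) if not a.is_hydrogen])
    charged = np.array([a.coords for a in residue.find_atoms(
        tables["charged_group"].get(cname, [])) if not a.is_hydrogen])

    donors = []  # (heavy coords, [H coords], is_backbone)
    for a in residue.backbone_atoms:
        if a.name == "N" and not a.is_hydrogen:
            donors.append((a.coords,
                           [h.coords for h in residue.hydrogens_bonded_to(a)], True))
    for nm in tables["donors"].get(cname, []):
        for a in residue.find_atoms([nm]):
            if not a.is_hydrogen:
                donors.append((a.coords,
                               [h.coords for h in residue.hydrogens_bonded_to(a)],
                               False))
    acceptors = []  # (coords, [antecedent coords], is_backbone)
    for a in residue.backbone_atoms:
        if a.name in ("O", "OXT") and not a.is_hydrogen:
            acceptors.append((a.coords, _res_antecedents(residue, a), True))
    for nm in tables["acceptors"].get(cname, []):
        for a in residue.find_atoms([nm]):
            if not a.is_hydrogen:
                acceptors.append((a.coords, _res_antecedents(residue, a), False))
    rings = []
    for names in tables["aromatic_rings"].get(cname, []):
        ats = [a.coords for a in residue.find_atoms(names) if not a.is_hydrogen]
        if len(ats) >= 3:
            ats = np.array(ats)
            n = np.cross(ats[1] - ats[0], ats[2] - ats[0])
            rings.append((ats.mean(axis=0), n / np.linalg.norm(n)))
    cation = charged.mean(axis=0) if ("positively_charged" in classes
                                      and charged.size) else None

    def hb(y, hs, x, ante) -> bool:
        for h in hs:
            if np.linalg.norm(h - x) > params.hbond_dist + eps:
                continue
            if 180.0 - _ang(y, h, x) > params.hbond_donor_angle_max + eps:
                continue
            if ante:
                mean = np.mean([(p - x) / np.linalg.norm(p - x) for p in ante],
                               axis=0)
                if np.linalg.norm(mean) > 1e-8:
                    if 180.0 - _ang(x + mean, x, h) \
                            > params.hbond_acceptor_angle_max + eps:
                        continue
            return True
        return False

    def put(row: str, cols: set[str]):
        if not cols:
            return
        for col in cols | {"Any"}:
            counts[ROW_INDEX[row], COL_INDEX[col]] += 1

    for f in features:
        cols: set[str] = set()
        if f.type == "A":
            bonded = False
            for y, hs, is_bb in donors:
                for i, x in enumerate(f.coords):
                    ante = (f.antecedents or {}).get(i, [])
                    if hs and hb(y, hs, x, ante):
                        bonded = True
                        cols |= {"D", "BB" if is_bb else "SC"}
            if not bonded and "polar" in classes and polar_atoms.size \
                    and _mind(f.coords, polar_atoms) <= params.contact_dist + eps:
                cols |= {"P", "SC"}
        elif f.type == "D":
            bonded = False
            for i, y in enumerate(f.coords):
                for x, ante, is_bb in acceptors:
                    if hb(y, f.donor_hs or [], x, ante):
                        bonded = True
                        cols |= {"A", "BB" if is_bb else "SC"}
            if not bonded and "polar" in classes and polar_atoms.size \
                    and _mind(f.coords, polar_atoms) <= params.contact_dist + eps:
                cols |= {"P", "SC"}
        elif f.type == "H":
            if "hydrophobic" in classes and cs_side.size \
                    and _mind(f.coords, cs_side) <= params.contact_dist + eps:
                cols |= {"H", "SC"}
        elif f.type == "N":
            if "positively_charged" in classes and charged.size \
                    and _mind(f.coords, charged) <= params.contact_dist + eps:
                cols |= {"C", "SC"}
        elif f.type == "P":
            if "negatively_charged" in classes and charged.size \
                    and _mind(f.coords, charged) <= params.contact_dist + eps:
                cols |= {"C", "SC"}
            for rc, _ in rings:
                if np.linalg.norm(rc - f.centroid) <= params.pi_cation_dist + eps:
                    cols |= {"R", "SC"}
        elif f.type == "R":
            for rc, rn in rings:
                dd = np.linalg.norm(rc - f.centroid)
                th = math.degrees(math.acos(
                    min(1.0, abs(float(np.dot(rn, f.normal))))))
                if (dd <= params.pi_ff_dist + eps
                        and th <= params.pi_ff_angle_max + eps) or \
                   (dd <= params.pi_ef_dist + eps
                        and th >= params.pi_ef_angle_min - eps):
                    cols |= {"R", "SC"}
            if cation is not None and \
                    np.linalg.norm(f.centroid - cation) <= params.pi_cation_dist + eps:
                cols |= {"R", "SC"}
            if "hydrophobic" in classes and cs_side.size \
                    and _mind(f.coords, cs_side) <= params.contact_dist + eps:
                cols |= {"H", "SC"}
        put(f.type, cols)

    vdw: set[str] = set()
    if bb.size and _mind(ligand_heavy, bb) <= params.contact_dist + eps:
        vdw |= {"BB"}
    if sc.size and _mind(ligand_heavy, sc) <= params.contact_dist + eps:
        vdw |= {"SC"}
    put("vdW", vdw)
    return counts


def _res_antecedents(residue: Residue, acceptor: Atom) -> list[np.ndarray]:
    out = []
    for a in residue.atoms:
        if a.is_hydrogen or a is acceptor:
            continue
        cutoff = 2.1 if "S" in (a.element, acceptor.element) else 1.8
        if np.linalg.norm(a.coords - acceptor.coords) <= cutoff:
            out.append(a.coords)
    return out


def make_pair_fixture(spec: FixtureSpec,
                      params: GeometryParams | None = None) -> PairFixture:
    """Build a one-residue complex with the probe at the exact requested
    geometry, plus the analytically expected 7×9 block."""
    params = params or GeometryParams()
    tables = residue_tables()
    residue = make_residue(spec.residue, seqnum=1)
    mol, _ = _place_probe(spec, residue, tables)
    ligand = _ligand_from_rdkit(mol, "mol")
    lig_heavy = ligand.coords(ligand.heavy_indices())
    res_pts = np.array([a.coords for a in residue.atoms])
    all_lig = np.array([a.coords for a in ligand.atoms])
    if _mind(all_lig, res_pts) < _CLASH_DIST:
        raise FixtureError(
            f"unrealizable placement: probe clashes with {spec.residue} "
            f"(closest approach {_mind(all_lig, res_pts):.2f} Å)")
    features = _reference_features(spec.canonical_probe(), mol)
    expected = ResidueBlock(
        counts=_reference_block(features, residue, lig_heavy, params, tables),
        residue_key=residue.key)
    cx = Complex(residues=[residue], ligand=ligand,
                 identifier=f"{spec.canonical_probe()}-{spec.residue}-"
                            f"{spec.distance:g}")
    return PairFixture(spec=spec, complex=cx, expected=expected, params=params)


# ---------------------------------------------------------------------------
# fixture files (PDB + MOL), exercising the real parsers

def residues_to_pdb(residues: list[Residue]) -> str:
    lines = []
    serial = 1
    for r in residues:
        for a in r.atoms:
            name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
            x, y, z = a.coords
            lines.append(
                f"ATOM  {serial:5d} {name:<4s}{'':1s}{r.name:>3s} "
                f"{r.chain:1s}{r.seqnum:4d}{r.insertion_code or '':1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {a.element:>2s}")
            serial += 1
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_pair_fixture(spec: FixtureSpec, directory) -> tuple[str, str]:
    """Emit the fixture as standard PDB (protein) + MOL (ligand) files;
    returns the two paths."""
    from pathlib import Path
    fixture = make_pair_fixture(spec)
    base = Path(directory) / fixture.complex.identifier.replace("/", "_")
    pdb_path, mol_path = f"{base}.pdb", f"{base}.mol"
    with open(pdb_path, "w") as fh:
        fh.write(residues_to_pdb(fixture.complex.residues))
    with open(mol_path, "w") as fh:
        fh.write(Chem.MolToMolBlock(fixture.complex.ligand.mol))
    return pdb_path, mol_path


# ---------------------------------------------------------------------------
# collections with known averages

def make_collection(spec: FixtureSpec, n: int, n_active: int,
                    jitter: float = 0.05, seed: int = 0,
                    generic_number: str | None = None,
                    params: GeometryParams | None = None,
                    ) -> tuple[list[InteractionMatrix], np.ndarray]:
    """A collection of ``n`` matrices in which the probe interacts in
    exactly ``n_active`` (the rest are displaced 5 Å out of range), so
    the cellwise mean is known exactly:
    ``expected_active_block * n_active / n``.

    Jitter perturbs the placement distance within ``±jitter`` Å; it must
    keep a 0.1 Å guard margin from every relevant decision boundary,
    otherwise a :class:`FixtureError` is raised.  Seeded, reproducible.
    """
    if not 0 <= n_active <= n:
        raise FixtureError("need 0 <= n_active <= n")
    params = params or GeometryParams()
    boundaries = [params.contact_dist, params.hbond_dist, params.pi_ff_dist,
                  params.pi_ef_dist, params.pi_cation_dist]
    gap = min(abs(spec.distance - b) for b in boundaries)
    if jitter > gap - 0.1:
        raise FixtureError(
            f"jitter {jitter} Å violates the 0.1 Å guard margin (distance "
            f"{spec.distance} Å is {gap:.2f} Å from the nearest boundary)")
    rng = np.random.default_rng(seed)
    base = make_pair_fixture(spec, params)
    matrices = []
    for i in range(n):
        d = spec.distance + (0.0 if jitter == 0 else rng.uniform(-jitter, jitter))
        if i >= n_active:
            d += 5.0
        fx = make_pair_fixture(replace(spec, distance=float(d)), params)
        if i < n_active and not np.array_equal(fx.expected.counts,
                                               base.expected.counts):
            raise FixtureError("jitter changed the expected detector outcome")
        if i >= n_active and fx.expected.counts.any():
            raise FixtureError("displaced (inactive) fixture still interacts")
        cx = fx.complex
        cx.identifier = f"{cx.identifier}#{i}"
        if generic_number:
            cx.residues[0].generic_number = generic_number
        matrices.append(build_matrix(cx, params))
    expected_mean = base.expected.counts * (n_active / n)
    return matrices, expected_mean


# ---------------------------------------------------------------------------
# random small complexes (for brute-force equivalence testing)

def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)]])


def make_random_complex(seed: int, max_residues: int = 5) -> Complex:
    """A randomly assembled complex: one random probe at a random
    orientation, 1..max_residues randomly chosen templates placed at
    random distances (2.5–8.5 Å) and orientations around it.  Detection
    outcomes are NOT known in advance — these fixtures exist for
    equivalence testing against an independent oracle."""
    rng = np.random.default_rng(seed)
    probe = PROBE_NAMES[rng.integers(len(PROBE_NAMES))]
    mol = _PROBE_BUILDERS[probe](_random_rotation(rng), rng.uniform(-1, 1, 3))
    ligand = _ligand_from_rdkit(mol, "mol")
    lig_pts = np.array([a.coords for a in ligand.atoms])
    names = sorted(TEMPLATES)
    residues = []
    n_res = int(rng.integers(1, max_residues + 1))
    seq = 1
    while len(residues) < n_res:
        template = names[rng.integers(len(names))]
        R = _random_rotation(rng)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        r = rng.uniform(2.5, 8.5)
        anchor = lig_pts[rng.integers(len(lig_pts))]
        tip = _template_coord(template, TEMPLATES[template]["tip"])
        t = anchor + r * direction - R @ tip
        res = make_residue(template, seqnum=seq, rotation=R, translation=t)
        if _mind(lig_pts, np.array([a.coords for a in res.atoms])) < _CLASH_DIST:
            continue
        residues.append(res)
        seq += 1
    residues.sort(key=lambda r: (r.chain, r.seqnum, r.insertion_code))
    return Complex(residues=residues, ligand=ligand,
                   identifier=f"random-{seed}")


# ---------------------------------------------------------------------------
# showcase complex: aryloxy-propanolamine-like probe vs ASP/SER/PHE

def make_showcase_complex() -> tuple[Complex, InteractionMatrix]:
    """A three-residue binding-site miniature mimicking an aminergic
    pocket: a protonated amine anchored by an aspartate, an ether oxygen
    accepting a serine hydrogen bond, and an aromatic ring stacked
    face-to-face on a phenylalanine.  Returns the complex and the
    hand-derived expected matrix."""
    # ligand: [NH3+]-CH2-CH2-O-CH2-phenyl, ring centered at the origin
    ring = [1.39 * np.array([0.0, math.cos(math.radians(60 * k)),
                             math.sin(math.radians(60 * k))]) for k in range(6)]
    c3 = np.array([0.0, 2.80, 0.55])   # benzylic CH2
    o = np.array([0.0, 4.20, 0.35])    # ether O
    c2 = np.array([0.0, 5.60, 0.00])
    c1 = np.array([0.0, 6.60, 1.05])
    n = np.array([0.0, 8.05, 1.10])
    hs = [n + 1.02 * d for d in _tetrahedral_dirs((c1 - n) / np.linalg.norm(c1 - n))]
    elements = ["C"] * 6 + ["C", "O", "C", "C", "N", "H", "H", "H"]
    coords = ring + [c3, o, c2, c1, n] + hs
    bonds = [(k, (k + 1) % 6, 2 if k % 2 == 0 else 1) for k in range(6)]
    bonds += [(0, 6, 1), (6, 7, 1), (7, 8, 1), (8, 9, 1), (9, 10, 1),
              (10, 11, 1), (10, 12, 1), (10, 13, 1)]
    mol = _build_mol(elements, coords, bonds, charges={10: 1})
    ligand = _ligand_from_rdkit(mol, "mol")

    # ASP above the ammonium (carboxylate O 3.3 Å from N, body along +z)
    asp_tip = _template_coord("ASP", "OD1")
    r_asp = _rotation_from_to([-1.0, 0.0, 0.0], [0.0, 0.0, -1.0])
    asp = make_residue("ASP", seqnum=10, rotation=r_asp,
                       translation=n + 3.3 * np.array([0.0, 0.0, 1.0])
                       - r_asp @ asp_tip)

    # SER donating to the ether O along its ideal acceptor direction
    # (opposite the mean direction of the oxygen's bonded carbons)
    ante = np.mean([(c2 - o) / np.linalg.norm(c2 - o),
                    (c3 - o) / np.linalg.norm(c3 - o)], axis=0)
    v = -ante / np.linalg.norm(ante)           # ideal H approach direction
    og = o + 2.97 * v                          # O···OG 2.97, H···O 2.00 Å
    hg_local = _template_coord("SER", "HG") - _template_coord("SER", "OG")
    r_ser = _rotation_from_to(hg_local / np.linalg.norm(hg_local), -v)
    ser = make_residue("SER", seqnum=20, rotation=r_ser,
                       translation=og - r_ser @ _template_coord("SER", "OG"))

    # PHE stacked face-to-face at 4.0 Å along the ligand ring normal
    phe = make_residue("PHE", seqnum=30,
                       translation=np.array([4.0, 0.0, 0.0])
                       - np.asarray(_PHE_RING_CENTER))

    cx = Complex(residues=[asp, ser, phe], ligand=ligand,
                 identifier="showcase")

    def block(cells: dict[tuple[str, str], int], res: Residue) -> ResidueBlock:
        counts = np.zeros((N_ROWS, N_COLS), dtype=np.int64)
        for (row, col), v in cells.items():
            counts[ROW_INDEX[row], COL_INDEX[col]] = v
        return ResidueBlock(counts=counts, residue_key=res.key)

    # the ammonium both salt-bridges the carboxylate and donates a
    # hydrogen bond to it, as a protonated amine genuinely does
    expected = InteractionMatrix(blocks=[
        block({("P", "C"): 1, ("P", "SC"): 1, ("P", "Any"): 1,
               ("D", "A"): 1, ("D", "SC"): 1, ("D", "Any"): 1,
               ("vdW", "Any"): 1, ("vdW", "SC"): 1}, asp),
        block({("A", "D"): 1, ("A", "SC"): 1, ("A", "Any"): 1,
               ("vdW", "Any"): 1, ("vdW", "SC"): 1}, ser),
        block({("R", "R"): 1, ("R", "SC"): 1, ("R", "Any"): 1}, phe),
    ], complex_id="showcase")
    return cx, expected


# ---------------------------------------------------------------------------
# boundary sweeps (used by the acceptance harness and the CLI)

def _cell_detected(spec: FixtureSpec, row: str, col: str,
                   params: GeometryParams) -> bool:
    fx = make_pair_fixture(spec, params)
    m = build_matrix(fx.complex, params)
    return m.blocks[0].counts[ROW_INDEX[row], COL_INDEX[col]] > 0


def sweep_boundary(values, make_spec, row: str, col: str,
                   params: GeometryParams | None = None,
                   extreme: str = "max") -> float | None:
    """Run the full pipeline across a parameter sweep and return the
    largest (or smallest) value at which the given cell is set."""
    params = params or GeometryParams()
    detected = [float(v) for v in values
                if _cell_detected(make_spec(float(v)), row, col, params)]
    if not detected:
        return None
    return max(detected) if extreme == "max" else min(detected)


def boundary_sweeps(params: GeometryParams | None = None,
                    step_scale: int = 1) -> dict[str, dict]:
    """All boundary-probe sweeps for the printed geometric criteria.

    Each entry sweeps one fixture parameter at 0.01 Å / 0.1° resolution
    (coarser when ``step_scale`` > 1) and reports the extreme value at
    which the corresponding interaction is still detected.
    """
    params = params or GeometryParams()

    def rng(lo, hi, step):
        step *= step_scale
        n = int(round((hi - lo) / step)) + 1
        return np.round(np.linspace(lo, hi, n), 6)

    sweeps = {
        "contact_max_dist": dict(
            values=rng(3.00, 4.00, 0.01), extreme="max", row="vdW", col="Any",
            spec=lambda v: FixtureSpec("methane", "LEU", v)),
        "hbond_max_dist": dict(
            values=rng(2.50, 3.20, 0.01), extreme="max", row="D", col="A",
            spec=lambda v: FixtureSpec("hydroxyl_donor", "SER", v)),
        "hbond_max_donor_dev": dict(
            values=rng(100.0, 140.0, 0.1), extreme="max", row="D", col="A",
            spec=lambda v: FixtureSpec("hydroxyl_donor", "SER", 2.0,
                                       donor_dev=v)),
        "hbond_max_acceptor_dev": dict(
            values=rng(70.0, 110.0, 0.1), extreme="max", row="D", col="A",
            spec=lambda v: FixtureSpec("hydroxyl_donor", "SER", 2.0,
                                       acceptor_dev=v)),
        "pi_ff_max_dist": dict(
            values=rng(4.00, 5.00, 0.01), extreme="max", row="R", col="R",
            spec=lambda v: FixtureSpec("benzene", "PHE", v, angle=0.0)),
        "pi_ef_max_dist": dict(
            values=rng(5.00, 6.00, 0.01), extreme="max", row="R", col="R",
            spec=lambda v: FixtureSpec("benzene", "PHE", v, angle=90.0)),
        "pi_cation_max_dist": dict(
            values=rng(6.00, 7.00, 0.01), extreme="max", row="R", col="R",
            spec=lambda v: FixtureSpec("benzene", "LYS", v)),
        "pi_ff_max_angle": dict(
            values=rng(20.0, 40.0, 0.1), extreme="max", row="R", col="R",
            spec=lambda v: FixtureSpec("benzene", "PHE", 4.0, angle=v)),
        "pi_ef_min_angle": dict(
            values=rng(50.0, 70.0, 0.1), extreme="min", row="R", col="R",
            spec=lambda v: FixtureSpec("benzene", "PHE", 5.0, angle=v)),
    }
    out = {}
    for name, sw in sweeps.items():
        value = sweep_boundary(sw["values"], sw["spec"], sw["row"], sw["col"],
                               params, sw["extreme"])
        out[name] = {"value": value, "n": len(sw["values"])}
    return out
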