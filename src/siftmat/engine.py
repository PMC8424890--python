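"""Geometric interaction detection and block construction.

For every residue of the complex, each ligand pharmacophore feature is
tested against the geometric criteria of the interaction types it can
form, and the firing detectors increment cells of the residue's 7×9
block.  All cutoffs are inclusive (a contact exactly at the cutoff
counts) and guarded by a small numerical epsilon so that rigid-body
transforms of the whole complex cannot flip a boundary case.

Default criteria:

* plain / hydrophobic / charged / polar contact: minimum heavy-atom
  distance <= 3.5 Å (plus feature/residue-class complementarity),
* hydrogen bond: H···acceptor distance <= 2.8 Å, donor deviation from
  linearity 180° − ∠(Y–H···X) <= 120°, acceptor deviation
  180° − ∠(antecedent–X···H) <= 90°,
* aromatic stacking: centroid separation <= 4.4 Å with interplanar
  angle <= 30° (face-to-face, takes precedence) or <= 5.5 Å with angle
  >= 60° (edge-to-face),
* π–cation: ring-centroid to cation-centroid distance <= 6.6 Å, no
  angle criterion, evaluated in both directions.

Redundancy rules: a feature instance increments a given cell at most
once per residue; a hydrogen bond suppresses the additional polar
increment for the same feature–residue pair; face-to-face takes
precedence over edge-to-face; the wildcard (vdW) row increments each
region column at most once per residue however many atoms touch.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass

import numpy as np
from scipy.spatial.distance import cdist

from ._tables import default_mask_spec, mask_array, residue_tables
from .constants import COL_INDEX, N_COLS, N_ROWS, ROW_INDEX
from .matrix import InteractionMatrix, ResidueBlock
from .pharmacophore import (GeometryError, PharmacophoreFeature, assign_features,
                            best_fit_plane)
from .structure import Atom, Complex, Residue

logger = logging.getLogger(__name__)

#: covalent-neighbour cutoff used to find an acceptor's antecedent
#: heavy atom(s) on the residue side (no explicit residue topology)
_COVALENT_MAX = 1.8
_COVALENT_MAX_S = 2.1  # sulfur bonds are longer


@dataclass(frozen=True)
class GeometryParams:
    """Distance/angle criteria of the interaction detectors (Å, degrees).

    ``hbond_distance_mode`` selects whether ``hbond_dist`` bounds the
    hydrogen-to-acceptor distance (default) or the donor-heavy to
    acceptor-heavy distance.  ``degraded_hbond_pad`` is added to
    ``hbond_dist`` in the distance-only fallback used when a donor has
    no resolvable hydrogens (heavy–heavy distance is then tested).
    ``boundary_eps`` is the inclusive-boundary numerical guard.
    """

    contact_dist: float = 3.5
    hbond_dist: float = 2.8
    hbond_donor_angle_max: float = 120.0
    hbond_acceptor_angle_max: float = 90.0
    pi_ff_dist: float = 4.4
    pi_ef_dist: float = 5.5
    pi_cation_dist: float = 6.6
    pi_ff_angle_max: float = 30.0
    pi_ef_angle_min: float = 60.0
    hbond_distance_mode: str = "hydrogen_acceptor"  # or "heavy_heavy"
    degraded_hbond_pad: float = 1.0
    boundary_eps: float = 1e-9

    def __post_init__(self):
        for name in ("contact_dist", "hbond_dist", "pi_ff_dist", "pi_ef_dist",
                     "pi_cation_dist"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("hbond_donor_angle_max", "hbond_acceptor_angle_max",
                     "pi_ff_angle_max", "pi_ef_angle_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 180.0:
                raise ValueError(f"{name} must lie in [0, 180] degrees")
        if self.hbond_distance_mode not in ("hydrogen_acceptor", "heavy_heavy"):
            raise ValueError("hbond_distance_mode must be "
                             "'hydrogen_acceptor' or 'heavy_heavy'")


def params_fingerprint(params: GeometryParams,
                       mask_spec=None) -> str:
    """Short stable hash of the geometry parameters and increment mask,
    stored on every matrix to guard against mixing incompatible ones."""
    mask_spec = mask_spec or default_mask_spec()
    payload = json.dumps({"params": asdict(params),
                          "mask": [[r, list(c)] for r, c in mask_spec]},
                         sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# geometric primitives

def min_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum pairwise Euclidean distance between two coordinate sets."""
    a, b = np.atleast_2d(a), np.atleast_2d(b)
    if a.size == 0 or b.size == 0:
        raise ValueError("min_distance requires two non-empty coordinate sets")
    return float(cdist(a, b).min())


def _le(value: float, limit: float, eps: float) -> bool:
    return value <= limit + eps


def _ge(value: float, limit: float, eps: float) -> bool:
    return value >= limit - eps


def angle_deg(a: np.ndarray, vertex: np.ndarray, c: np.ndarray) -> float:
    """Angle at ``vertex`` in degrees."""
    v1, v2 = a - vertex, c - vertex
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise GeometryError("degenerate angle (coincident points)")
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def interplanar_angle(n1: np.ndarray, n2: np.ndarray) -> float:
    """Angle between two ring planes, folded to [0°, 90°] (normal signs
    are arbitrary)."""
    cosang = abs(np.clip(np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2)),
                         -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))


# ---------------------------------------------------------------------------
# individual detectors

def detect_contact(ligand_coords: np.ndarray, residue: Residue,
                   params: GeometryParams) -> dict[str, bool]:
    """Plain-contact (vdW) flags per residue region."""
    flags = {}
    for region in ("all", "backbone", "sidechain"):
        pts = residue.heavy_coords(region)
        flags[region] = bool(pts.size) and _le(
            min_distance(ligand_coords, pts), params.contact_dist, params.boundary_eps)
    return {"any": flags["all"], "backbone": flags["backbone"],
            "sidechain": flags["sidechain"]}


def detect_hbond(donor_heavy: np.ndarray, donor_hydrogens: list[np.ndarray],
                 acceptor: np.ndarray, acceptor_antecedents: list[np.ndarray],
                 params: GeometryParams) -> bool:
    """Hydrogen-bond test for one donor heavy atom Y (with its bonded
    hydrogens) against one acceptor heavy atom X.

    With no hydrogens available the degraded distance-only mode tests
    the heavy–heavy distance against ``hbond_dist + degraded_hbond_pad``.
    Angle criteria are maximum deviations from ideal (linear) geometry:
    donor 180° − ∠(Y,H,X); acceptor 180° − ∠(antecedent-mean, X, H).
    An acceptor with no antecedent (isolated atom) skips the acceptor
    angle test.
    """
    eps = params.boundary_eps
    if not donor_hydrogens:
        return _le(float(np.linalg.norm(donor_heavy - acceptor)),
                   params.hbond_dist + params.degraded_hbond_pad, eps)
    if acceptor_antecedents:
        ante_dir = np.mean([(a - acceptor) / np.linalg.norm(a - acceptor)
                            for a in acceptor_antecedents], axis=0)
    else:
        ante_dir = None
    for h in donor_hydrogens:
        if params.hbond_distance_mode == "hydrogen_acceptor":
            dist = float(np.linalg.norm(h - acceptor))
        else:
            dist = float(np.linalg.norm(donor_heavy - acceptor))
        if not _le(dist, params.hbond_dist, eps):
            continue
        donor_dev = 180.0 - angle_deg(donor_heavy, h, acceptor)
        if not _le(donor_dev, params.hbond_donor_angle_max, eps):
            continue
        if ante_dir is not None and np.linalg.norm(ante_dir) > 1e-8:
            acc_dev = 180.0 - angle_deg(acceptor + ante_dir, acceptor, h)
            if not _le(acc_dev, params.hbond_acceptor_angle_max, eps):
                continue
        return True
    return False


def detect_charged(feature: PharmacophoreFeature, residue: Residue,
                   params: GeometryParams, tables: dict | None = None) -> bool:
    """Charge–charge contact: complementary classes and minimum distance
    between the feature atoms and the residue's charged-group atoms."""
    tables = tables or residue_tables()
    complement = {"N": "positively_charged", "P": "negatively_charged"}.get(feature.type)
    if complement is None or complement not in residue.classes:
        return False
    group = _charged_group_coords(residue, tables)
    if group.size == 0:
        return False
    return _le(min_distance(_feature_coords(feature), group),
               params.contact_dist, params.boundary_eps)


def detect_hydrophobic(feature: PharmacophoreFeature, residue: Residue,
                       params: GeometryParams) -> bool:
    """Hydrophobic contact against the carbon/sulfur sidechain atoms of a
    hydrophobic-class residue."""
    if "hydrophobic" not in residue.classes:
        return False
    targets = np.array([a.coords for a in residue.sidechain_atoms
                        if not a.is_hydrogen and a.element in ("C", "S")])
    if targets.size == 0:
        return False
    return _le(min_distance(_feature_coords(feature), targets),
               params.contact_dist, params.boundary_eps)


def detect_polar(feature: PharmacophoreFeature, residue: Residue,
                 params: GeometryParams, tables: dict | None = None) -> bool:
    """Distance-only polar contact (no angle test) between an A/D feature
    and the polar sidechain heavy atoms of a polar-class residue."""
    tables = tables or residue_tables()
    if "polar" not in residue.classes:
        return False
    names = tables["polar_sidechain"].get(_canonical(residue.name, tables), [])
    targets = np.array([a.coords for a in residue.find_atoms(names)
                        if not a.is_hydrogen])
    if targets.size == 0:
        return False
    return _le(min_distance(_feature_coords(feature), targets),
               params.contact_dist, params.boundary_eps)


def detect_aromatic(centroid_a: np.ndarray, normal_a: np.ndarray,
                    centroid_b: np.ndarray, normal_b: np.ndarray,
                    params: GeometryParams) -> str | None:
    """Classify a ring–ring geometry as ``"face_to_face"``,
    ``"edge_to_face"`` or ``None``; face-to-face takes precedence when
    both distance/angle windows are satisfied."""
    eps = params.boundary_eps
    d = float(np.linalg.norm(centroid_a - centroid_b))
    theta = interplanar_angle(normal_a, normal_b)
    if _le(d, params.pi_ff_dist, eps) and _le(theta, params.pi_ff_angle_max, eps):
        return "face_to_face"
    if _le(d, params.pi_ef_dist, eps) and _ge(theta, params.pi_ef_angle_min, eps):
        return "edge_to_face"
    return None


def detect_pi_cation(ring_centroid: np.ndarray, cation_centroid: np.ndarray,
                     params: GeometryParams) -> bool:
    """Distance-only π–cation criterion on the centroid separation."""
    return _le(float(np.linalg.norm(ring_centroid - cation_centroid)),
               params.pi_cation_dist, params.boundary_eps)


# ---------------------------------------------------------------------------
# residue-side geometry helpers

def _canonical(name: str, tables: dict) -> str:
    return tables["aliases"].get(name, name)


def _feature_coords(feature: PharmacophoreFeature) -> np.ndarray:
    # member coordinates are cached on the feature via centroid only;
    # the engine stores them alongside during block construction
    coords = getattr(feature, "_coords", None)
    if coords is None:
        raise GeometryError("feature has no attached member coordinates")
    return coords


def attach_feature_coords(features: list[PharmacophoreFeature], ligand) -> None:
    """Cache member heavy-atom coordinates on each feature instance."""
    for f in features:
        object.__setattr__(f, "_coords", ligand.coords(sorted(f.atom_indices)))


def _charged_group_coords(residue: Residue, tables: dict) -> np.ndarray:
    names = tables["charged_group"].get(_canonical(residue.name, tables), [])
    atoms = [a for a in residue.find_atoms(names) if not a.is_hydrogen]
    return np.array([a.coords for a in atoms]) if atoms else np.empty((0, 3))


def residue_cation_centroid(residue: Residue, tables: dict) -> np.ndarray | None:
    group = _charged_group_coords(residue, tables)
    return group.mean(axis=0) if group.size else None


def residue_rings(residue: Residue, tables: dict) -> list[tuple[np.ndarray, np.ndarray]]:
    """(centroid, normal) of each aromatic ring of the residue whose
    atoms are sufficiently resolved."""
    rings = []
    for names in tables["aromatic_rings"].get(_canonical(residue.name, tables), []):
        atoms = [a for a in residue.find_atoms(names) if not a.is_hydrogen]
        if len(atoms) >= 3:
            try:
                rings.append(best_fit_plane(np.array([a.coords for a in atoms])))
            except GeometryError:
                logger.warning("%s: degenerate aromatic ring skipped", residue.label)
    return rings


def _residue_donors(residue: Residue, tables: dict) -> list[tuple[Atom, bool]]:
    """(donor heavy atom, is_backbone) pairs: backbone N plus the
    sidechain donor atoms of the residue type."""
    donors = [(a, True) for a in residue.backbone_atoms
              if not a.is_hydrogen and a.name == "N"]
    names = tables["donors"].get(_canonical(residue.name, tables), [])
    donors += [(a, False) for a in residue.find_atoms(names) if not a.is_hydrogen]
    return donors


def _residue_acceptors(residue: Residue, tables: dict) -> list[tuple[Atom, bool]]:
    acceptors = [(a, True) for a in residue.backbone_atoms
                 if not a.is_hydrogen and a.name in ("O", "OXT")]
    names = tables["acceptors"].get(_canonical(residue.name, tables), [])
    acceptors += [(a, False) for a in residue.find_atoms(names) if not a.is_hydrogen]
    return acceptors


def _residue_antecedents(residue: Residue, acceptor: Atom) -> list[np.ndarray]:
    """Heavy atoms covalently bonded to a residue acceptor, found
    geometrically (residue topology is not stored)."""
    out = []
    for a in residue.atoms:
        if a.is_hydrogen or a is acceptor:
            continue
        cutoff = _COVALENT_MAX_S if "S" in (a.element, acceptor.element) else _COVALENT_MAX
        if np.linalg.norm(a.coords - acceptor.coords) <= cutoff:
            out.append(a.coords)
    return out


# ---------------------------------------------------------------------------
# block / matrix construction

def build_block(features: list[PharmacophoreFeature], residue: Residue,
                ligand, params: GeometryParams | None = None,
                mask: np.ndarray | None = None,
                tables: dict | None = None) -> ResidueBlock:
    """Evaluate every detector between the ligand features and one
    residue and return the populated 7×9 count block."""
    params = params or GeometryParams()
    tables = tables or residue_tables()
    if mask is None:
        mask = mask_array(default_mask_spec())
    counts = np.zeros((N_ROWS, N_COLS), dtype=np.int64)
    eps = params.boundary_eps

    donors = _residue_donors(residue, tables)
    acceptors = _residue_acceptors(residue, tables)
    rings = residue_rings(residue, tables) if "aromatic" in residue.classes else []
    cation = (residue_cation_centroid(residue, tables)
              if "positively_charged" in residue.classes else None)

    for f in features:
        cols: set[str] = set()
        fcoords = _feature_coords(f)

        if f.type == "A":
            hbond = False
            for donor_atom, is_bb in donors:
                hs = [h.coords for h in residue.hydrogens_bonded_to(donor_atom)]
                for xi in sorted(f.atom_indices):
                    ante = [ligand.atoms[j].coords for j in ligand.heavy_neighbors(xi)]
                    if detect_hbond(donor_atom.coords, hs, ligand.atoms[xi].coords,
                                    ante, params):
                        hbond = True
                        cols |= {"D", "BB" if is_bb else "SC"}
            if not hbond and detect_polar(f, residue, params, tables):
                cols |= {"P", "SC"}

        elif f.type == "D":
            hbond = False
            for yi in sorted(f.atom_indices):
                y = ligand.atoms[yi].coords
                hs = [ligand.atoms[j].coords for j in ligand.hydrogens_bonded_to(yi)]
                for acc_atom, is_bb in acceptors:
                    ante = _residue_antecedents(residue, acc_atom)
                    if detect_hbond(y, hs, acc_atom.coords, ante, params):
                        hbond = True
                        cols |= {"A", "BB" if is_bb else "SC"}
            if not hbond and detect_polar(f, residue, params, tables):
                cols |= {"P", "SC"}

        elif f.type == "H":
            if detect_hydrophobic(f, residue, params):
                cols |= {"H", "SC"}

        elif f.type == "N":
            if detect_charged(f, residue, params, tables):
                cols |= {"C", "SC"}

        elif f.type == "P":
            if detect_charged(f, residue, params, tables):
                cols |= {"C", "SC"}
            for ring_c, _ in rings:
                if detect_pi_cation(ring_c, f.centroid, params):
                    cols |= {"R", "SC"}

        elif f.type == "R":
            for ring_c, ring_n in rings:
                if detect_aromatic(f.centroid, f.ring_normal, ring_c, ring_n,
                                   params) is not None:
                    cols |= {"R", "SC"}
            if cation is not None and detect_pi_cation(f.centroid, cation, params):
                cols |= {"R", "SC"}
            if detect_hydrophobic(f, residue, params):
                cols |= {"H", "SC"}

        if cols:
            cols.add("Any")
        row = ROW_INDEX[f.type]
        for col in cols:
            ci = COL_INDEX[col]
            if mask[row, ci]:
                counts[row, ci] += 1

    # wildcard row: any ligand heavy atom touching the residue, at most
    # one increment per region column
    heavy = ligand.coords(ligand.heavy_indices())
    if heavy.size:
        flags = detect_contact(heavy, residue, params)
        vdw = ROW_INDEX["vdW"]
        for col, key in (("Any", "any"), ("BB", "backbone"), ("SC", "sidechain")):
            if flags[key] and mask[vdw, COL_INDEX[col]]:
                counts[vdw, COL_INDEX[col]] += 1

    return ResidueBlock(counts=counts, residue_key=residue.key,
                        generic_number=residue.generic_number)


def build_matrix(cx: Complex, params: GeometryParams | None = None,
                 mask_spec=None, tables: dict | None = None,
                 definitions=None) -> InteractionMatrix:
    """Full pipeline for one complex: assign ligand features, evaluate
    every residue, concatenate the blocks in residue order."""
    params = params or GeometryParams()
    mask_spec = mask_spec or default_mask_spec()
    tables = tables or residue_tables()
    mask = mask_array(mask_spec)
    features = assign_features(cx.ligand, definitions)
    attach_feature_coords(features, cx.ligand)
    blocks = [build_block(features, r, cx.ligand, params, mask, tables)
              for r in cx.residues]
    metadata = {"n_features": len(features),
                "degraded_hbond_mode": not cx.has_polar_hydrogens}
    if not cx.has_polar_hydrogens:
        logger.warning("%s: distance-only hydrogen-bond mode (no protein "
                       "hydrogens)", cx.identifier)
    return InteractionMatrix(blocks=blocks, complex_id=cx.identifier,
                             params_fingerprint=params_fingerprint(params, mask_spec),
                             mask_spec=tuple(mask_spec), metadata=metadata)
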