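"""Ligand pharmacophore feature assignment.

Features (hydrogen-bond acceptor/donor, hydrophobic patch, negatively
and positively charged group, aromatic ring) are assigned by SMARTS
matching against the ligand molecule; the pattern set lives in an
editable text file so results are reproducible and user-tunable.  The
seventh, wildcard row ("any atom") is not materialised as a feature:
every ligand heavy atom is vdW-capable and the interaction engine
evaluates plain contacts per residue directly.

Geometric attributes: each feature carries the unweighted centroid of
its heavy member atoms; aromatic features additionally carry the unit
normal of the best-fit ring plane (sign unspecified — all angle
comparisons downstream fold to [0°, 90°]).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from ._tables import feature_definitions
from .constants import FEATURE_ROWS, ROW_INDEX
from .structure import Ligand


class FeatureError(Exception):
    pass


class GeometryError(Exception):
    pass


@dataclass(frozen=True)
class PharmacophoreFeature:
    type: str                     # one of A, D, H, N, P, R
    atom_indices: frozenset[int]  # ligand heavy-atom indices
    centroid: np.ndarray          # (3,) Å
    ring_normal: np.ndarray | None = None  # unit vector, R features only
    feature_id: int = -1

    def __post_init__(self):
        if not self.atom_indices:
            raise FeatureError("feature with no member atoms")
        if (self.type == "R") != (self.ring_normal is not None):
            raise FeatureError("ring_normal must be present iff type is R")


def best_fit_plane(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and unit normal of the least-squares plane through
    ``coords`` (n >= 3, non-collinear).  The normal minimizes the sum of
    squared out-of-plane deviations; its sign is arbitrary."""
    pts = np.asarray(coords, dtype=float)
    if pts.shape[0] < 3:
        raise GeometryError("ring plane needs at least 3 atoms")
    centroid = pts.mean(axis=0)
    _, s, vt = np.linalg.svd(pts - centroid)
    if s[1] < 1e-8:
        raise GeometryError("ring atoms are collinear; no plane defined")
    return centroid, vt[2]


def ring_geometry(feature: PharmacophoreFeature) -> tuple[np.ndarray, np.ndarray]:
    """(centroid, unit normal) of an aromatic feature."""
    if feature.type != "R":
        raise FeatureError("ring_geometry requires an aromatic (R) feature")
    return feature.centroid, feature.ring_normal


def _connected_components(atoms: set[int], ligand: Ligand) -> list[frozenset[int]]:
    adj: dict[int, set[int]] = {a: set() for a in atoms}
    for i, j, _ in ligand.bonds:
        if i in atoms and j in atoms:
            adj[i].add(j)
            adj[j].add(i)
    seen: set[int] = set()
    comps = []
    for start in sorted(atoms):
        if start in seen:
            continue
        comp, stack = set(), [start]
        while stack:
            a = stack.pop()
            if a in comp:
                continue
            comp.add(a)
            stack.extend(adj[a] - comp)
        seen |= comp
        comps.append(frozenset(comp))
    return comps


def assign_features(ligand: Ligand,
                    definitions: dict[str, list[tuple[str, str]]] | None = None,
                    ) -> list[PharmacophoreFeature]:
    """Assign pharmacophore features to a ligand by SMARTS matching.

    Post-processing: matches with identical heavy-atom sets are merged;
    hydrophobic matches are merged into maximal bonded components (one
    feature per contiguous hydrophobic patch); aromatic matches are
    deduplicated per ring, so fused systems contribute one feature per
    smallest ring.  Hydrogens never appear as member atoms (they enter
    only through donor geometry in the interaction engine).

    Feature ids are dense from 0 in (row order, atom-set) order.
    """
    if ligand.mol is None:
        raise FeatureError("ligand has no perceived molecule (bonds/aromaticity)")
    definitions = definitions or feature_definitions()
    mol = ligand.mol
    hydrogens = {i for i, a in enumerate(ligand.atoms) if a.is_hydrogen}

    matched: dict[str, set[frozenset[int]]] = {t: set() for t in FEATURE_ROWS[:-1]}
    for ftype, patterns in definitions.items():
        for name, smarts in patterns:
            query = Chem.MolFromSmarts(smarts)
            if query is None:
                raise FeatureError(f"unparsable SMARTS for pattern {name!r}: {smarts!r}")
            for match in mol.GetSubstructMatches(query, uniquify=True):
                heavy = frozenset(match) - hydrogens
                if heavy:
                    matched[ftype].add(frozenset(heavy))

    # hydrophobic patches: maximal bonded components of matched atoms
    if matched["H"]:
        flat = set().union(*matched["H"])
        matched["H"] = set(_connected_components(flat, ligand))

    features: list[PharmacophoreFeature] = []
    for ftype in FEATURE_ROWS[:-1]:
        for atom_set in sorted(matched[ftype], key=sorted):
            coords = ligand.coords(sorted(atom_set))
            if ftype == "R":
                centroid, normal = best_fit_plane(coords)
            else:
                centroid, normal = coords.mean(axis=0), None
            features.append(PharmacophoreFeature(
                type=ftype, atom_indices=atom_set, centroid=centroid,
                ring_normal=normal, feature_id=len(features)))
    return features


def features_by_type(features: list[PharmacophoreFeature]) -> dict[str, list[PharmacophoreFeature]]:
    out: dict[str, list[PharmacophoreFeature]] = {t: [] for t in FEATURE_ROWS[:-1]}
    for f in features:
        out[f.type].append(f)
    return out


def feature_summary(features: list[PharmacophoreFeature]) -> dict[str, int]:
    """Count of feature instances per row type (diagnostics)."""
    counts = {t: 0 for t in FEATURE_ROWS[:-1]}
    for f in features:
        counts[f.type] += 1
    return dict(sorted(counts.items(), key=lambda kv: ROW_INDEX[kv[0]]))
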