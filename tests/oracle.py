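"""Independent brute-force reference for the interaction engine.

A deliberately naive re-implementation of every geometric criterion and
incrementation rule: all atom pairs, plain loops, no shared code with
``siftmat.engine``.  Used to check ``build_matrix`` on randomly
generated small complexes.
"""

from __future__ import annotations

import math

import numpy as np

from siftmat._tables import residue_tables
from siftmat.constants import COL_INDEX, N_COLS, N_ROWS, ROW_INDEX
from siftmat.pharmacophore import assign_features

# transcribed incrementable-cell table (kept literal on purpose)
MASK = {
    "A": {"Any", "BB", "SC", "P", "D"},
    "D": {"Any", "BB", "SC", "P", "A"},
    "H": {"Any", "BB", "SC", "H"},
    "N": {"Any", "SC", "C"},
    "P": {"Any", "SC", "C", "R"},
    "R": {"Any", "BB", "SC", "H", "R"},
    "vdW": {"Any", "BB", "SC"},
}


def _dist(p, q):
    return math.dist(tuple(p), tuple(q))


def _mind(aset, bset):
    return min(_dist(p, q) for p in aset for q in bset)


def _angle(a, v, c):
    v1 = np.asarray(a, float) - v
    v2 = np.asarray(c, float) - v
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def _plane_normal(pts):
    pts = np.asarray(pts, float)
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid)
    return centroid, vt[2]


def _hbond(y, hs, x, ante, p):
    eps = p.boundary_eps
    if not hs:
        return _dist(y, x) <= p.hbond_dist + p.degraded_hbond_pad + eps
    for h in hs:
        d = _dist(h, x) if p.hbond_distance_mode == "hydrogen_acceptor" \
            else _dist(y, x)
        if d > p.hbond_dist + eps:
            continue
        if 180.0 - _angle(y, h, x) > p.hbond_donor_angle_max + eps:
            continue
        if ante:
            mean = np.mean([(np.asarray(a, float) - x) / _dist(a, x)
                            for a in ante], axis=0)
            if np.linalg.norm(mean) > 1e-8:
                if 180.0 - _angle(np.asarray(x) + mean, np.asarray(x), h) \
                        > p.hbond_acceptor_angle_max + eps:
                    continue
        return True
    return False


def brute_force_matrix(cx, params) -> list[np.ndarray]:
    """Per-residue 7x9 blocks computed the slow, obvious way."""
    tables = residue_tables()
    eps = params.boundary_eps
    features = assign_features(cx.ligand)
    lig = cx.ligand
    fcoords = {f.feature_id: [lig.atoms[i].coords for i in sorted(f.atom_indices)]
               for f in features}
    blocks = []
    for res in cx.residues:
        counts = np.zeros((N_ROWS, N_COLS), dtype=np.int64)
        cname = tables["aliases"].get(res.name, res.name)
        classes = res.classes
        bb = [a.coords for a in res.backbone_atoms if not a.is_hydrogen]
        sc = [a.coords for a in res.sidechain_atoms if not a.is_hydrogen]
        cs_side = [a.coords for a in res.sidechain_atoms
                   if not a.is_hydrogen and a.element in ("C", "S")]
        polar = [a.coords for a in res.atoms if not a.is_hydrogen
                 and a.name in tables["polar_sidechain"].get(cname, [])]
        charged = [a.coords for a in res.atoms if not a.is_hydrogen
                   and a.name in tables["charged_group"].get(cname, [])]
        donors, acceptors = [], []
        for a in res.backbone_atoms:
            if a.is_hydrogen:
                continue
            if a.name == "N":
                donors.append((a, True))
            if a.name in ("O", "OXT"):
                acceptors.append((a, True))
        for a in res.atoms:
            if a.is_hydrogen:
                continue
            if a.name in tables["donors"].get(cname, []):
                donors.append((a, False))
            if a.name in tables["acceptors"].get(cname, []):
                acceptors.append((a, False))
        rings = []
        if "aromatic" in classes:
            for names in tables["aromatic_rings"].get(cname, []):
                pts = [a.coords for a in res.atoms
                       if not a.is_hydrogen and a.name in names]
                if len(pts) >= 3:
                    rings.append(_plane_normal(pts))
        cation = (np.mean(charged, axis=0)
                  if "positively_charged" in classes and charged else None)

        def res_hs(atom):
            return [h.coords for h in res.atoms if h.is_hydrogen
                    and _dist(h.coords, atom.coords) <= 1.3]

        def res_ante(atom):
            out = []
            for a in res.atoms:
                if a.is_hydrogen or a is atom:
                    continue
                cut = 2.1 if "S" in (a.element, atom.element) else 1.8
                if _dist(a.coords, atom.coords) <= cut:
                    out.append(a.coords)
            return out

        for f in features:
            pts = fcoords[f.feature_id]
            cols = set()
            if f.type == "A":
                hb = False
                for datom, is_bb in donors:
                    for i in sorted(f.atom_indices):
                        ante = [lig.atoms[j].coords
                                for j in lig.heavy_neighbors(i)]
                        if _hbond(datom.coords, res_hs(datom),
                                  lig.atoms[i].coords, ante, params):
                            hb = True
                            cols |= {"D", "BB" if is_bb else "SC"}
                if not hb and "polar" in classes and polar \
                        and _mind(pts, polar) <= params.contact_dist + eps:
                    cols |= {"P", "SC"}
            elif f.type == "D":
                hb = False
                for i in sorted(f.atom_indices):
                    hs = [lig.atoms[j].coords
                          for j in lig.hydrogens_bonded_to(i)]
                    for aatom, is_bb in acceptors:
                        if _hbond(lig.atoms[i].coords, hs, aatom.coords,
                                  res_ante(aatom), params):
                            hb = True
                            cols |= {"A", "BB" if is_bb else "SC"}
                if not hb and "polar" in classes and polar \
                        and _mind(pts, polar) <= params.contact_dist + eps:
                    cols |= {"P", "SC"}
            elif f.type == "H":
                if "hydrophobic" in classes and cs_side \
                        and _mind(pts, cs_side) <= params.contact_dist + eps:
                    cols |= {"H", "SC"}
            elif f.type == "N":
                if "positively_charged" in classes and charged \
                        and _mind(pts, charged) <= params.contact_dist + eps:
                    cols |= {"C", "SC"}
            elif f.type == "P":
                if "negatively_charged" in classes and charged \
                        and _mind(pts, charged) <= params.contact_dist + eps:
                    cols |= {"C", "SC"}
                for rc, _ in rings:
                    if _dist(rc, f.centroid) <= params.pi_cation_dist + eps:
                        cols |= {"R", "SC"}
            elif f.type == "R":
                for rc, rn in rings:
                    d = _dist(rc, f.centroid)
                    th = math.degrees(math.acos(
                        min(1.0, abs(float(np.dot(rn, f.ring_normal))))))
                    ff = d <= params.pi_ff_dist + eps \
                        and th <= params.pi_ff_angle_max + eps
                    ef = d <= params.pi_ef_dist + eps \
                        and th >= params.pi_ef_angle_min - eps
                    if ff or ef:
                        cols |= {"R", "SC"}
                if cation is not None and \
                        _dist(f.centroid, cation) <= params.pi_cation_dist + eps:
                    cols |= {"R", "SC"}
                if "hydrophobic" in classes and cs_side \
                        and _mind(pts, cs_side) <= params.contact_dist + eps:
                    cols |= {"H", "SC"}
            if cols:
                cols.add("Any")
            for c in cols & MASK[f.type]:
                counts[ROW_INDEX[f.type], COL_INDEX[c]] += 1

        heavy = [a.coords for a in lig.atoms if not a.is_hydrogen]
        vdw = set()
        if bb and _mind(heavy, bb) <= params.contact_dist + eps:
            vdw |= {"BB", "Any"}
        if sc and _mind(heavy, sc) <= params.contact_dist + eps:
            vdw |= {"SC", "Any"}
        for c in vdw & MASK["vdW"]:
            counts[ROW_INDEX["vdW"], COL_INDEX[c]] += 1
        blocks.append(counts)
    return blocks
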