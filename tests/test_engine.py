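"""Geometric detectors and block/matrix construction."""

import math

import numpy as np
import pytest
from rdkit import Chem

from siftmat.constants import COL_INDEX, ROW_INDEX
from siftmat.engine import (GeometryParams, build_matrix, detect_aromatic,
                            detect_hbond, detect_pi_cation, min_distance)
from siftmat.fixtures import (FixtureSpec, _build_mol, _methanol_at,
                              make_pair_fixture, make_residue)
from siftmat.structure import Complex, _ligand_from_rdkit

from oracle import brute_force_matrix


def _cell(matrix, block_idx, row, col):
    return int(matrix.blocks[block_idx].counts[ROW_INDEX[row], COL_INDEX[col]])


class TestPrimitives:
    @pytest.mark.parametrize("a,b,expected", [
        ([[0, 0, 0]], [[3, 4, 0]], 5.0),
        ([[1, 2, 3]], [[1, 2, 3]], 0.0),
        ([[0, 0, 0], [10, 0, 0]], [[0, 0, 2]], 2.0),
    ])
    def test_min_distance(self, a, b, expected):
        assert min_distance(np.array(a), np.array(b)) == pytest.approx(expected)

    def test_min_distance_empty_set_rejected(self):
        with pytest.raises(ValueError):
            min_distance(np.empty((0, 3)), np.array([[0.0, 0.0, 0.0]]))

    @pytest.mark.parametrize("field,value", [
        ("contact_dist", -1.0),
        ("hbond_donor_angle_max", 200.0),
        ("hbond_distance_mode", "nonsense"),
    ])
    def test_params_validation(self, field, value):
        with pytest.raises(ValueError):
            GeometryParams(**{field: value})


class TestHydrogenBond:
    """Collinear Y-H···X geometries with a single antecedent behind X."""

    @staticmethod
    def _geometry(d_hx, donor_dev=0.0, acc_dev=0.0):
        x = np.zeros(3)
        w = np.array([1.0, 0.0, 0.0])
        rot = lambda deg: np.array(
            [[math.cos(math.radians(deg)), -math.sin(math.radians(deg)), 0],
             [math.sin(math.radians(deg)), math.cos(math.radians(deg)), 0],
             [0, 0, 1]])
        h = x + d_hx * (rot(acc_dev) @ w)
        y = h + 0.97 * (rot(acc_dev + donor_dev) @ w)
        ante = [x - w]  # antecedent directly opposite the ideal approach
        return y, [h], x, ante

    @pytest.mark.parametrize("d,expected", [(2.8, True), (2.9, False)])
    def test_distance_boundary_inclusive(self, d, expected):
        y, hs, x, ante = self._geometry(d)
        assert detect_hbond(y, hs, x, ante, GeometryParams()) is expected

    @pytest.mark.parametrize("dev,expected", [(119.9, True), (120.0, True),
                                              (121.0, False)])
    def test_donor_angle_boundary(self, dev, expected):
        y, hs, x, ante = self._geometry(2.0, donor_dev=dev)
        assert detect_hbond(y, hs, x, ante, GeometryParams()) is expected

    @pytest.mark.parametrize("dev,expected", [(90.0, True), (91.0, False)])
    def test_acceptor_angle_boundary(self, dev, expected):
        y, hs, x, ante = self._geometry(2.0, acc_dev=dev)
        assert detect_hbond(y, hs, x, ante, GeometryParams()) is expected

    def test_degraded_mode_without_hydrogens(self):
        y = np.array([3.7, 0.0, 0.0])
        x = np.zeros(3)
        p = GeometryParams()
        assert detect_hbond(y, [], x, [], p)  # 3.7 <= 2.8 + 1.0
        assert not detect_hbond(np.array([3.9, 0, 0]), [], x, [], p)

    def test_heavy_heavy_mode(self):
        p = GeometryParams(hbond_distance_mode="heavy_heavy")
        y, hs, x, ante = self._geometry(2.0)
        # Y sits at 2.97 from X: fails the 2.8 heavy-heavy bound
        assert not detect_hbond(y, hs, x, ante, p)
        y2, hs2, x2, ante2 = self._geometry(1.8)
        assert detect_hbond(y2, hs2, x2, ante2, p)


class TestAromaticAndPiCation:
    N = np.array([0.0, 0.0, 1.0])

    def _tilted(self, deg):
        r = math.radians(deg)
        return np.array([math.sin(r), 0.0, math.cos(r)])

    @pytest.mark.parametrize("d,theta,expected", [
        (4.4, 0.0, "face_to_face"),
        (4.5, 0.0, None),             # between cutoffs, wrong angle for EF
        (5.0, 90.0, "edge_to_face"),
        (5.51, 90.0, None),
        (4.0, 30.0, "face_to_face"),
        (4.0, 30.1, None),
        (5.0, 60.0, "edge_to_face"),
        (5.0, 59.9, None),
        (4.4, 90.0, "edge_to_face"),  # inside both distances, EF angle wins
    ])
    def test_stacking_classification(self, d, theta, expected):
        c1 = np.zeros(3)
        c2 = np.array([0.0, 0.0, d])
        out = detect_aromatic(c1, self.N, c2, self._tilted(theta),
                              GeometryParams())
        assert out == expected

    def test_face_to_face_precedence(self):
        # parallel rings within the FF window also satisfy no EF angle;
        # at a shared boundary FF must win
        out = detect_aromatic(np.zeros(3), self.N, np.array([0, 0, 4.0]),
                              self.N, GeometryParams(pi_ef_angle_min=0.0))
        assert out == "face_to_face"

    @pytest.mark.parametrize("d,expected", [(6.6, True), (6.7, False)])
    def test_pi_cation_boundary(self, d, expected):
        assert detect_pi_cation(np.zeros(3), np.array([d, 0, 0]),
                                GeometryParams()) is expected


class TestDetectorsViaFixtures:
    """Spec'd detector examples exercised through the full pipeline."""

    @pytest.mark.parametrize("spec,row,col,expected", [
        (FixtureSpec("methane", "LEU", 3.5), "vdW", "Any", 1),
        (FixtureSpec("methane", "LEU", 3.51), "vdW", "Any", 0),
        (FixtureSpec("methane", "LEU", 3.3), "H", "H", 1),       # LEU CD1
        (FixtureSpec("methane", "SER", 3.3), "H", "H", 0),       # not hydrophobic
        (FixtureSpec("methane", "LEU", 5.0), "H", "H", 0),
        (FixtureSpec("ammonium", "ASP", 3.4), "P", "C", 1),
        (FixtureSpec("ammonium", "GLU", 3.6), "P", "C", 0),      # beyond cutoff
        (FixtureSpec("carboxylate", "ARG", 3.4), "N", "C", 1),
        (FixtureSpec("carboxylate", "ASP", 3.4), "N", "C", 0),   # like charges
        (FixtureSpec("benzene", "LYS", 6.6), "R", "R", 1),
        (FixtureSpec("benzene", "LYS", 6.7), "R", "R", 0),
        (FixtureSpec("ammonium", "PHE", 5.0), "P", "R", 1),      # reverse direction
    ])
    def test_detector_examples(self, spec, row, col, expected):
        fx = make_pair_fixture(spec)
        m = build_matrix(fx.complex)
        assert _cell(m, 0, row, col) == expected

    def test_polar_without_angle_test(self):
        # hydroxyl O at 3.2 Å from ASN OD1: the ligand-acceptor row
        # picks up a polar contact on distance alone (its own O-H bond
        # goes to OD1 in the D row, which suppresses polar only there)
        fx = make_pair_fixture(FixtureSpec("hydroxyl_donor", "ASN", 2.23))
        m = build_matrix(fx.complex)
        assert _cell(m, 0, "A", "P") == 1
        assert _cell(m, 0, "A", "SC") == 1
        far = make_pair_fixture(FixtureSpec("hydroxyl_donor", "ASN", 2.63))
        assert _cell(build_matrix(far.complex), 0, "A", "P") == 0

    def test_polar_needs_polar_class_residue(self):
        # same hydroxyl near a VAL sidechain: no polar-class target
        fx = make_pair_fixture(FixtureSpec("hydroxyl_donor", "VAL", 2.23))
        m = build_matrix(fx.complex)
        assert _cell(m, 0, "A", "P") == 0
        assert _cell(m, 0, "vdW", "Any") == 1


class TestBuildBlock:
    def test_two_rings_stacking_one_phe(self):
        """Two ligand aromatic rings face-to-face with one PHE give a
        count of 2 in the aromatic cell."""
        phe = make_residue("PHE")
        rc = np.array([-2.90, -0.09, 0.00])
        centers = [rc + np.array([-4.0, 0.0, 0.0]),
                   rc + np.array([-2.0, 3.2, 0.0])]
        elements, coords, bonds = [], [], []
        for c_i, center in enumerate(centers):
            base = 6 * c_i
            for k in range(6):
                a = math.radians(60 * k)
                elements.append("C")
                # rings in planes perpendicular to x (parallel to PHE ring)
                coords.append(center + 1.39 * np.array([0.0, math.cos(a),
                                                        math.sin(a)]))
                bonds.append((base + k, base + (k + 1) % 6,
                              2 if k % 2 == 0 else 1))
        lig = _ligand_from_rdkit(_build_mol(elements, coords, bonds), "mol")
        cx = Complex(residues=[phe], ligand=lig, identifier="two-rings")
        m = build_matrix(cx)
        assert _cell(m, 0, "R", "R") == 2
        assert _cell(m, 0, "R", "Any") == 2
        assert np.array_equal(m.blocks[0].counts,
                              brute_force_matrix(cx, GeometryParams())[0])

    def test_out_of_range_block_is_all_zero(self):
        fx = make_pair_fixture(FixtureSpec("methane", "LEU", 8.0))
        m = build_matrix(fx.complex)
        assert not m.blocks[0].counts.any()

    def test_donor_to_backbone_oxygen(self):
        """Ligand hydroxyl donating to a backbone O: row D sets the
        residue-acceptor and backbone columns, not sidechain."""
        ala = make_residue("ALA")
        o = next(a for a in ala.backbone_atoms if a.name == "O")
        c = next(a for a in ala.backbone_atoms if a.name == "C")
        approach = (o.coords - c.coords)
        approach /= np.linalg.norm(approach)
        h = o.coords + 2.0 * approach
        y = h + 0.97 * approach
        lig = _ligand_from_rdkit(
            _methanol_at(y, h, np.array([a.coords for a in ala.atoms])), "mol")
        cx = Complex(residues=[ala], ligand=lig, identifier="bb-donor")
        m = build_matrix(cx)
        assert _cell(m, 0, "D", "A") == 1
        assert _cell(m, 0, "D", "BB") == 1
        assert _cell(m, 0, "D", "Any") == 1
        assert _cell(m, 0, "D", "SC") == 0

    def test_hbond_suppresses_polar_same_pair(self):
        # SER accepting from methanol: polar-class residue in polar
        # range, but the D row carries the H-bond, not an extra P
        fx = make_pair_fixture(FixtureSpec("hydroxyl_donor", "SER", 2.0))
        m = build_matrix(fx.complex)
        assert _cell(m, 0, "D", "A") == 1
        assert _cell(m, 0, "D", "P") == 0

    def test_masked_cells_stay_zero(self, default_mask):
        for seed in range(5):
            from siftmat.fixtures import make_random_complex
            m = build_matrix(make_random_complex(seed))
            for b in m.blocks:
                assert not b.counts[~default_mask].any()


class TestBuildMatrix:
    def test_two_residue_shape(self):
        lig_fx = make_pair_fixture(FixtureSpec("methane", "LEU", 3.0))
        far_ser = make_residue("SER", seqnum=2,
                               translation=np.array([40.0, 0.0, 0.0]))
        cx = Complex(residues=lig_fx.complex.residues + [far_ser],
                     ligand=lig_fx.complex.ligand, identifier="pair")
        m = build_matrix(cx)
        assert m.n_residues == 2
        assert m.stacked().shape == (7, 18)
        assert m.blocks[0].counts.any()
        assert not m.blocks[1].counts.any()

    def test_matrix_carries_params_fingerprint(self):
        fx = make_pair_fixture(FixtureSpec("methane", "LEU", 3.0))
        m1 = build_matrix(fx.complex)
        m2 = build_matrix(fx.complex, GeometryParams(contact_dist=4.0))
        assert m1.params_fingerprint != m2.params_fingerprint

    def test_rigid_body_invariance(self, showcase):
        cx, _ = showcase
        reference = build_matrix(cx).stacked()
        rng = np.random.default_rng(11)
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        R = np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)]])
        t = np.array([5.0, -3.0, 12.0])
        moved = _transform_complex(cx, R, t)
        assert np.array_equal(build_matrix(moved).stacked(), reference)

    def test_monotone_in_distance(self):
        """Moving a probe closer along the contact axis never unfires a
        distance-only detector."""
        for probe, res, row, col in [("methane", "LEU", "H", "H"),
                                     ("ammonium", "ASP", "P", "C"),
                                     ("benzene", "LYS", "R", "R")]:
            fired = False
            for d in np.arange(7.0, 1.9, -0.5):
                fx = make_pair_fixture(FixtureSpec(probe, res, float(d)))
                now = _cell(build_matrix(fx.complex), 0, row, col) > 0
                assert now or not fired, (probe, res, d)
                fired = fired or now
            assert fired


def _transform_complex(cx, R, t):
    from siftmat.structure import Atom, Residue, split_backbone_sidechain
    residues = []
    for r in cx.residues:
        atoms = [Atom(a.name, a.element, R @ a.coords + t, a.is_hydrogen)
                 for a in r.atoms]
        res = Residue(chain=r.chain, seqnum=r.seqnum,
                      insertion_code=r.insertion_code, name=r.name,
                      atoms=atoms, generic_number=r.generic_number,
                      classes=r.classes)
        residues.append(split_backbone_sidechain(res))
    mol = Chem.Mol(cx.ligand.mol)
    conf = mol.GetConformer()
    for i in range(mol.GetNumAtoms()):
        p = conf.GetAtomPosition(i)
        conf.SetAtomPosition(i, (R @ np.array([p.x, p.y, p.z]) + t).tolist())
    return Complex(residues=residues, ligand=_ligand_from_rdkit(mol, "mol"),
                   identifier=cx.identifier,
                   has_polar_hydrogens=cx.has_polar_hydrogens)
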