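"""Profile averaging, silencing, contact frequencies, hotspots,
differential profiles and outlier ranking."""

import numpy as np
import pytest

from siftmat.matrix import CompatibilityError, InteractionMatrix, MatrixError
from siftmat.profiles import (average_profile, contact_frequency,
                              differential_profile, hotspots, outlier_scan,
                              read_profile, silence, write_profile)


def _matrices_with_cell(n_set: int, n_total: int, make_block,
                        cell=("A", "P"), generic="3x32", fp="testparams"):
    """n_total single-position matrices; the cell is 1 in the first
    n_set of them."""
    out = []
    for i in range(n_total):
        cells = {cell: 1, (cell[0], "Any"): 1} if i < n_set else {}
        blk = make_block(cells, key=("A", 1, "", "SER"), generic=generic)
        out.append(InteractionMatrix(blocks=[blk], complex_id=f"m{i}",
                                     params_fingerprint=fp))
    return out


class TestAverageProfile:
    def test_identical_matrices_mean_is_matrix(self, make_block):
        mats = _matrices_with_cell(10, 10, make_block)
        prof = average_profile(mats)
        assert prof.block("3x32")[0, 3] == pytest.approx(1.0)
        assert prof.support == [10]

    def test_two_of_ten_silenced(self, make_block):
        prof = average_profile(_matrices_with_cell(2, 10, make_block))
        assert prof.block("3x32")[0, 3] == 0.0  # 0.2 < 0.3 silenced

    def test_three_of_ten_retained_at_boundary(self, make_block):
        prof = average_profile(_matrices_with_cell(3, 10, make_block))
        assert prof.block("3x32")[0, 3] == pytest.approx(0.3)  # not "lower than"

    def test_single_matrix_threshold_zero_is_cast(self, make_random_matrix):
        m = make_random_matrix(np.random.default_rng(2), n_res=3,
                               generic_numbers=["1x50", "2x50", "3x50"])
        prof = average_profile([m], threshold=0.0)
        for pos, blk in zip(prof.positions, prof.values):
            assert np.array_equal(blk, m.blocks[prof.positions.index(pos)]
                                  .counts.astype(float))

    def test_denominator_modes_with_absent_positions(self, make_block):
        from siftmat.matrix import align_by_generic
        a = InteractionMatrix(
            blocks=[make_block({("A", "P"): 1}, generic="3x32")],
            complex_id="a", params_fingerprint="fp")
        b = InteractionMatrix(
            blocks=[make_block({("H", "H"): 1}, generic="4x50")],
            complex_id="b", params_fingerprint="fp")
        aligned = align_by_generic([a, b])
        all_m = average_profile(aligned, threshold=0.0,
                                denominator_mode="all_matrices")
        present = average_profile(aligned, threshold=0.0,
                                  denominator_mode="present_only")
        assert all_m.block("3x32")[0, 3] == pytest.approx(0.5)
        assert present.block("3x32")[0, 3] == pytest.approx(1.0)

    def test_mixed_params_rejected(self, make_block):
        mats = _matrices_with_cell(2, 2, make_block)
        mats[1].params_fingerprint = "different"
        with pytest.raises(CompatibilityError):
            average_profile(mats)

    def test_silencing_idempotent(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(0, 1, size=(7, 9))
        once = silence(v, 0.3)
        assert np.array_equal(silence(once, 0.3), once)
        assert (once[once > 0] >= 0.3 - 1e-12).all()


class TestContactFrequency:
    def test_fraction_counts_any_nonzero_cell(self, make_block):
        freq = contact_frequency(_matrices_with_cell(25, 35, make_block))
        assert freq.fractions["3x32"] == pytest.approx(25 / 35)

    def test_position_absent_everywhere_is_zero(self, make_block):
        freq = contact_frequency(_matrices_with_cell(0, 5, make_block))
        assert freq.fractions["3x32"] == 0.0

    def test_single_matrix_fraction_is_zero_or_one(self, make_block):
        freq = contact_frequency(_matrices_with_cell(1, 1, make_block))
        assert set(freq.fractions.values()) <= {0.0, 1.0}

    def test_order_invariance(self, make_block):
        mats = _matrices_with_cell(3, 6, make_block)
        f1 = contact_frequency(mats)
        f2 = contact_frequency(mats[::-1])
        assert f1.fractions == f2.fractions

    def test_dominant_labels_carry_categories(self, make_block):
        freq = contact_frequency(_matrices_with_cell(5, 5, make_block,
                                                     cell=("D", "A")))
        labels = freq.dominant_labels(0.3)["3x32"]
        assert ("D", "A", "hb_acceptor", 1.0) in labels


class TestHotspots:
    def _freq(self, fractions):
        from siftmat.profiles import FrequencyTable
        return FrequencyTable(positions=list(fractions),
                              fractions=dict(fractions),
                              cell_fractions={p: np.zeros((7, 9))
                                              for p in fractions},
                              n_matrices=100, denominator_mode="all_matrices")

    def test_strictly_greater_than(self):
        freq = self._freq({"1x50": 0.31, "2x50": 0.30, "3x50": 0.29})
        assert hotspots(freq, 0.30) == ["1x50"]

    def test_empty_table(self):
        assert hotspots(self._freq({})) == []

    def test_all_max_sorted_by_position(self):
        freq = self._freq({"7x38": 1.0, "3x32": 1.0, "3x33": 1.0})
        assert hotspots(freq, 0.30) == ["3x32", "3x33", "7x38"]

    def test_zero_threshold_returns_all_contacted(self):
        freq = self._freq({"1x50": 0.01, "2x50": 0.0})
        assert hotspots(freq, 0.0) == ["1x50"]


class TestDifferentialProfile:
    def test_identical_profiles_all_common_zero(self, make_block):
        mats = _matrices_with_cell(5, 5, make_block)
        p = average_profile(mats)
        diff = differential_profile(p, p)
        assert set(diff.classification.values()) == {"common"}
        assert not any(d.any() for d in diff.differences)

    def test_unique_positions(self, make_block):
        from siftmat.matrix import align_by_generic
        a = InteractionMatrix(
            blocks=[make_block({("A", "D"): 1}, generic="3x32")],
            complex_id="a", params_fingerprint="fp")
        b = InteractionMatrix(
            blocks=[make_block({("H", "H"): 1}, generic="5x42")],
            complex_id="b", params_fingerprint="fp")
        pa = average_profile(align_by_generic([a]), threshold=0.0)
        pb = average_profile(align_by_generic([b]), threshold=0.0)
        # put both on the same axis by aligning the union
        both = align_by_generic([a, b])
        pa = average_profile([both[0]], threshold=0.0)
        pb = average_profile([both[1]], threshold=0.0)
        diff = differential_profile(pa, pb)
        assert diff.classification["3x32"] == "unique_to_a"
        assert diff.classification["5x42"] == "unique_to_b"

    def test_opposite_signed_cells_at_common_position(self, make_block):
        """One collection hydrogen-bonds where the other packs
        hydrophobically at the same position."""
        a = [InteractionMatrix(blocks=[make_block({("D", "A"): 1,
                                                   ("D", "Any"): 1},
                                                  generic="3x32")],
                               complex_id=f"a{i}", params_fingerprint="fp")
             for i in range(4)]
        b = [InteractionMatrix(blocks=[make_block({("H", "H"): 1,
                                                   ("H", "Any"): 1},
                                                  generic="3x32")],
                               complex_id=f"b{i}", params_fingerprint="fp")
             for i in range(4)]
        pa, pb = average_profile(a), average_profile(b)
        diff = differential_profile(pa, pb)
        assert diff.classification["3x32"] == "common"
        block = diff.block("3x32")
        assert block[1, 5] == pytest.approx(1.0)   # (D, A): a only
        assert block[2, 4] == pytest.approx(-1.0)  # (H, H): b only

    def test_axis_mismatch_rejected(self, make_block):
        pa = average_profile(_matrices_with_cell(2, 2, make_block,
                                                 generic="3x32"))
        pb = average_profile(_matrices_with_cell(2, 2, make_block,
                                                 generic="4x50"))
        with pytest.raises(MatrixError):
            differential_profile(pa, pb)


class TestOutlierScan:
    def test_identical_collection_all_zero(self, make_block):
        mats = _matrices_with_cell(6, 6, make_block)
        prof = average_profile(mats)
        ranking = outlier_scan(mats, prof)
        assert all(d == pytest.approx(0.0) for _, d in ranking)

    def test_deviant_matrix_ranks_first(self, make_block):
        mats = _matrices_with_cell(10, 10, make_block)
        extra = make_block({("A", "P"): 1, ("A", "Any"): 1, ("R", "R"): 3,
                            ("R", "Any"): 3}, generic="3x32")
        mats[-1] = InteractionMatrix(blocks=[extra], complex_id="deviant",
                                     params_fingerprint="testparams")
        prof = average_profile(mats, threshold=0.0)
        ranking = outlier_scan(mats, prof)
        assert ranking[0][0] == "deviant"
        assert ranking[0][1] > ranking[1][1]

    def test_stable_tie_break_by_complex_id(self, make_block):
        mats = _matrices_with_cell(2, 2, make_block)
        prof = average_profile(mats)
        ranking = outlier_scan(mats, prof)
        assert [cid for cid, _ in ranking] == sorted(m.complex_id for m in mats)


class TestProfileSerialization:
    def test_roundtrip(self, make_block, tmp_path):
        prof = average_profile(_matrices_with_cell(3, 10, make_block))
        path = tmp_path / "p.json"
        write_profile(path, prof)
        back = read_profile(path)
        assert back.positions == prof.positions
        assert back.support == prof.support
        assert back.threshold == prof.threshold
        assert back.n_matrices == prof.n_matrices
        for v1, v2 in zip(back.values, prof.values):
            assert np.allclose(v1, v2)
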