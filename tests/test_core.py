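"""Domain types, consolidation ordering, refolding and area bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mcrsims as M

from conftest import make_cube, make_peaklist


class TestPeakList:
    def test_valid_list_roundtrips_length(self):
        pl = make_peaklist(5)
        assert len(pl) == 5

    @pytest.mark.parametrize(
        "mz, labels",
        [
            ([10.0, 9.0, 11.0], ("a", "b", "c")),  # not increasing
            ([10.0, 10.0, 11.0], ("a", "b", "c")),  # not strictly increasing
            ([-1.0, 2.0], ("a", "b")),  # non-positive m/z
            ([10.0, 11.0], ("a", "a")),  # duplicate labels
            ([10.0, 11.0], ("a", "")),  # empty label
            ([10.0, 11.0], ("a",)),  # length mismatch
        ],
    )
    def test_invalid_lists_rejected(self, mz, labels):
        with pytest.raises(ValueError):
            M.PeakList(mz=np.array(mz), labels=labels)

    def test_unknown_polarity_rejected(self):
        with pytest.raises(ValueError, match="polarity"):
            M.PeakList(mz=np.array([1.0]), labels=("a",), polarity="both")


class TestSampleCube:
    def test_negative_intensities_rejected_not_clipped(self):
        arr = np.ones((2, 2, 3))
        arr[0, 0, 0] = -0.5
        with pytest.raises(ValueError, match="negative"):
            M.SampleCube(sample_id="s", intensities=arr)

    def test_dimensionality_enforced(self):
        with pytest.raises(ValueError):
            M.SampleCube(sample_id="s", intensities=np.ones((2, 3)))

    def test_unfold_is_row_major(self):
        arr = np.arange(8, dtype=float).reshape(2, 2, 2)
        cube = M.SampleCube(sample_id="s", intensities=arr)
        assert np.array_equal(cube.unfold()[1], arr[0, 1])


class TestConsolidate:
    def test_two_small_cubes_stack_in_input_order(self):
        pl = make_peaklist(3)
        c1 = make_cube("a", 2, 2, 3, seed=1)
        c2 = make_cube("b", 2, 2, 3, seed=2)
        mat = M.consolidate([c1, c2], pl)
        assert mat.data.shape == (8, 3)
        assert len(mat.row_map) == 8
        assert np.array_equal(mat.data[:4], c1.unfold())
        assert np.array_equal(mat.data[4:], c2.unfold())
        assert mat.row_map[0] == ("a", 0, 0)
        assert mat.row_map[5] == ("b", 0, 1)

    def test_eight_full_resolution_cubes_pixel_count(self):
        pl = make_peaklist(1)
        cubes = [make_cube(f"s{i}", 256, 256, 1, fill=0.0) for i in range(8)]
        mat = M.consolidate(cubes, pl)
        assert mat.total_pixels == 8 * 256 * 256 == 524_288

    def test_mixing_the_two_peak_lists_is_a_dimensional_error(self):
        # a 461-channel cube paired with a 417-entry list must be refused
        cube = M.SampleCube(sample_id="pos01", intensities=np.zeros((1, 2, 461)))
        negative_list = make_peaklist(417)
        with pytest.raises(ValueError, match="pos01"):
            M.consolidate([cube], negative_list)

    def test_duplicate_sample_ids_rejected(self):
        pl = make_peaklist(3)
        with pytest.raises(ValueError, match="duplicate"):
            M.consolidate([make_cube("a"), make_cube("a")], pl)

    def test_no_pretreatment_preserves_values_and_norm(self):
        pl = make_peaklist(4)
        cubes = [make_cube(f"s{i}", 3, 5, 4, seed=i) for i in range(3)]
        mat = M.consolidate(cubes, pl)
        stacked = np.vstack([c.unfold() for c in cubes])
        assert np.array_equal(mat.data, stacked)  # bit-exact, no scaling
        norms_sq = sum(np.linalg.norm(c.intensities) ** 2 for c in cubes)
        assert np.isclose(np.linalg.norm(mat.data), np.sqrt(norms_sq), rtol=1e-12)

    @given(
        h1=st.integers(1, 4), w1=st.integers(1, 4),
        h2=st.integers(1, 4), w2=st.integers(1, 4),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_row_map_is_a_bijection(self, h1, w1, h2, w2):
        pl = make_peaklist(2)
        mat = M.consolidate(
            [make_cube("a", h1, w1, 2, fill=1.0), make_cube("b", h2, w2, 2, fill=2.0)], pl
        )
        seen = set()
        for row in range(mat.total_pixels):
            sid, r, c = mat.loc_of(row)
            assert mat.row_of(sid, r, c) == row
            seen.add((sid, r, c))
        assert len(seen) == mat.total_pixels
        assert mat.row_map == sorted(seen, key=lambda t: mat.row_of(*t))


class TestRefoldScores:
    def _model(self, scores):
        k = scores.shape[1]
        loadings = np.eye(k, 3)  # unit rows
        return M.MCRModel(k=k, scores=scores, loadings=loadings, lof_percent=0.0,
                          n_iter=1, converged=True, seed=0)

    def test_constant_column_gives_uniform_images(self):
        pl = make_peaklist(3)
        mat = M.consolidate([make_cube("a", 2, 3, 3), make_cube("b", 4, 2, 3)], pl)
        model = self._model(np.ones((mat.total_pixels, 2)))
        images = M.refold_scores(model, mat)
        assert np.array_equal(images["a"][0], np.ones((2, 3)))
        assert np.array_equal(images["b"][1], np.ones((4, 2)))

    def test_row_major_ordering_contract(self):
        pl = make_peaklist(3)
        mat = M.consolidate([make_cube("a", 2, 2, 3)], pl)
        model = self._model(np.array([[0.0], [1.0], [2.0], [3.0]]))
        images = M.refold_scores(model, mat)
        assert np.array_equal(images["a"][0], [[0.0, 1.0], [2.0, 3.0]])

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_refold_then_unfold_is_identity(self, seed):
        rng = np.random.default_rng(seed)
        pl = make_peaklist(3)
        mat = M.consolidate([make_cube("a", 3, 2, 3), make_cube("b", 2, 5, 3)], pl)
        scores = rng.random((mat.total_pixels, 2))
        model = self._model(scores)
        assert np.array_equal(M.unfold_scores(M.refold_scores(model, mat), mat), scores)

    def test_row_count_mismatch_rejected(self):
        pl = make_peaklist(3)
        mat = M.consolidate([make_cube("a", 2, 2, 3)], pl)
        model = self._model(np.ones((5, 1)))
        with pytest.raises(ValueError, match="pixels"):
            M.refold_scores(model, mat)


class TestAreaEquivalent:
    def test_eight_standard_fields_make_one_by_two_mm(self):
        cubes = [make_cube(f"s{i}", 4, 4, 1, fill=1.0) for i in range(8)]
        eq = M.area_equivalent(cubes)
        assert eq.area_mm2 == pytest.approx(2.0)
        assert eq.rect_mm == pytest.approx((1.0, 2.0))

    @pytest.mark.parametrize(
        "n, field, expected",
        [(1, (500.0, 500.0), 0.25), (4, (100.0, 100.0), 0.04)],
    )
    def test_area_arithmetic(self, n, field, expected):
        cubes = [make_cube(f"s{i}", 2, 2, 1, fill=1.0, field_um=field) for i in range(n)]
        assert M.area_equivalent(cubes).area_mm2 == pytest.approx(expected)

    def test_heterogeneous_fields_refused(self):
        cubes = [
            make_cube("a", 2, 2, 1, fill=1.0, field_um=(500.0, 500.0)),
            make_cube("b", 2, 2, 1, fill=1.0, field_um=(250.0, 250.0)),
        ]
        with pytest.raises(ValueError, match="heterogeneous"):
            M.area_equivalent(cubes)


class TestMCRModelInvariants:
    def test_negative_factors_rejected(self):
        with pytest.raises(ValueError):
            M.MCRModel(k=1, scores=-np.ones((2, 1)), loadings=np.ones((1, 2)) / np.sqrt(2),
                       lof_percent=0.0, n_iter=1, converged=True, seed=0)

    def test_non_unit_loading_rows_rejected(self):
        with pytest.raises(ValueError, match="unit-norm"):
            M.MCRModel(k=1, scores=np.ones((2, 1)), loadings=np.full((1, 2), 3.0),
                       lof_percent=0.0, n_iter=1, converged=True, seed=0)

    def test_zero_row_requires_degenerate_flag(self):
        with pytest.raises(ValueError, match="degenerate"):
            M.MCRModel(k=1, scores=np.ones((2, 1)), loadings=np.zeros((1, 2)),
                       lof_percent=50.0, n_iter=1, converged=False, seed=0)
        model = M.MCRModel(k=1, scores=np.ones((2, 1)), loadings=np.zeros((1, 2)),
                           lof_percent=50.0, n_iter=1, converged=False, seed=0,
                           degenerate=True)
        assert model.degenerate
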