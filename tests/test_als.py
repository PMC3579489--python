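"""ALS engine: half-step exactness, convergence, monotonicity, fit metrics."""

import numpy as np
import pytest
from scipy.optimize import nnls as scipy_nnls

import mcrsims as M
from mcrsims.als import LOF_FLOOR, _reinit_component

from conftest import tiny_spec


class TestRandomInit:
    def test_same_seed_identical_different_seed_not(self):
        a = M.random_init(3, 8, 20, seed=5)
        b = M.random_init(3, 8, 20, seed=5)
        c = M.random_init(3, 8, 20, seed=6)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
        assert not np.array_equal(a[0], c[0])

    def test_factors_strictly_positive_and_loadings_unit_norm(self):
        scores, loadings = M.random_init(4, 10, 50, seed=0)
        assert np.all(scores > 0) and np.all(loadings > 0)
        assert np.allclose(np.linalg.norm(loadings, axis=1), 1.0, atol=1e-12)

    def test_dimensions_validated(self):
        with pytest.raises(ValueError):
            M.random_init(0, 5, 5, seed=0)


class TestHalfSteps:
    def test_rank_one_exact_given_true_loadings(self):
        rng = np.random.default_rng(0)
        c = rng.random(30) * 5
        s = rng.random(6)
        s /= np.linalg.norm(s)
        D = np.outer(c, s)
        recovered = M.update_scores(D, s[None, :])
        assert np.allclose(recovered[:, 0], c, atol=1e-8)

    def test_interior_optimum_equals_ordinary_least_squares(self):
        rng = np.random.default_rng(1)
        C_true = rng.random((40, 3)) + 0.5
        S_true = rng.random((3, 9)) + 0.5
        D = C_true @ S_true
        C = M.update_scores(D, S_true)
        C_ols = np.linalg.lstsq(S_true.T, D.T, rcond=None)[0].T
        assert np.allclose(C, C_ols, atol=1e-8)

    def test_single_pixel_matches_bruteforce_minimizer(self):
        # D = [1, 0] against fixed loading [0.6, 0.8]: grid + calculus say 0.6
        D = np.array([[1.0, 0.0]])
        s = np.array([[0.6, 0.8]])
        c_grid = min(np.linspace(0, 2, 20001),
                     key=lambda c: np.linalg.norm(D - c * s))
        score = M.update_scores(D, s)[0, 0]
        assert score == pytest.approx(0.6, abs=1e-10)
        assert score == pytest.approx(c_grid, abs=1e-4)

    def test_update_loadings_rows_unit_norm(self):
        rng = np.random.default_rng(2)
        D = rng.random((30, 8))
        C = rng.random((30, 2))
        S = M.update_loadings(D, C)
        assert np.allclose(np.linalg.norm(S, axis=1), 1.0, atol=1e-12)


class TestLackOfFit:
    def test_perfect_reconstruction_is_zero(self):
        rng = np.random.default_rng(3)
        C = rng.random((20, 2))
        S = rng.random((2, 5))
        assert M.lack_of_fit(C @ S, C, S) == pytest.approx(0.0, abs=1e-10)

    def test_zero_scores_give_one_hundred_percent(self):
        rng = np.random.default_rng(4)
        D = rng.random((10, 4))
        assert M.lack_of_fit(D, np.zeros((10, 2)), np.zeros((2, 4))) == pytest.approx(100.0)

    def test_matches_naive_elementwise_computation(self):
        rng = np.random.default_rng(5)
        D = rng.random((12, 6))
        C = rng.random((12, 3))
        S = rng.random((3, 6))
        num = sum((D[i, j] - C[i] @ S[:, j]) ** 2 for i in range(12) for j in range(6))
        den = sum(D[i, j] ** 2 for i in range(12) for j in range(6))
        assert M.lack_of_fit(D, C, S) == pytest.approx(100 * np.sqrt(num / den), rel=1e-10)

    def test_zero_data_rejected(self):
        with pytest.raises(ValueError):
            M.lack_of_fit(np.zeros((3, 3)), np.ones((3, 1)), np.ones((1, 3)))


class TestFitMCR:
    def test_rank_one_matrix_recovered_exactly(self):
        rng = np.random.default_rng(6)
        D = np.outer(rng.random(50) + 0.1, rng.random(7) + 0.1)
        model = M.fit_mcr(D, M.ALSConfig(k=1, seed=0))
        assert model.lof_percent < 1e-4

    def test_noiseless_two_component_phantom_recovered(self):
        comps = (
            M.ComponentSpec(role="background", present_in=(0,), amplitude=100.0),
            M.ComponentSpec(role="spot", present_in=(0,), amplitude=80.0),
        )
        spec = M.PhantomSpec(n_samples=1, height=16, width=16, n_channels=10,
                             components=comps, seed=5)
        truth = M.generate_phantom(spec)
        mat = M.consolidate(truth.cubes, truth.peaklist)
        model = M.fit_mcr(mat, M.ALSConfig(k=2, seed=1))
        assert model.lof_percent < 0.1
        cos = M.loading_cosines(truth.true_loadings, model.loadings)
        assert cos.min() >= 0.99

    def test_lof_floor_declares_convergence(self):
        D = np.outer(np.arange(1, 30, dtype=float), np.ones(4))
        model = M.fit_mcr(D, M.ALSConfig(k=1, seed=2))
        assert model.converged
        assert model.lof_percent <= LOF_FLOOR

    def test_monotone_lack_of_fit_on_noisy_data(self):
        truth = M.generate_phantom(tiny_spec(noise="poisson"))
        mat = M.consolidate(truth.cubes, truth.peaklist)
        for seed in (0, 1, 2):
            model = M.fit_mcr(mat, M.ALSConfig(k=3, seed=seed))
            assert np.all(np.diff(model.lof_trace) <= 1e-10)

    def test_k_exceeding_rank_bound_rejected(self):
        with pytest.raises(ValueError, match="k="):
            M.fit_mcr(np.ones((4, 3)), M.ALSConfig(k=4))

    def test_non_finite_data_rejected(self):
        D = np.ones((5, 3))
        D[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            M.fit_mcr(D, M.ALSConfig(k=1))

    def test_init_loadings_steer_the_fit(self, tiny_truth, tiny_matrix):
        cfg = M.ALSConfig(k=3, seed=9, init_loadings=tiny_truth.true_loadings)
        model = M.fit_mcr(tiny_matrix, cfg)
        cos = M.loading_cosines(tiny_truth.true_loadings, model.loadings)
        assert cos.min() >= 1 - 1e-6  # perfect start is a fixed point

    def test_config_validation(self):
        with pytest.raises(ValueError):
            M.ALSConfig(k=0)
        with pytest.raises(ValueError):
            M.ALSConfig(k=1, tol=0.0)
        with pytest.raises(ValueError):
            M.ALSConfig(k=2, init_loadings=np.ones((3, 4)))
        with pytest.raises(ValueError):
            M.ALSConfig(k=1, init_loadings=-np.ones((1, 4)))


class TestDegenerateHandling:
    def test_reinit_component_never_worsens_the_fit(self):
        rng = np.random.default_rng(8)
        D = rng.random((40, 6))
        C = rng.random((40, 2))
        C[:, 1] = 0.0
        S = np.vstack([rng.random(6), np.zeros(6)])
        S[0] /= np.linalg.norm(S[0])
        before = np.linalg.norm(D - C @ S)
        _reinit_component(D, C, S, 1)
        after = np.linalg.norm(D - C @ S)
        assert after <= before + 1e-12
        assert np.all(S[1] >= 0) and np.linalg.norm(S[1]) == pytest.approx(1.0, abs=1e-9)


class TestBruteForceOracle:
    @staticmethod
    def _grid_unit_vectors(m: int, steps: int = 4):
        """All non-negative unit vectors on a coarse simplex grid."""
        from itertools import product

        vecs = []
        for w in product(range(steps + 1), repeat=m):
            if sum(w) == 0:
                continue
            v = np.array(w, dtype=float)
            vecs.append(v / np.linalg.norm(v))
        return np.unique(np.round(vecs, 12), axis=0)

    @classmethod
    def _grid_lof(cls, D: np.ndarray, k: int) -> float:
        """Coarse grid search: enumerate loading tuples, exact NNLS scores."""
        from itertools import combinations_with_replacement

        vecs = cls._grid_unit_vectors(D.shape[1])
        best = np.inf
        for idx in combinations_with_replacement(range(len(vecs)), k):
            S = vecs[list(idx)]
            A = S.T  # channels x k
            resid_sq = 0.0
            for row in D:
                _, r = scipy_nnls(A, row)
                resid_sq += r * r
            lof = 100 * np.sqrt(resid_sq) / np.linalg.norm(D)
            best = min(best, lof)
        return best

    @pytest.mark.parametrize("seed, k", [(0, 1), (1, 1), (0, 2), (2, 2)])
    def test_als_at_least_matches_coarse_grid(self, seed, k):
        rng = np.random.default_rng(seed)
        D = rng.random((6, 4)) ** 2 * 10
        model = M.fit_mcr(D, M.ALSConfig(k=k, seed=seed))
        grid = self._grid_lof(D, k)
        assert model.lof_percent <= grid + 1.0
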