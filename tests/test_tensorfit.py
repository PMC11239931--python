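"""Fixed-mode CP decomposition, core consistency, and the scaling grid search."""

import numpy as np
import pytest

from lgpc.model import ScalingParams, contrast_design
from lgpc.tensorfit import (DeviantTensor, FixedModeCP, ScalingGridSearch,
                            core_consistency, grid_search, parafac_fixed,
                            select_best, tensor_from_maps)

from .oracles import cp_tensor

A_REF = contrast_design(ScalingParams(0.4, 0.85, 0.75)).A


def _exact_tensor(rng, n=4, m=60, A=None):
    A = A_REF if A is None else A
    B = rng.standard_normal((n, 2))
    C = rng.standard_normal((m, 2))
    return cp_tensor(A, B, C), B, C


class TestFixedModeCP:
    def test_exact_rank2_recovery(self):
        rng = np.random.default_rng(0)
        X, B, C = _exact_tensor(rng)
        fit = parafac_fixed(X, A_REF)
        assert fit.rss <= 1e-8 * (X ** 2).sum()
        # loadings recovered up to the scale convention: reconstruction matches
        est = FixedModeCP(A=A_REF).fit(X)
        np.testing.assert_allclose(est.reconstruct(), X, atol=1e-6)
        # C columns are unit norm (magnitude absorbed into B)
        np.testing.assert_allclose(np.linalg.norm(est.C_, axis=0), 1.0, atol=1e-9)

    def test_noise_rss_matches_noise_energy(self):
        rng = np.random.default_rng(1)
        X, _, _ = _exact_tensor(rng, m=400)
        E = 0.05 * rng.standard_normal(X.shape)
        fit = parafac_fixed(X + E, A_REF)
        noise = (E ** 2).sum()
        assert 0.5 * noise <= fit.rss <= 1.1 * noise

    def test_rank1_tensor_fit_exactly(self):
        # a tensor whose Contrast-mode structure is a single vector is always
        # inside the fixed-A rank-2 model class (A nonsingular spans it)
        rng = np.random.default_rng(2)
        a = np.array([1.0, -0.5])
        X = np.einsum("i,j,k->ijk", a, rng.standard_normal(4),
                      rng.standard_normal(50))
        fit = parafac_fixed(X, A_REF)
        assert fit.rss <= 1e-10 * (X ** 2).sum()

    def test_singular_fixed_matrix_rejected(self):
        rng = np.random.default_rng(3)
        X, _, _ = _exact_tensor(rng)
        with pytest.raises(ValueError, match="rank-deficient"):
            parafac_fixed(X, np.array([[1.0, 2.0], [2.0, 4.0]]))

    def test_all_zero_tensor(self):
        fit = parafac_fixed(np.zeros((2, 3, 10)), A_REF)
        assert fit.rss == 0.0
        assert np.isnan(fit.core_consistency)
        np.testing.assert_array_equal(fit.B, 0.0)

    def test_rss_invariant_to_column_scaling_of_A(self):
        rng = np.random.default_rng(4)
        X, _, _ = _exact_tensor(rng, m=80)
        X = X + 0.1 * rng.standard_normal(X.shape)
        r1 = parafac_fixed(X, A_REF).rss
        r2 = parafac_fixed(X, A_REF @ np.diag([2.0, 0.5])).rss
        assert r1 == pytest.approx(r2, rel=1e-6)

    def test_rss_non_increasing_in_iteration_budget(self):
        rng = np.random.default_rng(5)
        X, _, _ = _exact_tensor(rng, m=100)
        X = X + 0.3 * rng.standard_normal(X.shape)
        rss = [FixedModeCP(A=A_REF, max_iter=k, tol=0.0,
                           n_random_starts=0).fit(X).rss_
               for k in (1, 2, 4, 8, 16)]
        assert all(a >= b - 1e-12 for a, b in zip(rss, rss[1:]))


class TestCoreConsistency:
    def test_exact_structure_is_100(self):
        rng = np.random.default_rng(6)
        X, _, _ = _exact_tensor(rng)
        fit = parafac_fixed(X, A_REF)
        assert fit.core_consistency == pytest.approx(100.0, abs=1e-6)
        assert core_consistency(fit, X) == pytest.approx(100.0, abs=1e-6)

    def test_rank3_tensor_breaks_consistency(self):
        rng = np.random.default_rng(7)
        X, _, _ = _exact_tensor(rng, n=5, m=120)
        nuisance = cp_tensor(rng.standard_normal((2, 1)),
                             rng.standard_normal((5, 1)),
                             rng.standard_normal((120, 1))) * 1.5
        fit = parafac_fixed(X + nuisance, A_REF)
        assert fit.core_consistency < 80.0

    def test_consistency_monotone_in_snr(self):
        rng = np.random.default_rng(8)
        X, _, _ = _exact_tensor(rng, n=3, m=100)
        scale = np.sqrt((X ** 2).mean())
        E0 = rng.standard_normal(X.shape)  # one noise direction, scaled
        ccs = [parafac_fixed(X + noise * scale * E0, A_REF).core_consistency
               for noise in (0.1, 0.5, 1.5)]
        assert ccs[0] > ccs[1] > ccs[2]


class TestGridSearch:
    def test_default_grid_has_9261_cells(self):
        rng = np.random.default_rng(9)
        X, _, _ = _exact_tensor(rng, n=3, m=40)
        gs = ScalingGridSearch().fit(X)
        assert gs.n_models_ == 21 * 21 * 21 == 9261
        assert len(gs.table_) == 9261

    def test_single_cell_grid_equals_single_fit(self):
        rng = np.random.default_rng(10)
        X, _, _ = _exact_tensor(rng, n=3, m=40)
        p = (0.4, 0.85, 0.75)
        gs = grid_search(X, s0_values=[p[0]], s1_values=[p[1]], s2_values=[p[2]],
                         threshold=0.0)
        single = parafac_fixed(X, contrast_design(ScalingParams(*p)).A)
        assert gs.rss_[0] == pytest.approx(single.rss, rel=1e-6, abs=1e-12)

    def test_threshold_zero_gives_global_minimum(self):
        rng = np.random.default_rng(11)
        X, _, _ = _exact_tensor(rng, n=3, m=40)
        gs = ScalingGridSearch(s0_values=np.linspace(0, 1, 5),
                               s1_values=np.linspace(0, 2, 5),
                               s2_values=np.linspace(0.1, 2, 5)).fit(X)
        best = select_best(gs, threshold=0.0)
        assert best is not None
        idx, _, _ = best
        finite = np.where(gs.valid_, gs.rss_, np.inf)
        ok = finite.copy()
        ok[~(gs.consistency_ > 0)] = np.inf
        assert idx == int(np.argmin(ok))

    def test_unreachable_threshold_gives_empty_result(self):
        rng = np.random.default_rng(12)
        X, _, _ = _exact_tensor(rng, n=3, m=40)
        gs = ScalingGridSearch(s0_values=[0.3], s1_values=[0.9],
                               s2_values=[0.8], threshold=100.5).fit(X)
        assert gs.best_params_ is None
        assert select_best(gs, threshold=100.5) is None

    def test_degenerate_cells_recorded_not_fatal(self):
        rng = np.random.default_rng(13)
        X, _, _ = _exact_tensor(rng, n=3, m=40)
        # s2 = 0 makes the PE2 column equal the PE1 column -> singular
        gs = ScalingGridSearch(s0_values=[0.5], s1_values=[0.9],
                               s2_values=[0.0, 0.8]).fit(X)
        assert not gs.valid_[0] and np.isinf(gs.rss_[0])
        assert gs.valid_[1] and np.isfinite(gs.rss_[1])

    def test_quick_parameter_recovery(self):
        from lgpc.benchmarks import run_recovery
        planted = ScalingParams(0.4, 0.8, 0.7)
        best, gs = run_recovery(planted, seed=123)
        assert best is not None
        assert best.as_tuple() == pytest.approx(planted.as_tuple(), abs=1e-12)
        assert gs.consistency_[gs.best_index_] > 80.0


class TestDeviantTensor:
    def test_from_maps_flattening(self, roi_grid):
        maps = np.arange(2 * 3 * roi_grid.n_freqs * roi_grid.n_times,
                         dtype=float).reshape(2, 3, *roi_grid.shape)
        t = tensor_from_maps(maps, roi_grid, ic_indices=(0, 2, 5))
        assert t.values.shape == (2, 3, roi_grid.n_tf)
        assert t.metadata["tf_flatten_order"] == "frequency-major"
        np.testing.assert_array_equal(
            roi_grid.unflatten_tf(t.values[1, 2]), maps[1, 2])

    def test_non_finite_rejected(self, roi_grid):
        bad = np.full((2, 1, roi_grid.n_tf), np.nan)
        with pytest.raises(ValueError, match="finite"):
            DeviantTensor(values=bad, grid=roi_grid)
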