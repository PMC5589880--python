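"""Engine-level checks: design matrices, criterion arithmetic, the L1/L2
projection against a grid-search oracle, the SVD equivalence of the
unpenalized two-block fit, monotone convergence, and recovery behavior."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from blockcca import (SGCCA, DesignSpec, build_design, components, criterion,
                      fit, project_l1_l2)
from conftest import standardized_blocks

TWO_BLOCK = DesignSpec(block_order=("a", "b"), C=np.array([[0, 1], [1, 0]]))


class TestDesigns:
    @pytest.mark.parametrize("name, expected", [
        ("sequential", [[0, 1, 0], [1, 0, 1], [0, 1, 0]]),
        ("complete", [[0, 1, 1], [1, 0, 1], [1, 1, 0]]),
        ("reversed_sequential", [[0, 1, 1], [1, 0, 0], [1, 0, 0]]),
    ])
    def test_named_designs(self, name, expected):
        spec = build_design(name)
        np.testing.assert_array_equal(spec.C, expected)
        assert spec.block_order == ("rna", "imaging", "dx")

    def test_unknown_name_lists_valid_ones(self):
        with pytest.raises(ValueError, match="sequential"):
            build_design("circular")

    @pytest.mark.parametrize("C, match", [
        (np.array([[0, 1], [0, 0]]), "symmetric"),
        (np.array([[1, 1], [1, 0]]), "diagonal"),
        (np.zeros((2, 2)), "at least one connection"),
        (np.array([[0, 1, 0], [1, 0, 0], [0, 0, 0]]), "connected"),
    ])
    def test_invalid_matrices(self, C, match):
        order = tuple("abc"[: len(C)])
        with pytest.raises(ValueError, match=match):
            DesignSpec(block_order=order, C=C)


class TestCriterion:
    def test_identical_unit_variance_columns_give_two(self):
        x = np.arange(5, dtype=float)[:, None]
        x = (x - x.mean()) / x.std(ddof=1)
        value = criterion([x, x], [np.ones(1), np.ones(1)], TWO_BLOCK, "horst")
        assert value == pytest.approx(2.0)  # cov 1 counted for (j,k) and (k,j)

    @pytest.mark.parametrize("scheme", ["horst", "factorial", "centroid"])
    def test_five_subject_toy_matches_direct_arithmetic(self, scheme):
        rng = np.random.default_rng(0)
        X1, X2 = rng.standard_normal((5, 3)), rng.standard_normal((5, 2))
        a1, a2 = rng.standard_normal(3), rng.standard_normal(2)
        cov = (X1 @ a1) @ (X2 @ a2) / 4
        g = {"horst": cov, "factorial": cov ** 2, "centroid": abs(cov)}[scheme]
        assert criterion([X1, X2], [a1, a2], TWO_BLOCK, scheme) == pytest.approx(2 * g)


class TestProjection:
    def grid_oracle(self, v, bound, n_grid=4000):
        """Best soft-thresholded unit vector over a dense threshold grid."""
        best, best_val = None, -np.inf
        for lam in np.linspace(0, np.abs(v).max() * (1 - 1e-9), n_grid):
            s = np.sign(v) * np.maximum(np.abs(v) - lam, 0)
            nrm = np.linalg.norm(s)
            if nrm == 0:
                continue
            w = s / nrm
            if np.abs(w).sum() <= bound * (1 + 1e-9) and v @ w > best_val:
                best, best_val = w, v @ w
        return best, best_val

    def test_vacuous_bound_returns_unit_vector(self):
        v = np.array([1.0, -2.0, 0.5])
        np.testing.assert_allclose(project_l1_l2(v, np.sqrt(3)),
                                   v / np.linalg.norm(v), atol=1e-12)

    def test_tightest_bound_returns_signed_one_hot(self):
        w = project_l1_l2(np.array([1.0, -3.0, 2.0]), 1.0)
        np.testing.assert_allclose(w, [0.0, -1.0, 0.0], atol=1e-9)

    def test_two_entry_example_against_grid_and_kkt(self):
        v = np.array([3.0, 1.0])
        w = project_l1_l2(v, 1.2)
        assert np.linalg.norm(w) == pytest.approx(1.0, abs=1e-6)
        assert np.abs(w).sum() == pytest.approx(1.2, abs=1e-6)
        assert w[0] > w[1] > 0
        _, oracle_val = self.grid_oracle(v, 1.2)
        assert v @ w >= oracle_val - 1e-6

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000), st.integers(2, 10), st.floats(0.0, 1.0))
    def test_matches_grid_oracle_on_random_vectors(self, seed, p, frac):
        v = np.random.default_rng(seed).standard_normal(p)
        bound = 1.0 + frac * (np.sqrt(p) - 1.0)
        w = project_l1_l2(v, bound)
        assert np.linalg.norm(w) <= 1 + 1e-9
        assert np.abs(w).sum() <= bound * (1 + 1e-6)
        _, oracle_val = self.grid_oracle(v, bound)
        assert v @ w >= oracle_val - 1e-5
        if np.abs(w).sum() < bound - 1e-6:  # slack L1 -> plain normalization
            np.testing.assert_allclose(w, v / np.linalg.norm(v), atol=1e-9)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            project_l1_l2(np.zeros(3), 1.5)


class TestFit:
    def test_two_block_unpenalized_fit_is_the_leading_singular_pair(self):
        """tau = 1, identity scheme: the fit solves the covariance SVD."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X1, X2 = standardized_blocks(rng, 20, [5, 4])
            res = fit([X1, X2], design=TWO_BLOCK, scheme="horst", tau=1.0,
                      seed=seed)
            u, s, vt = np.linalg.svd(X1.T @ X2 / 19)
            assert res.criterion_trace[-1] / 2 == pytest.approx(s[0], abs=1e-6)
            assert abs(res.weights[0] @ u[:, 0]) == pytest.approx(1.0, abs=1e-6)
            assert abs(res.weights[1] @ vt[0]) == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("design", ["sequential", "complete", "reversed_sequential"])
    @pytest.mark.parametrize("scheme", ["horst", "factorial", "centroid"])
    def test_trace_monotone_and_constraints_tight(self, design, scheme):
        for seed in range(3):
            rng = np.random.default_rng(seed)
            blocks = standardized_blocks(rng, 30, [6, 5, 1])
            res = fit(blocks, design=design, scheme=scheme,
                      sparsity=(0.7, 0.7, None), seed=seed)
            assert np.all(np.diff(res.criterion_trace) >= -1e-10)
            for b, a in enumerate(res.weights):
                assert np.linalg.norm(a) <= 1 + 1e-8
                bound = (0.7 if b < 2 else 1.0) * np.sqrt(len(a))
                assert np.abs(a).sum() <= bound + 1e-8
            assert np.linalg.norm(res.weights[0]) == pytest.approx(1.0, abs=1e-6)

    def test_sparse_with_vacuous_bound_reproduces_regularized_tau1(self):
        rng = np.random.default_rng(5)
        blocks = standardized_blocks(rng, 25, [4, 3])
        dense = fit(blocks, design=TWO_BLOCK, scheme="centroid", tau=1.0, seed=1)
        sparse = fit(blocks, design=TWO_BLOCK, scheme="centroid",
                     sparsity=(1.0, 1.0), seed=1)
        for a, b in zip(dense.weights, sparse.weights):
            np.testing.assert_allclose(a, b, atol=1e-6)

    def test_column_permutation_equivariance(self):
        rng = np.random.default_rng(8)
        X1, X2 = standardized_blocks(rng, 40, [6, 4])
        perm = rng.permutation(6)
        r1 = fit([X1, X2], design=TWO_BLOCK, scheme="horst", seed=0)
        r2 = fit([X1[:, perm], X2], design=TWO_BLOCK, scheme="horst", seed=0)
        np.testing.assert_allclose(r2.weights[0], r1.weights[0][perm], atol=1e-6)
        assert r1.criterion_trace[-1] == pytest.approx(r2.criterion_trace[-1],
                                                       abs=1e-8)

    def test_canonical_sign_convention(self):
        rng = np.random.default_rng(9)
        blocks = standardized_blocks(rng, 30, [5, 4])
        res = fit(blocks, design=TWO_BLOCK, scheme="centroid", seed=2)
        for a in res.weights:
            assert a[np.argmax(np.abs(a))] > 0

    def test_multistart_criteria_agree(self):
        rng = np.random.default_rng(10)
        blocks = standardized_blocks(rng, 60, [5, 4, 1])
        finals = [fit(blocks, design="complete", scheme="factorial",
                      seed=s).criterion_trace[-1] for s in range(10)]
        assert max(finals) - min(finals) < 1e-4

    def test_criterion_bounded_by_connected_pairs(self):
        rng = np.random.default_rng(11)
        blocks = standardized_blocks(rng, 30, [6, 5, 1])
        for scheme in ("horst", "centroid"):
            res = fit(blocks, design="complete", scheme=scheme, seed=0)
            # standardized blocks: |cov| of unit-norm-weight components is
            # bounded by the largest block operator norm
            bound = 6 * max(np.linalg.norm(X, 2) ** 2 / (X.shape[0] - 1)
                            for X in blocks)
            assert res.criterion_trace[-1] <= bound

    def test_nonconvergence_warns_but_returns(self):
        rng = np.random.default_rng(12)
        blocks = standardized_blocks(rng, 30, [8, 7])
        with pytest.warns(RuntimeWarning, match="did not converge"):
            res = fit(blocks, design=TWO_BLOCK, scheme="centroid",
                      sparsity=(0.6, 0.6), max_iter=2, seed=0)
        assert res.converged is False

    def test_mismatched_rows_rejected(self):
        with pytest.raises(ValueError, match="rows"):
            fit([np.zeros((5, 2)), np.zeros((6, 2))], design=TWO_BLOCK)


class TestComponents:
    def test_scores_are_weighted_column_sums(self):
        rng = np.random.default_rng(0)
        blocks = standardized_blocks(rng, 15, [4, 3])
        res = fit(blocks, design=TWO_BLOCK, seed=0)
        scores = components(res, blocks)
        for X, a, y in zip(blocks, res.weights, scores):
            np.testing.assert_allclose(y, X @ a, atol=1e-12)

    def test_shape_mismatch_raises(self):
        rng = np.random.default_rng(1)
        blocks = standardized_blocks(rng, 15, [4, 3])
        res = fit(blocks, design=TWO_BLOCK, seed=0)
        with pytest.raises(ValueError, match="width"):
            components(res, [blocks[0][:, :3], blocks[1]])

    def test_supervised_fit_aligns_imaging_score_with_phenotype(self):
        """Adding the diagnosis block steers the imaging component toward the
        group contrast in most replicates."""
        from blockcca import SyntheticSpec, generate_multiblock
        from blockcca.preprocess import ConfoundResidualizer
        wins = 0
        for seed in range(20):
            ds = generate_multiblock(SyntheticSpec(
                n_case=30, n_control=30, covariate_effects={}, seed=seed))
            Xr = ConfoundResidualizer().fit_transform(ds.block_matrix("rna"))
            Xi = ConfoundResidualizer().fit_transform(ds.block_matrix("imaging"))
            y = ds.y().astype(float)
            dx = ((y - y.mean()) / y.std(ddof=1))[:, None]
            unsup = fit([Xr, Xi], design=TWO_BLOCK, seed=seed)
            sup = fit([Xr, Xi, dx], design="complete", seed=seed)
            def img_corr(res):
                return abs(np.corrcoef(res.components[1], y)[0, 1])
            wins += img_corr(sup) >= img_corr(unsup)
        assert wins >= 16
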