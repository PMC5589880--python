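"""Screening: group-model p-values against a normal-equations oracle, BH
step-up against a brute-force implementation, MANCOVA calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from blockcca import (MancovaInfeasibleError, MultiblockDataset, adjust_bh,
                      differential_table, fit_group_models, mancova)


def bh_bruteforce(p: np.ndarray, m: int) -> np.ndarray:
    """Literal step-up rule: adjusted_i = min(1, min_{j>=i} m p_(j) / j)."""
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    adj = np.empty_like(ranked)
    running = 1.0
    for i in range(len(ranked) - 1, -1, -1):
        running = min(running, m * ranked[i] / (i + 1))
        adj[i] = running
    out = np.empty_like(adj)
    out[order] = adj
    return out


def _dataset_from_blocks(blocks: dict, y: np.ndarray, seed=0) -> MultiblockDataset:
    rng = np.random.default_rng(seed)
    n = len(y)
    ids = pd.Index([f"S{i}" for i in range(n)])
    cov = pd.DataFrame({"age": rng.uniform(20, 60, n),
                        "sex": rng.binomial(1, 0.5, n).astype(float),
                        "smoking": rng.binomial(1, 0.5, n).astype(float)},
                       index=ids)
    return MultiblockDataset(
        blocks={k: pd.DataFrame(v, index=ids,
                                columns=[f"{k}{j}" for j in range(v.shape[1])])
                for k, v in blocks.items()},
        covariates=cov,
        phenotype=pd.Series(y, index=ids))


class TestGroupModels:
    def test_matches_normal_equations_oracle(self):
        """Two-sided t on the group coefficient, computed independently from
        the normal equations, to 1e-10."""
        rng = np.random.default_rng(7)
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        X = rng.standard_normal((8, 3))
        ds = _dataset_from_blocks({"b": X}, y, seed=7)
        table = fit_group_models(ds).table
        D = np.column_stack([np.ones(8), y, ds.covariates.to_numpy()])
        XtX_inv = np.linalg.inv(D.T @ D)
        for j in range(3):
            beta = XtX_inv @ D.T @ X[:, j]
            resid = X[:, j] - D @ beta
            s2 = resid @ resid / (8 - D.shape[1])
            t = beta[1] / np.sqrt(s2 * XtX_inv[1, 1])
            p = 2 * stats.t.sf(abs(t), df=8 - D.shape[1])
            row = table[table.variable == f"b{j}"].iloc[0]
            assert row.coef == pytest.approx(beta[1], abs=1e-10)
            assert row.raw_p == pytest.approx(p, abs=1e-10)

    def test_perfect_separation_p_is_numerically_zero(self):
        y = np.repeat([1, 0], 10)
        X = (y.astype(float) + 1e-9 * np.random.default_rng(0).standard_normal(20))[:, None]
        ds = _dataset_from_blocks({"b": X}, y)
        assert fit_group_models(ds).table.raw_p.iloc[0] < 1e-12

    def test_type_one_error_is_nominal_on_noise(self):
        """Fraction of p < 0.05 over 1000 independent noise variables."""
        rng = np.random.default_rng(42)
        y = np.repeat([1, 0], 100)
        ds = _dataset_from_blocks({"b": rng.standard_normal((200, 1000))}, y)
        frac = (fit_group_models(ds).table.raw_p < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(3)
        y = np.repeat([1, 0], 15)
        X = rng.standard_normal((30, 2))
        p1 = fit_group_models(_dataset_from_blocks({"b": X}, y)).table.raw_p
        p2 = fit_group_models(_dataset_from_blocks({"b": 7.3 * X - 2.0}, y)).table.raw_p
        np.testing.assert_allclose(p1, p2, atol=1e-10)

    def test_single_group_raises(self):
        X = np.random.default_rng(0).standard_normal((10, 2))
        ds = _dataset_from_blocks({"b": X}, np.ones(10, dtype=int))
        with pytest.raises(ValueError, match="both diagnostic groups"):
            fit_group_models(ds)

    def test_covariate_adjustment_restores_calibration(self):
        """A smoking effect plus a smoking-diagnosis association inflates the
        naive group test; adjusting for the covariates restores it."""
        rng = np.random.default_rng(11)
        n = 400
        y = np.repeat([1, 0], n // 2)
        smoking = np.where(y == 1, rng.binomial(1, 0.7, n), rng.binomial(1, 0.3, n))
        X = rng.standard_normal((n, 300)) + 0.6 * smoking[:, None]
        ids = pd.Index([f"S{i}" for i in range(n)])
        cov = pd.DataFrame({"age": rng.uniform(20, 60, n),
                            "sex": rng.binomial(1, 0.5, n).astype(float),
                            "smoking": smoking.astype(float)}, index=ids)
        ds = MultiblockDataset(
            blocks={"b": pd.DataFrame(X, index=ids,
                                      columns=[f"v{j}" for j in range(300)])},
            covariates=cov, phenotype=pd.Series(y, index=ids))
        adjusted_frac = (fit_group_models(ds).table.raw_p < 0.05).mean()
        # naive two-sample t ignoring covariates, on the same columns
        t, p_naive = stats.ttest_ind(X[y == 1], X[y == 0], axis=0)
        assert (p_naive < 0.05).mean() > 2 * 0.05
        assert 0.02 <= adjusted_frac <= 0.08


class TestBenjaminiHochberg:
    def test_published_family_of_52_anchors(self):
        from blockcca.published import SCREENING_TABLE
        raw = np.array([r[2] for r in SCREENING_TABLE])
        adj = adjust_bh(raw, m=52)
        assert f"{adj[0]:.2e}" == "3.79e-03"
        assert f"{adj[8]:.2e}" == "5.25e-01"

    def test_equal_p_values_adjust_to_themselves(self):
        np.testing.assert_allclose(adjust_bh(np.full(5, 0.2), m=5), 0.2)

    def test_matches_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            k = rng.integers(1, 40)
            p = rng.uniform(size=k)
            m = k + rng.integers(0, 10)
            np.testing.assert_allclose(adjust_bh(p, m=m), bh_bruteforce(p, m),
                                       atol=1e-12)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30),
           st.integers(0, 20))
    def test_stepup_properties(self, p_list, extra):
        p = np.array(p_list)
        adj = adjust_bh(p, m=len(p) + extra)
        assert np.all((0 <= adj) & (adj <= 1))
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(adj[order]) >= -1e-15)  # monotone in rank

    def test_family_smaller_than_tests_raises(self):
        with pytest.raises(ValueError, match="family size"):
            adjust_bh(np.array([0.1, 0.2, 0.3]), m=2)


class TestMancova:
    def test_planted_effect_is_detected(self):
        rng = np.random.default_rng(0)
        y = np.repeat([1.0, 0.0], 30)
        Y = np.column_stack([y + 0.01 * rng.standard_normal(60),
                             rng.standard_normal(60)])
        cov = rng.standard_normal((60, 3))
        res = mancova(Y, cov, y)
        assert res.p_value("group") < 1e-6

    def test_too_wide_block_is_an_explicit_error(self):
        rng = np.random.default_rng(1)
        n, p = 20, 16  # p + q + 1 = 20 >= n
        with pytest.raises(MancovaInfeasibleError, match="exceed"):
            mancova(rng.standard_normal((n, p)), rng.standard_normal((n, 3)),
                    np.repeat([1.0, 0.0], n // 2))

    def test_type_one_error_calibrated_on_noise(self):
        """Group rejection rate at alpha=0.05 over 200 pure-noise datasets."""
        rng = np.random.default_rng(2)
        y = np.repeat([1.0, 0.0], 100)
        rejections = 0
        for _ in range(200):
            Y = rng.standard_normal((200, 5))
            cov = rng.standard_normal((200, 3))
            rejections += mancova(Y, cov, y).p_value("group") < 0.05
        assert 0.02 <= rejections / 200 <= 0.09

    def test_wilks_statistic_available(self):
        rng = np.random.default_rng(3)
        y = np.repeat([1.0, 0.0], 25)
        res = mancova(rng.standard_normal((50, 4)), rng.standard_normal((50, 3)),
                      y, statistic="wilks")
        assert res.statistic == "wilks"
        assert set(res.table.index) >= {"group"}


class TestDifferentialTable:
    def test_sorted_with_adjusted_column(self, signal_dataset):
        table = differential_table(signal_dataset, m=52).table
        assert list(table.columns) == ["variable", "block", "coef", "raw_p", "adj_p"]
        assert table.raw_p.is_monotonic_increasing
        assert (table.adj_p >= table.raw_p - 1e-15).all()
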