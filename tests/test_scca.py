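"""Sparse CCA core against SVD/brute-force oracles and planted models."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mbcca.datamodel import ValidationError
from mbcca.scca import (
    _standardize,
    l1_project,
    loocv_extract,
    penalty_grid,
    permutation_significance,
    pmd_rank1,
    scca_fit,
    soft_threshold,
    tune_penalty,
)
from mbcca.synthetic import simulate_paired_omics


class TestSoftThreshold:
    def test_identity_full_shrinkage_and_hand_case(self):
        assert np.allclose(soft_threshold([1.0, -2.0], 0.0), [1.0, -2.0])
        assert np.allclose(soft_threshold([0.5], 1.0), [0.0])
        assert np.allclose(
            soft_threshold([3.0, -2.0, 0.5], 1.0), [2.0, -1.0, 0.0]
        )
        with pytest.raises(ValidationError):
            soft_threshold([1.0], -0.1)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(-10, 10), min_size=1, max_size=10),
        st.floats(0, 5),
    )
    def test_shrinks_toward_zero_preserving_sign(self, w, delta):
        out = soft_threshold(w, delta)
        w = np.asarray(w)
        assert (np.abs(out) <= np.abs(w) + 1e-12).all()
        assert ((np.sign(out) == np.sign(w)) | (out == 0)).all()


class TestL1Project:
    def test_inactive_constraint_at_sqrt_p(self):
        w = np.array([3.0, -1.0, 2.0, 0.5])
        out = l1_project(w, np.sqrt(4))
        assert np.allclose(out, w / np.linalg.norm(w))

    def test_c_one_selects_single_largest_with_tie_break(self):
        out = l1_project(np.array([1.0, -3.0, 2.0]), 1.0)
        assert np.allclose(out, [0.0, -1.0, 0.0])
        tied = l1_project(np.array([2.0, -2.0]), 1.0)
        assert np.allclose(tied, [1.0, 0.0])  # lowest index wins

    def test_matches_fine_grid_scan(self, rng):
        for _ in range(20):
            w = rng.standard_normal(12)
            c = float(rng.uniform(1.0, np.sqrt(12)))
            out = l1_project(w, c)
            assert np.abs(np.linalg.norm(out) - 1.0) < 1e-9
            assert np.abs(out).sum() <= c + 1e-6
            # brute-force: smallest feasible delta on a fine grid (vectorized)
            deltas = np.linspace(0, np.abs(w).max() * (1 - 1e-9), 100_001)
            S = np.sign(w) * np.maximum(np.abs(w)[None, :] - deltas[:, None], 0)
            norms = np.linalg.norm(S, axis=1)
            ok = norms > 0
            l1 = np.full(len(deltas), np.inf)
            l1[ok] = np.abs(S[ok] / norms[ok, None]).sum(axis=1)
            first = np.flatnonzero(l1 <= c)[0]
            best = S[first] / norms[first]
            assert abs(np.abs(out).sum() - np.abs(best).sum()) < 1e-4

    def test_zero_vector_rejected(self):
        with pytest.raises(ValidationError):
            l1_project(np.zeros(3), 1.0)


class TestPmdRank1:
    def test_no_sparsity_limit_equals_svd(self, rng):
        Z = rng.standard_normal((8, 10))
        u, v, d, conv = pmd_rank1(
            Z, np.sqrt(8), np.sqrt(10), tol=1e-12, max_iter=5000
        )
        assert conv
        U, s, Vt = np.linalg.svd(Z)
        ref_u = U[:, 0]
        if ref_u[np.argmax(np.abs(ref_u))] < 0:
            ref_u = -ref_u
        assert d == pytest.approx(s[0], abs=1e-6)
        assert abs(u @ ref_u) > 1 - 1e-6

    def test_recovers_planted_sparse_rank_one(self):
        a = np.zeros(20)
        a[[2, 5, 11]] = [0.8, -0.36, 0.48]
        b = np.zeros(15)
        b[[0, 7]] = [0.6, 0.8]
        Z = 5.0 * np.outer(a, b)
        c_a, c_b = np.abs(a).sum() + 1e-6, np.abs(b).sum() + 1e-6
        u, v, d, _ = pmd_rank1(Z, c_a, c_b, tol=1e-12, max_iter=5000)
        assert abs(u @ a) >= 1 - 1e-6
        assert abs(v @ b) >= 1 - 1e-6

    def test_sign_convention_invariance(self, rng):
        Z = rng.standard_normal((6, 7))
        _, _, d1, _ = pmd_rank1(Z, 2.0, 2.0)
        u2, _, d2, _ = pmd_rank1(-Z, 2.0, 2.0)
        assert d1 == pytest.approx(d2, abs=1e-9)
        assert u2[np.argmax(np.abs(u2))] > 0


class TestPenaltyGrid:
    def test_stated_defaults(self):
        grid = penalty_grid()
        assert len(grid) == 20
        assert grid[0] == pytest.approx(0.02)
        assert grid[-1] == pytest.approx(0.5)
        spacing = np.diff(grid)
        assert np.allclose(spacing, (0.5 - 0.02) / 19)

    def test_degenerate_grids_rejected(self):
        with pytest.raises(ValidationError):
            penalty_grid(0.3, 0.3, 5)
        with pytest.raises(ValidationError):
            penalty_grid(0.02, 0.5, 1)


class TestSccaFit:
    def test_noiseless_identity(self):
        X, Y, truth = simulate_paired_omics(
            50, 40, 40, 1, 6, [1.0], 0.0, seed=1
        )
        fit = scca_fit(X, Y, 1, 1.0)
        comp = fit.components[0]
        assert comp.canonical_correlation == pytest.approx(1.0, abs=1e-6)
        assert set(comp.selected_x) == truth.support_x(0)
        assert set(comp.selected_y) == truth.support_y(0)

    def test_full_penalty_reproduces_truncated_svd(self, rng):
        X = rng.standard_normal((30, 20))
        Y = rng.standard_normal((30, 25))
        Xs, _ = _standardize(X)
        Ys, _ = _standardize(Y)
        s = np.linalg.svd(Xs.T @ Ys, compute_uv=False)
        fit = scca_fit(X, Y, 4, 1.0)
        assert np.allclose([c.d for c in fit.components], s[:4], atol=1e-6)

    def test_planted_two_component_recovery(self):
        cosines = []
        pen = np.sqrt(10) / np.sqrt(200)
        for seed in range(5):
            X, Y, truth = simulate_paired_omics(
                200, 200, 200, 2, 10, [0.9, 0.7], 1.0, seed=seed
            )
            fit = scca_fit(X, Y, 2, pen, tol=1e-8)
            per_comp = []
            for comp in fit.components:
                u = comp.u.to_numpy()
                best = max(
                    abs(u @ truth.loadings_x[:, k]) for k in range(2)
                )
                per_comp.append(best)
            cosines.append(per_comp)
        med = np.median(np.asarray(cosines), axis=0)
        assert (med >= 0.9).all()

    def test_null_correlation_below_permutation_quantile(self, rng):
        X = rng.standard_normal((100, 20))
        Y = rng.standard_normal((100, 20))
        fit = scca_fit(X, Y, 1, 0.3, tol=1e-8)
        obs = fit.components[0].canonical_correlation
        nulls = []
        for _ in range(99):
            perm = rng.permutation(100)
            nf = scca_fit(X, Y[perm], 1, 0.3, tol=1e-8)
            nulls.append(nf.components[0].canonical_correlation)
        assert obs < np.quantile(nulls, 0.95)

    def test_unit_norms_and_l1_budgets(self):
        X, Y, _ = simulate_paired_omics(40, 30, 35, 2, 5, [0.9, 0.8], 1.0, 3)
        pen = 0.4
        fit = scca_fit(X, Y, 2, pen, tol=1e-8)
        for comp in fit.components:
            u, v = comp.u.to_numpy(), comp.v.to_numpy()
            assert np.linalg.norm(u) == pytest.approx(1.0, abs=1e-8)
            assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-8)
            assert np.abs(u).sum() <= pen * np.sqrt(30) + 1e-6
            assert np.abs(v).sum() <= pen * np.sqrt(35) + 1e-6

    def test_deflation_orthogonality(self, rng):
        X = rng.standard_normal((25, 12))
        Y = rng.standard_normal((25, 14))
        Xs, _ = _standardize(X)
        Ys, _ = _standardize(Y)
        Z = Xs.T @ Ys
        fit = scca_fit(X, Y, 3, 0.6, tol=1e-10)
        Zd = Z.copy()
        for comp in fit.components:
            u, v = comp.u.to_numpy(), comp.v.to_numpy()
            Zd = Zd - comp.d * np.outer(u, v)
            assert abs(u @ Zd @ v) < 1e-8

    def test_sparsity_monotone_in_penalty_on_rank_one_data(self):
        X, Y, _ = simulate_paired_omics(60, 30, 30, 1, 6, [1.0], 0.0, seed=4)
        nnz_prev = None
        for pen in np.linspace(1.0, 0.2, 9):
            fit = scca_fit(X, Y, 1, pen)
            nnz = len(fit.components[0].selected_x)
            if nnz_prev is not None:
                assert nnz <= nnz_prev
            nnz_prev = nnz

    def test_sample_mismatch_and_bad_k_rejected(self, rng):
        X = rng.standard_normal((10, 5))
        Y = rng.standard_normal((11, 5))
        with pytest.raises(ValidationError):
            scca_fit(X, Y, 1, 0.5)
        with pytest.raises(ValidationError):
            scca_fit(X, rng.standard_normal((10, 5)), 6, 0.5)


class TestTunePenalty:
    def test_selected_at_least_as_good_as_endpoints(self):
        gains = []
        for seed in range(3):
            X, Y, _ = simulate_paired_omics(
                24, 40, 40, 1, 6, [0.9], 1.0, seed=seed
            )
            grid = penalty_grid(0.1, 0.9, 5)
            best, table = tune_penalty(X, Y, 1, grid)
            scores = table.set_index("penalty")["mean_cv_correlation"]
            gains.append(
                scores.loc[best]
                >= max(scores.iloc[0], scores.iloc[-1]) - 1e-12
            )
        assert all(gains)

    def test_tie_breaks_to_smallest_and_table_complete(self):
        X, Y, _ = simulate_paired_omics(20, 10, 10, 1, 3, [1.0], 0.0, seed=2)
        grid = penalty_grid(0.6, 1.0, 4)
        best, table = tune_penalty(X, Y, 1, grid)
        assert len(table) == 4
        # noiseless: every penalty achieves held-out correlation 1 -> tie
        assert best == pytest.approx(grid[0])

    def test_empty_grid_rejected(self, rng):
        X = rng.standard_normal((10, 4))
        with pytest.raises(ValidationError):
            tune_penalty(X, X, 1, [])


class TestPermutationSignificance:
    def test_saturated_null_gives_minimum_p(self):
        X, Y, _ = simulate_paired_omics(100, 30, 30, 1, 5, [0.9], 1.0, seed=2)
        out = permutation_significance(
            X, Y, 0.3, K=1, n_perm=199, seed=3, tol=1e-8
        )
        assert out["raw_p"].iloc[0] == pytest.approx(1 / 200)

    def test_adjusted_never_below_raw(self):
        X, Y, _ = simulate_paired_omics(
            30, 15, 15, 3, 4, [0.9, 0.6, 0.4], 1.0, seed=5
        )
        out = permutation_significance(
            X, Y, 0.4, K=3, n_perm=49, seed=1, tol=1e-6
        )
        assert (out["adjusted_p"] >= out["raw_p"] - 1e-12).all()

    def test_null_pvalues_super_uniform(self):
        # KS check of p-value uniformity under independent X, Y
        from scipy.stats import kstest

        pvals = []
        for rep in range(200):
            rng = np.random.default_rng(60_000 + rep)
            X = rng.standard_normal((20, 10))
            Y = rng.standard_normal((20, 10))
            out = permutation_significance(
                X, Y, 0.4, K=1, n_perm=39, seed=rep, tol=1e-5, max_iter=300
            )
            pvals.append(out["raw_p"].iloc[0])
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestLoocvExtract:
    def test_noiseless_robust_sets_equal_planted_support(self):
        X, Y, truth = simulate_paired_omics(
            30, 20, 20, 1, 4, [1.0], 0.0, seed=1
        )
        out = loocv_extract(X, Y, 1.0, K=1, retention=1.0)
        assert set(out[0]["robust_x"]) == truth.support_x(0)
        assert set(out[0]["robust_y"]) == truth.support_y(0)

    def test_planted_features_stable_noise_features_not(self):
        planted_rates, noise_rates = [], []
        pen = np.sqrt(8) / np.sqrt(60)
        for seed in range(5):
            X, Y, truth = simulate_paired_omics(
                100, 60, 60, 1, 8, [0.9], 1.0, seed=seed
            )
            out = loocv_extract(X, Y, pen, K=1, retention=0.9, tol=1e-8)
            rx = set(out[0]["robust_x"])
            support = truth.support_x(0)
            noise = {f"x{j:04d}" for j in range(60)} - support
            planted_rates.append(len(rx & support) / len(support))
            noise_rates.append(len(rx & noise) / len(noise))
        assert np.median(planted_rates) >= 0.9
        assert np.median(noise_rates) < 0.1

    def test_robust_subset_of_selected(self):
        X, Y, _ = simulate_paired_omics(20, 15, 15, 2, 4, [0.9, 0.7], 1.0, 6)
        fit_sets = loocv_extract(X, Y, 0.4, K=2, retention=0.5, tol=1e-6)
        fit = scca_fit(X, Y, 2, 0.4, tol=1e-6)
        for comp, robust in zip(fit.components, fit_sets):
            assert set(robust["robust_x"]) <= set(comp.selected_x)
            assert set(robust["robust_y"]) <= set(comp.selected_y)

    def test_too_few_samples_rejected(self, rng):
        X = rng.standard_normal((2, 5))
        with pytest.raises(ValidationError):
            loocv_extract(X, X, 0.5, K=1)
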