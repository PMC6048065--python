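"""Elastic-net selection, OLS refit, LMG importance, permutation GOF."""

import numpy as np
import pandas as pd
import pytest

from momira.cell_decomposition import (diagnosis_partial_r2, elasticnet_select,
                                       lmg_importance, permutation_gof,
                                       refit_variance_explained,
                                       shared_effect_test)


class TestElasticNetSelect:
    def test_informative_regressor_selected(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(60, 10))
            y = 2.0 * X[:, 0] + rng.normal(0, 1, 60)
            sel = elasticnet_select(y, pd.DataFrame(X, columns=[f"x{i}" for i in range(10)]),
                                    alpha_grid=(0.5, 1.0), n_lambda=20, cv=5,
                                    repeats=1, seed=seed)
            hits += "x0" in sel["selected"]
        assert hits >= 19

    def test_large_lambda_empties_selection(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 5))
        y = rng.normal(size=30)
        sel = elasticnet_select(y, X, alpha_grid=(1.0,), lambda_grid=[1e6],
                                cv=5, repeats=1, seed=0)
        assert sel["selected"] == []

    def test_ridge_path_matches_closed_form(self):
        rng = np.random.default_rng(2)
        n, p = 40, 6
        Q, _ = np.linalg.qr(rng.normal(size=(n, p)))
        X = Q * np.sqrt(n)                         # orthonormal-ish design
        y = X[:, 0] + rng.normal(0, 0.5, n)
        from momira.cell_decomposition import _ridge_path, _standardize_xy
        Xs, yc = _standardize_xy(X, y)
        lambdas = np.array([0.01, 0.1, 1.0])
        _, W = _ridge_path(Xs, yc, Xs[:0], lambdas)
        for j, lam in enumerate(lambdas):
            closed = np.linalg.solve(Xs.T @ Xs / n + lam * np.eye(p), Xs.T @ yc / n)
            assert np.allclose(W[:, j], closed, atol=1e-6)

    def test_too_few_samples_raise(self):
        with pytest.raises(ValueError):
            elasticnet_select(np.zeros(8), np.zeros((8, 2)))

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 4)); y = X[:, 1] + rng.normal(0, 1, 40)
        a = elasticnet_select(y, X, alpha_grid=(0.0, 1.0), n_lambda=10, cv=5,
                              repeats=1, seed=9)
        b = elasticnet_select(y, X, alpha_grid=(0.0, 1.0), n_lambda=10, cv=5,
                              repeats=1, seed=9)
        assert a["alpha"] == b["alpha"] and a["lambda"] == b["lambda"]
        assert a["cv_rmse"] == b["cv_rmse"]


class TestRefitR2:
    def test_exact_linear_r2_one(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 3))
        y = X @ np.array([1.0, -2.0, 0.5]) + 3
        assert refit_variance_explained(y, X) == pytest.approx(1.0)

    def test_single_regressor_equals_squared_correlation(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        y = 0.6 * x + rng.normal(0, 1, 50)
        r2 = refit_variance_explained(y, x[:, None])
        assert r2 == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2, abs=1e-12)

    def test_null_r2_matches_p_over_n_expectation(self):
        rng = np.random.default_rng(2)
        n, p, reps = 200, 5, 200
        r2s = [refit_variance_explained(rng.normal(size=n), rng.normal(size=(n, p)))
               for _ in range(reps)]
        assert np.mean(r2s) == pytest.approx(p / (n - 1), abs=0.01)

    def test_collinear_warns(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        X = np.column_stack([x, x])
        with pytest.warns(UserWarning, match="collinear"):
            refit_variance_explained(x + rng.normal(0, 0.1, 30), X)


class TestLMG:
    def test_single_regressor_share_is_r2(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        y = x + rng.normal(0, 1, 40)
        share = lmg_importance(y, x[:, None])
        assert share.iloc[0] == pytest.approx(refit_variance_explained(y, x[:, None]), abs=1e-10)

    def test_shares_sum_to_r2(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 6))
        y = X @ rng.normal(size=6) + rng.normal(0, 1, 50)
        shares = lmg_importance(y, X)
        assert abs(shares.sum() - refit_variance_explained(y, X)) < 1e-8
        assert (shares >= -1e-12).all()

    def test_orthogonal_regressors_get_marginal_r2(self):
        rng = np.random.default_rng(2)
        n = 64
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)        # exactly orthogonal
        y = 2 * x1 + 0.5 * x2 + rng.normal(0, 1, n)
        X = np.column_stack([x1, x2])
        shares = lmg_importance(y, X)
        for i in range(2):
            marginal = refit_variance_explained(y, X[:, [i]])
            assert shares.iloc[i] == pytest.approx(marginal, abs=1e-10)

    def test_duplicated_regressor_splits_equally(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=60)
        y = x + rng.normal(0, 0.1, 60)
        X = np.column_stack([x, x])
        shares = lmg_importance(y, X)
        assert shares.iloc[0] == pytest.approx(shares.iloc[1], abs=1e-10)
        assert shares.sum() == pytest.approx(refit_variance_explained(y, X[:, [0]]), abs=1e-8)

    def test_order_permutation_permutes_shares(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 4))
        y = X @ np.array([1.0, 0.5, 0.2, 0.0]) + rng.normal(0, 1, 40)
        shares = lmg_importance(y, X)
        perm = [2, 0, 3, 1]
        shares_p = lmg_importance(y, X[:, perm])
        assert np.allclose(shares.to_numpy()[perm], shares_p.to_numpy(), atol=1e-10)

    def test_monte_carlo_close_to_exact(self):
        rng = np.random.default_rng(5)
        p = 7
        X = rng.normal(size=(80, p))
        y = X @ rng.normal(size=p) + rng.normal(0, 1, 80)
        exact = lmg_importance(y, X, max_exact=15)
        mc = lmg_importance(y, X, max_exact=0, n_orderings=5000, seed=0)
        # 3 Monte-Carlo SEs of a share increment bounded by ~R2/sqrt(n_orderings)
        tol = 3 * 1.0 / np.sqrt(5000)
        assert np.abs(exact.to_numpy() - mc.to_numpy()).max() < tol


class TestPermutationGOF:
    fast = dict(alpha_grid=(0.0, 1.0), n_lambda=8, cv=5, repeats=1)

    def test_strong_signal_small_p(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 5))
        y = X[:, 0] * 2 + rng.normal(0, 0.5, 60)
        out = permutation_gof(y, X, n_perm=99, seed=1, **self.fast)
        assert out["p"] <= 0.01

    def test_add_one_smoothing_lower_bound(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 3))
        y = X[:, 0] + rng.normal(0, 0.1, 30)
        out = permutation_gof(y, X, n_perm=10, seed=2, **self.fast)
        assert out["p"] >= 1 / 11 - 1e-12

    def test_null_p_not_extreme(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 4))
        y = rng.normal(size=40)
        out = permutation_gof(y, X, n_perm=39, seed=3, **self.fast)
        assert 0.025 <= out["p"] <= 1.0


class TestDiagnosisPartialR2:
    def test_indicator_response_unadjusted_one(self):
        d = np.array(["RA"] * 10 + ["HC"] * 10)
        y = (d == "RA").astype(float)
        X = np.random.default_rng(0).normal(size=(20, 2))
        out = diagnosis_partial_r2(y, d, X)
        assert out["r2_unadjusted"] == pytest.approx(1.0)

    def test_cell_driven_response_adjusts_to_zero(self):
        rng = np.random.default_rng(1)
        d = np.array(["RA"] * 40 + ["HC"] * 40)
        cells = rng.normal(size=(80, 3)) + 1.2 * (d == "RA")[:, None]
        y = cells @ np.array([1.0, 0.5, -0.5]) + rng.normal(0, 0.05, 80)
        out = diagnosis_partial_r2(y, d, cells)
        assert out["r2_adjusted"] < 0.06
        assert out["r2_unadjusted"] > 0.1
        # exactly cell-driven response: degenerate residuals handled
        exact = diagnosis_partial_r2(cells @ np.array([1.0, 0.5, -0.5]), d, cells)
        assert exact["r2_adjusted"] == 0.0

    def test_single_group_raises(self):
        with pytest.raises(ValueError):
            diagnosis_partial_r2(np.zeros(10), np.array(["RA"] * 10), np.zeros((10, 1)))


class TestSharedEffect:
    def _scores(self, delta, seed=0, n_cells=8, n_subj=30):
        rng = np.random.default_rng(seed)
        diag = np.array(["RA"] * (n_subj // 2) + ["HC"] * (n_subj - n_subj // 2))
        cell_off = rng.normal(0, 0.5, n_cells)
        rows = []
        for c in range(n_cells):
            for s in range(n_subj):
                val = cell_off[c] + delta * (diag[s] == "RA") + rng.normal(0, 1)
                rows.append((val, diag[s], f"cell{c}"))
        arr = np.array(rows, dtype=object)
        return (np.array([r[0] for r in rows], dtype=float),
                np.array([r[1] for r in rows]),
                np.array([r[2] for r in rows]))

    def test_planted_shared_shift_detected(self):
        hits = 0
        for seed in range(10):
            y, d, c = self._scores(delta=1.0, seed=seed)
            hits += shared_effect_test(y, d, c)["p"] < 0.05
        assert hits >= 9

    def test_null_calibrated(self):
        from scipy.stats import kstest
        ps = [shared_effect_test(*self._scores(0.0, seed=s))["p"] for s in range(100)]
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_single_cell_type_raises(self):
        y = np.random.default_rng(0).normal(size=20)
        d = np.array(["RA"] * 10 + ["HC"] * 10)
        with pytest.raises(ValueError):
            shared_effect_test(y, d, np.array(["cell0"] * 20))
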