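"""PLS1 core, component selection, kappa, splits, and the ensemble contract."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.cross_decomposition import PLSRegression

from momira.ensemble import (call_molecular_remission, cohen_kappa,
                             fit_ensemble, member_probabilities,
                             permutation_null, predict_probability,
                             repeated_split, select_ncomp, to_log_odds)
from momira.plsr import fit_plsr


class TestPLS1:
    def test_scores_orthogonal(self):
        rng = np.random.default_rng(0)
        X, y = rng.normal(size=(25, 12)), rng.normal(size=25)
        fit = fit_plsr(X, y, 5)
        G = fit.scores.T @ fit.scores
        off = G - np.diag(np.diag(G))
        norms = np.sqrt(np.diag(G))
        assert np.abs(off).max() < 1e-8 * norms.max() ** 2

    def test_matches_sklearn_predictions(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            X, y = rng.normal(size=(20, 8)), rng.normal(size=20)
            fit = fit_plsr(X, y, 3)
            sk = PLSRegression(n_components=3).fit(X, y)
            assert np.allclose(fit.predict(X), sk.predict(X).ravel(), atol=1e-10)

    def test_full_rank_equals_ols(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            X, y = rng.normal(size=(10, 4)), rng.normal(size=10)
            fit = fit_plsr(X, y, 4)
            D = np.column_stack([np.ones(10), X])
            beta = np.linalg.lstsq(D, y, rcond=None)[0]
            assert np.allclose(fit.predict(X), D @ beta, atol=1e-8)

    def test_exact_fit_single_informative_column(self):
        rng = np.random.default_rng(3)
        X = np.column_stack([np.linspace(0, 1, 12), np.zeros(12) + rng.normal(0, 1e-12, 12)])
        y = 3.0 * X[:, 0] - 1.0
        fit = fit_plsr(X[:, :1], y, 1)
        assert np.abs(fit.predict(X[:, :1]) - y).max() < 1e-8

    def test_feature_permutation_symmetry(self):
        rng = np.random.default_rng(4)
        X, y = rng.normal(size=(15, 6)), rng.normal(size=15)
        perm = rng.permutation(6)
        a = fit_plsr(X, y, 3)
        b = fit_plsr(X[:, perm], y, 3)
        assert np.allclose(a.loadings[perm], b.loadings, atol=1e-10)
        assert np.allclose(a.predict(X), b.predict(X[:, perm]), atol=1e-10)

    def test_rank_exceeded_raises(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(6, 3))
        with pytest.raises(ValueError, match="rank"):
            fit_plsr(X, rng.normal(size=6), 5)

    def test_constant_outcome_raises(self):
        with pytest.raises(ValueError, match="constant"):
            fit_plsr(np.eye(4), np.ones(4), 1)

    def test_affine_feature_rescaling_invariant(self):
        rng = np.random.default_rng(6)
        X, y = rng.normal(size=(18, 5)), rng.normal(size=18)
        X2 = X * np.array([10, 0.1, 3, 1, 7.0]) + np.array([5, -2, 0, 100, 1.0])
        a, b = fit_plsr(X, y, 3), fit_plsr(X2, y, 3)
        assert np.allclose(a.predict(X), b.predict(X2), atol=1e-8)


class TestKappa:
    def test_perfect_agreement(self):
        assert cohen_kappa([0, 1, 0, 1], [0, 1, 0, 1]) == 1.0

    def test_hand_computed_value(self):
        # 4 TP, 4 TN, 1 FP, 1 FN with balanced marginals: p_o=0.8, p_e=0.5
        pred = [1] * 4 + [0] * 4 + [1, 0]
        true = [1] * 4 + [0] * 4 + [0, 1]
        assert math.isclose(cohen_kappa(pred, true), 0.6)

    def test_independent_labels_near_zero(self):
        rng = np.random.default_rng(0)
        pred = rng.integers(0, 2, 20000)
        true = rng.integers(0, 2, 20000)
        assert abs(cohen_kappa(pred, true)) < 0.03

    def test_degenerate_marginals_return_zero(self):
        assert cohen_kappa([1, 1, 1], [1, 1, 1]) == 0.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            cohen_kappa([], [])


class TestRepeatedSplit:
    def test_counts_and_coverage(self):
        ids = [f"s{i}" for i in range(80)]
        labels = np.array([1] * 45 + [0] * 35)
        splits = repeated_split(ids, labels, k=5, repeats=3, seed=0)
        assert len(splits) == 15
        test_counts = pd.Series(0, index=ids)
        for sp in splits:
            assert len(sp["train"]) + len(sp["test"]) == 80
            assert 14 <= len(sp["test"]) <= 18
            test_counts[sp["test"]] += 1
        assert (test_counts == 3).all()

    def test_single_repeat_gives_k_splits(self):
        splits = repeated_split(list("abcdefghij"), [0, 1] * 5, k=5, repeats=1, seed=1)
        assert len(splits) == 5

    def test_reproducible(self):
        ids = [f"s{i}" for i in range(30)]
        labels = [0, 1] * 15
        a = repeated_split(ids, labels, seed=7)
        b = repeated_split(ids, labels, seed=7)
        assert a == b

    def test_small_class_raises(self):
        with pytest.raises(ValueError):
            repeated_split(list("abcdef"), [0, 0, 0, 0, 1, 1], k=5)


class TestSelectNcomp:
    def test_singleton_grid(self):
        rng = np.random.default_rng(0)
        assert select_ncomp(rng.normal(size=(20, 5)), rng.integers(0, 2, 20), grid=[3]) == 3

    def test_tie_goes_to_smallest(self):
        # rank-1 X: every component count yields identical predictions,
        # so all kappas tie and the smallest grid value wins
        X = np.outer(np.arange(24, dtype=float), [1.0, 2.0, 3.0, 4.0])
        y = np.array([0, 1] * 12)
        assert select_ncomp(X, y, grid=[1, 2, 3], seed=0) == 1

    def test_single_latent_factor_selects_small(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n, m = 60, 40
            y = np.array([0, 1] * (n // 2))
            factor = y * 3.0 + rng.normal(0, 0.5, n)
            X = np.outer(factor, rng.normal(size=m) / np.sqrt(m)) + rng.normal(0, 1, (n, m))
            hits += select_ncomp(X, y.astype(float), seed=seed) <= 2
        assert hits >= 18


class TestEnsemble:
    def test_probability_mean_of_members(self, small_cohort):
        _, layers, meta, _ = small_cohort
        model = fit_ensemble(layers["transcript"], meta, seed=0)
        assert len(model.members) == 15
        probs = member_probabilities(model, layers["transcript"].values)
        ens = predict_probability(model, layers["transcript"].values)
        assert np.allclose(ens.to_numpy(), probs.mean(axis=0))
        assert (ens >= 0).all() and (ens <= 1).all()

    def test_each_sample_tests_three_times(self, small_cohort):
        _, layers, meta, _ = small_cohort
        model = fit_ensemble(layers["transcript"], meta, seed=0)
        counts = {}
        for m in model.members:
            for s in m.test_ids:
                counts[s] = counts.get(s, 0) + 1
        assert set(counts.values()) == {3}

    def test_heldout_accuracy_beats_null(self, small_cohort):
        _, layers, meta, _ = small_cohort
        model = fit_ensemble(layers["transcript"], meta, seed=0)
        null = permutation_null(layers["transcript"], meta, n_perm=3, seed=0)
        assert model.heldout_accuracy >= null["mean"] + 0.3

    def test_missing_features_raise(self, small_cohort):
        _, layers, meta, _ = small_cohort
        model = fit_ensemble(layers["transcript"], meta, seed=0)
        with pytest.raises(ValueError, match="missing"):
            predict_probability(model, layers["transcript"].values.iloc[:10])

    def test_training_sample_bias_absent(self, small_cohort):
        """Disease probability of in-training cases is not inflated against
        held-out cases (each member scores its own test fold)."""
        _, layers, meta, _ = small_cohort
        model = fit_ensemble(layers["transcript"], meta, seed=1)
        X = layers["transcript"].values
        meta_i = meta.set_index("sample_id")
        in_train, heldout = [], []
        for m in model.members:
            p = np.clip(m.fit.predict(X[m.train_ids].T.to_numpy()), 0, 1)
            in_train.extend(p[(meta_i.loc[m.train_ids, "diagnosis"] == "RA").to_numpy()])
            p = np.clip(m.fit.predict(X[m.test_ids].T.to_numpy()), 0, 1)
            heldout.extend(p[(meta_i.loc[m.test_ids, "diagnosis"] == "RA").to_numpy()])
        assert abs(np.mean(in_train) - np.mean(heldout)) < 0.1


class TestProbabilityTransforms:
    @pytest.mark.parametrize("p,expected", [
        (0.5, 0.0),
        (0.9, math.log(9)),
        (1.0, math.log((1 - 1e-6) / 1e-6)),
    ])
    def test_log_odds_values(self, p, expected):
        assert math.isclose(to_log_odds(p), expected, rel_tol=1e-9)

    @given(st.floats(min_value=0.0, max_value=1.0),
           st.floats(min_value=0.0, max_value=1.0))
    @settings(deadline=None, max_examples=50)
    def test_log_odds_monotone(self, a, b):
        lo, hi = sorted([a, b])
        assert to_log_odds(lo) <= to_log_odds(hi)

    @pytest.mark.parametrize("p,expected", [(0.49, True), (0.5, False), (0.51, False)])
    def test_molecular_remission_strict_threshold(self, p, expected):
        assert call_molecular_remission(p) is expected
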