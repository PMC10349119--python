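"""The four linear/geometric classifiers, CV harness and importance scores."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from ramanclass import linear as lin
from ramanclass import synthetic as syn
from ramanclass.dataset import SpectralDataset
from ramanclass.errors import (
    InsufficientDataError,
    InvalidConfigError,
    ShapeError,
    UndefinedAUCError,
)


def _ds(X, y, w=None):
    X = np.asarray(X, dtype=float)
    w = np.arange(X.shape[1], dtype=float) if w is None else w
    return SpectralDataset(w, X, y)


class TestClassMeans:
    def test_mean_of_identical_rows(self):
        ds = _ds([[1, 2], [1, 2], [0, 0]], [1, 1, 0])
        cm = lin.class_means(ds)
        assert np.array_equal(cm.h1, [1, 2])

    def test_midpoint(self):
        ds = _ds([[0, 0], [2, 2], [5, 5]], [1, 1, 0])
        assert np.array_equal(lin.class_means(ds).h1, [1, 1])

    def test_matches_brute_force_columnwise_mean(self, rng):
        X = rng.normal(size=(50, 10))
        y = (np.arange(50) % 2).astype(int)
        cm = lin.class_means(_ds(X, y))
        h1 = np.array([np.mean([X[i, j] for i in range(50) if y[i] == 1]) for j in range(10)])
        assert np.allclose(cm.h1, h1)

    def test_single_class_rejected(self):
        with pytest.raises(InsufficientDataError):
            lin.class_means(_ds([[1.0, 2.0]], [1]))


class TestL2Distance:
    @pytest.mark.parametrize(
        "x,h,expected",
        [([1, 2], [1, 2], 0.0), ([1, 2], [0, 0], 5.0), ([3], [-1], 16.0)],
    )
    def test_examples(self, x, h, expected):
        assert lin.l2_distance_sq(np.array(x, float), np.array(h, float)) == expected

    def test_length_mismatch(self):
        with pytest.raises(ShapeError):
            lin.l2_distance_sq(np.zeros(3), np.zeros(4))


class TestL2DRule:
    def test_tau_zero_always_predicts_one(self, rng):
        model = lin.L2DModel(lin.ClassMeans(rng.normal(size=5), rng.normal(size=5)), tau=0.0)
        assert lin.l2d_classify(rng.normal(size=5), model) == 1

    def test_weighted_comparison(self):
        # x=1 with h1=1+sqrt(5), h2=1+sqrt(3) gives d1=5, d2=3;
        # at tau=0.5, 2.5 <= 1.5 is false -> class 0
        means = lin.ClassMeans(np.array([1 + np.sqrt(5.0)]), np.array([1 + np.sqrt(3.0)]))
        model = lin.L2DModel(means, tau=0.5)
        assert lin.l2d_classify(np.array([1.0]), model) == 0

    def test_point_at_h1_classified_one(self, rng):
        h1 = rng.normal(size=6)
        model = lin.L2DModel(lin.ClassMeans(h1, h1 + 1.0), tau=0.5)
        assert lin.l2d_classify(h1, model) == 1

    def test_tau_half_is_nearest_centroid(self, rng):
        # brute-force agreement on 1000 random instances
        h1, h2 = rng.normal(size=8), rng.normal(size=8)
        model = lin.L2DModel(lin.ClassMeans(h1, h2), tau=0.5)
        X = rng.normal(size=(1000, 8))
        pred = lin.l2d_classify(X, model)
        brute = np.array(
            [1 if ((x - h1) ** 2).sum() <= ((x - h2) ** 2).sum() else 0 for x in X]
        )
        assert np.array_equal(pred, brute)

    def test_fit_selects_tau_near_half_for_symmetric_classes(self, rng):
        mu = rng.normal(size=12)
        delta = rng.normal(size=12)
        X1 = mu + delta + rng.normal(0, 1.0, size=(150, 12))
        X0 = mu - delta + rng.normal(0, 1.0, size=(150, 12))
        ds = _ds(np.vstack([X1, X0]), np.r_[np.ones(150, int), np.zeros(150, int)])
        model = lin.fit_l2d(ds, seed=0)
        assert abs(model.tau - 0.5) <= 0.1

    def test_singleton_grid(self, hw_effect_dataset):
        model = lin.fit_l2d(hw_effect_dataset, tau_grid=np.array([0.3]))
        assert model.tau == 0.3

    def test_empty_grid_rejected(self, hw_effect_dataset):
        with pytest.raises(InvalidConfigError):
            lin.fit_l2d(hw_effect_dataset, tau_grid=np.array([]))


class TestPoolingFeatures:
    def test_global_mean_examples(self):
        assert lin.global_mean_feature(np.full(7, 3.0)) == 3.0
        assert lin.global_mean_feature(np.array([1.0, 2.0, 3.0])) == 2.0

    def test_constant_spectrum_constant_features(self):
        scheme = lin.PoolingScheme((0.0, 2.0, 4.0))
        w = np.arange(4, dtype=float)
        feats = lin.average_pooling(np.full(4, 2.5), scheme, w)
        assert np.allclose(feats, 2.5)

    def test_two_bin_means(self):
        scheme = lin.PoolingScheme((0.0, 2.0, 4.0))
        feats = lin.average_pooling(np.array([1.0, 2.0, 3.0, 4.0]), scheme, np.arange(4.0))
        assert np.allclose(feats, [1.5, 3.5])

    def test_single_bin_reduces_to_global_mean(self, rng):
        x = rng.normal(size=30)
        w = np.linspace(0, 10, 30)
        scheme = lin.PoolingScheme((0.0, 10.0))
        assert lin.average_pooling(x, scheme, w)[0] == pytest.approx(lin.global_mean_feature(x))

    def test_empty_bin_rejected(self):
        scheme = lin.PoolingScheme((0.0, 1.0, 1.5, 4.0))
        with pytest.raises(InvalidConfigError):
            lin.average_pooling(np.zeros(4), scheme, np.array([0.0, 2.0, 3.0, 4.0]))

    def test_default_schemes_have_paper_feature_counts(self):
        assert lin.default_pooling_scheme("LW").n_features == 4
        assert lin.default_pooling_scheme("HW").n_features == 3


class TestLogistic:
    def test_zero_coefficients_give_half(self):
        model = lin.LogisticModel(beta0=0.0, betas=[0.0, 0.0])
        assert np.allclose(model.predict_proba([[3.0, -1.0]]), 0.5)

    def test_intercept_ln3_gives_three_quarters(self):
        model = lin.LogisticModel(beta0=np.log(3.0), betas=[0.0])
        assert model.predict_proba([[42.0]])[0] == pytest.approx(0.75)

    def test_separable_feature_stays_finite(self):
        X = np.r_[np.zeros(20), np.ones(20)][:, None]
        y = np.r_[np.zeros(20, int), np.ones(20, int)]
        model = lin.fit_logistic(X, y, shrinkage=1.0)
        assert np.isfinite(model.betas).all() and np.isfinite(model.beta0)

    def test_recovers_direction(self, rng):
        z = rng.normal(size=200)
        y = (z + 0.3 * rng.normal(size=200) > 0).astype(int)
        model = lin.fit_logistic(z[:, None], y)
        assert model.betas[0] > 0

    def test_threshold_examples(self):
        probs = np.array([0.3, 0.7])
        assert np.array_equal(lin.classify_threshold(probs, 0.0), [1, 1])
        assert np.array_equal(lin.classify_threshold(probs, 1.0), [0, 0])
        assert np.array_equal(lin.classify_threshold(probs, 0.5), [0, 1])
        with pytest.raises(InvalidConfigError):
            lin.classify_threshold(probs, 1.5)


class TestPCA:
    def test_collinear_points(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        model = lin.fit_pca(X, m_policy=2)
        assert np.allclose(np.abs(model.loadings[:, 0]), 1 / np.sqrt(2))
        assert model.loadings[np.abs(model.loadings[:, 0]).argmax(), 0] > 0
        assert model.proportions[0] == pytest.approx(1.0)

    def test_variance_trace_conserved(self, rng):
        X = rng.normal(size=(30, 8))
        model = lin.fit_pca(X, m_policy=8)
        assert model.variances.sum() == pytest.approx(X.var(axis=0, ddof=1).sum())
        assert model.proportions.sum() == pytest.approx(1.0)
        assert np.all(np.diff(model.cumulative_proportions) >= -1e-12)

    def test_matches_dense_eigendecomposition_oracle(self, rng):
        X = rng.normal(size=(20, 6))
        model = lin.fit_pca(X, m_policy=6)
        Y = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(Y.T @ Y / (X.shape[0] - 1))
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        assert np.allclose(model.variances, evals, atol=1e-8)
        for i in range(6):
            dot = abs(np.dot(model.loadings[:, i], evecs[:, i]))
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_projection_of_column_means_is_zero(self, rng):
        X = rng.normal(size=(15, 5))
        model = lin.fit_pca(X, m_policy=3)
        z = lin.project(model.column_means[None, :], model)
        assert np.allclose(z, 0.0, atol=1e-10)

    def test_full_reconstruction(self, rng):
        X = rng.normal(size=(12, 5))
        model = lin.fit_pca(X, m_policy=5)
        z = lin.project(X, model)
        back = z @ model.loadings.T + model.column_means
        assert np.allclose(back, X, atol=1e-8)

    def test_default_policy_caps_at_five(self, hw_effect_dataset):
        model = lin.fit_pca(hw_effect_dataset)
        assert 1 <= model.m <= 5


class TestROCAUC:
    def test_three_of_four_pairs(self):
        scores = np.array([0.9, 0.8, 0.7, 0.85])
        labels = np.array([1, 1, 0, 0])
        assert lin.roc_auc(scores, labels) == 0.75

    def test_perfect_separation(self):
        assert lin.roc_auc(np.array([1.0, 2.0, 3.0, 4.0]), np.array([0, 0, 1, 1])) == 1.0

    def test_all_ties_give_half(self):
        assert lin.roc_auc(np.full(6, 2.0), np.array([0, 1, 0, 1, 0, 1])) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedAUCError):
            lin.roc_auc(np.array([1.0, 2.0]), np.array([1, 1]))

    @given(
        pos=st.lists(st.integers(-20, 20), min_size=1, max_size=25),
        neg=st.lists(st.integers(-20, 20), min_size=1, max_size=25),
    )
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_matches_brute_force_pair_count(self, pos, neg):
        scores = np.array(pos + neg, dtype=float)
        labels = np.array([1] * len(pos) + [0] * len(neg))
        wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
        assert lin.roc_auc(scores, labels) == pytest.approx(wins / (len(pos) * len(neg)))

    def test_agrees_with_sklearn(self, rng):
        scores = rng.normal(size=200)
        labels = rng.integers(0, 2, size=200)
        if labels.sum() in (0, 200):
            labels[0] = 1 - labels[0]
        assert lin.roc_auc(scores, labels) == pytest.approx(roc_auc_score(labels, scores))

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=100)
        labels = rng.integers(0, 2, size=100)
        labels[:2] = [0, 1]
        base = lin.roc_auc(scores, labels)
        assert lin.roc_auc(np.exp(scores), labels) == pytest.approx(base)
        assert lin.roc_auc(3 * scores - 7, labels) == pytest.approx(base)


class TestCrossValidate:
    def test_fold_count_and_range(self, hw_effect_dataset):
        from ramanclass.dataset import select_region

        sub = select_region(hw_effect_dataset, "HW")
        res = lin.cross_validate(lin.LRAClassifier, sub, k=10, seed=0)
        assert res.fold_aucs.shape == (10,)
        assert np.all((res.fold_aucs >= 0) & (res.fold_aucs <= 1))
        assert res.mean_auc == pytest.approx(res.fold_aucs.mean())

    def test_seeded_determinism(self, hw_effect_dataset):
        a = lin.cross_validate(lin.LRAClassifier, hw_effect_dataset, k=5, seed=3)
        b = lin.cross_validate(lin.LRAClassifier, hw_effect_dataset, k=5, seed=3)
        assert np.array_equal(a.fold_aucs, b.fold_aucs)

    def test_too_many_folds_rejected(self, hw_effect_dataset):
        with pytest.raises(InvalidConfigError):
            lin.cross_validate(lin.LRAClassifier, hw_effect_dataset, k=10**6)


class TestPermutationImportance:
    def test_ignored_feature_scores_zero(self, rng):
        model = lin.LogisticModel(beta0=0.0, betas=[2.0, 0.0])
        X = rng.normal(size=(100, 2))
        y = (X[:, 0] > 0).astype(int)
        imp = lin.permutation_importance(model.predict_proba, X, y, n_perm=5, seed=0)
        assert imp.scores[1] == 0.0
        assert imp.scores[0] > 0.0

    def test_informative_vs_noise_feature(self, rng):
        y = rng.integers(0, 2, size=300)
        X = np.c_[3.0 * y + rng.normal(size=300), rng.normal(size=300)]
        model = lin.fit_logistic(X, y)
        imp = lin.permutation_importance(model.predict_proba, X, y, n_perm=30, seed=1)
        assert imp.scores[0] > 0.2
        assert abs(imp.scores[1]) < 0.05

    def test_reproducible_with_seed(self, rng):
        model = lin.LogisticModel(beta0=0.0, betas=[1.0, -1.0])
        X = rng.normal(size=(60, 2))
        y = rng.integers(0, 2, size=60)
        y[:2] = [0, 1]
        a = lin.permutation_importance(model.predict_proba, X, y, n_perm=1, seed=9)
        b = lin.permutation_importance(model.predict_proba, X, y, n_perm=1, seed=9)
        assert np.array_equal(a.scores, b.scores)
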