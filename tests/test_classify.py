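import numpy as np
import pytest

from finpigment.classify import (
    ClassifyError,
    discriminant_axes,
    discriminant_scores,
    fit,
    loocv,
    predict,
    shrink_covariance,
)


def _toy_clusters(rng, n_classes=3, per_class=10, p=2, sep=8.0, noise=0.5):
    X, y = [], []
    for k in range(n_classes):
        centre = rng.normal(0, 1, p) * 0 + sep * np.eye(1, p, 0)[0] * 0
        centre = np.zeros(p)
        centre[k % p] = sep * (1 + k // p)
        X.append(centre + rng.normal(0, noise, (per_class, p)))
        y += [f"C{k}"] * per_class
    return np.vstack(X), np.array(y)


class TestShrinkCovariance:
    def test_full_shrinkage_diagonal(self, rng):
        X = rng.normal(size=(20, 5))
        X -= X.mean(axis=0)
        sigma, lam = shrink_covariance(X, shrinkage=1.0)
        assert lam == 1.0
        off = sigma[~np.eye(5, dtype=bool)]
        np.testing.assert_allclose(off, 0.0, atol=1e-12)
        np.testing.assert_allclose(np.diag(sigma), (X**2).sum(axis=0) / (len(X) - 1))

    def test_zero_shrinkage_empirical(self, rng):
        X = rng.normal(size=(20, 5))
        X -= X.mean(axis=0)
        sigma, lam = shrink_covariance(X, shrinkage=0.0)
        np.testing.assert_allclose(sigma, X.T @ X / (len(X) - 1), atol=1e-12)

    def test_lambda_small_for_large_n(self, rng):
        # n >> p from a known covariance: estimated intensity is small and
        # the shrunk estimate lands near the truth
        A = rng.normal(size=(5, 5))
        true_cov = A @ A.T + np.eye(5)
        L = np.linalg.cholesky(true_cov)
        X = rng.normal(size=(1000, 5)) @ L.T
        X -= X.mean(axis=0)
        sigma, lam = shrink_covariance(X)
        assert 0 <= lam < 0.1
        rel = np.linalg.norm(sigma - true_cov) / np.linalg.norm(true_cov)
        assert rel < 0.10

    def test_lambda_in_unit_interval_high_dim(self, rng):
        X = rng.normal(size=(10, 50))
        X -= X.mean(axis=0)
        sigma, lam = shrink_covariance(X)
        assert 0.0 <= lam <= 1.0
        # shrunk matrix must be positive definite even though n < p
        np.linalg.cholesky(sigma)

    def test_zero_variance_floored(self, rng):
        X = rng.normal(size=(15, 4))
        X[:, 2] = 3.14  # constant
        X -= X.mean(axis=0)
        with pytest.warns(UserWarning, match="floored"):
            sigma, _ = shrink_covariance(X)
        assert sigma[2, 2] > 0

    def test_single_row_rejected(self):
        with pytest.raises(ClassifyError):
            shrink_covariance(np.ones((1, 3)))


class TestFit:
    def test_two_identical_point_classes_midpoint_boundary(self):
        X = np.array([[0.0, 0.0]] * 5 + [[4.0, 0.0]] * 5)
        y = np.array(["A"] * 5 + ["B"] * 5)
        model = fit(X, y, shrinkage=1.0)
        # the discriminant boundary is the midpoint hyperplane x = 2
        for x0, winner in [(1.9, "A"), (2.1, "B")]:
            assert predict(model, np.array([x0, 0.0])).ranking[0] == winner
        scores = discriminant_scores(model, np.array([2.0, 0.0]))[0]
        assert scores[0] == pytest.approx(scores[1])

    def test_row_order_invariance(self, rng):
        X, y = _toy_clusters(rng)
        model_a = fit(X, y)
        perm = rng.permutation(len(y))
        model_b = fit(X[perm], y[perm])
        np.testing.assert_allclose(model_a.class_means, model_b.class_means, atol=1e-12)
        np.testing.assert_allclose(
            model_a.pooled_covariance_shrunk, model_b.pooled_covariance_shrunk, atol=1e-12
        )
        assert model_a.shrinkage_intensity == pytest.approx(model_b.shrinkage_intensity)

    def test_scores_match_direct_formula_three_class_toy(self, rng):
        X, y = _toy_clusters(rng, n_classes=3, per_class=8, p=2)
        model = fit(X, y)
        x = rng.normal(size=2)
        scores = discriminant_scores(model, x)[0]
        sigma_inv = np.linalg.inv(model.pooled_covariance_shrunk)
        for k, mu in enumerate(model.class_means):
            expected = x @ sigma_inv @ mu - 0.5 * mu @ sigma_inv @ mu + np.log(model.priors[k])
            assert scores[k] == pytest.approx(expected, rel=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(ClassifyError):
            fit(np.zeros((4, 2)), np.array(["A"] * 4))

    def test_missing_features_imputed_with_training_means(self, rng):
        X, y = _toy_clusters(rng)
        X[0, 1] = np.nan
        model = fit(X, y)
        assert np.isfinite(model.imputation_means).all()
        assert np.isfinite(model.class_means).all()

    def test_empirical_priors(self, rng):
        X = np.vstack([rng.normal(0, 1, (6, 2)), rng.normal(5, 1, (2, 2))])
        y = np.array(["A"] * 6 + ["B"] * 2)
        model = fit(X, y, priors="empirical")
        np.testing.assert_allclose(model.priors, [0.75, 0.25])


class TestPredict:
    def test_class_mean_ranked_first(self, rng):
        X, y = _toy_clusters(rng, sep=10.0)
        model = fit(X, y)
        for k, cid in enumerate(model.class_ids):
            pred = predict(model, model.class_means[k])
            assert pred.ranking[0] == cid

    def test_posteriors_sum_to_one(self, rng):
        X, y = _toy_clusters(rng)
        model = fit(X, y)
        pred = predict(model, rng.normal(size=2))
        assert pred.posteriors.sum() == pytest.approx(1.0, abs=1e-9)

    def test_two_class_one_feature_closed_form(self):
        # equal-variance 1-D LDA posterior is the logistic of the
        # standardised distance to the midpoint
        rng = np.random.default_rng(3)
        a = rng.normal(0.0, 1.0, 50)
        b = rng.normal(4.0, 1.0, 50)
        X = np.concatenate([a, b])[:, None]
        y = np.array(["A"] * 50 + ["B"] * 50)
        model = fit(X, y, shrinkage=0.0)
        mu_a, mu_b = model.class_means[:, 0]
        s2 = model.pooled_covariance_shrunk[0, 0]
        for x0 in [-1.0, 1.7, 2.0, 3.5]:
            pred = predict(model, np.array([x0]))
            expected = 1.0 / (1.0 + np.exp(-(mu_b - mu_a) / s2 * (x0 - (mu_a + mu_b) / 2)))
            assert pred.posteriors[1] == pytest.approx(expected, abs=1e-9)

    def test_deterministic_tie_break(self):
        X = np.array([[0.0], [0.0], [2.0], [2.0]])
        y = np.array(["B", "B", "A", "A"])
        model = fit(X, y, shrinkage=1.0)
        pred = predict(model, np.array([1.0]))  # exact midpoint: tie
        assert pred.ranking == ("A", "B")  # ties broken by class ID order


class TestLOOCV:
    def test_separable_classes_perfect(self, rng):
        X, y = _toy_clusters(rng, sep=50.0, noise=0.1)
        report = loocv(X, y)
        assert report.top1_accuracy == 1.0

    def test_topk_with_all_classes_is_one(self, rng):
        X, y = _toy_clusters(rng, n_classes=3, sep=0.0, noise=1.0)  # no signal
        report = loocv(X, y, k_list=(1, 3))
        ranks = report.ranks["rank"]
        assert (ranks <= 3).mean() == 1.0

    def test_uniform_lift_is_accuracy_times_k(self, rng):
        X, y = _toy_clusters(rng, n_classes=4, per_class=6, p=3, sep=3.0)
        report = loocv(X, y)
        assert report.lift_uniform == pytest.approx(report.top1_accuracy * 4)

    def test_empirical_lift_definition(self, rng):
        X = np.vstack([rng.normal(0, 1, (8, 2)), rng.normal(6, 1, (4, 2))])
        y = np.array(["A"] * 8 + ["B"] * 4)
        report = loocv(X, y, baseline_kind="empirical")
        p = np.array([8 / 12, 4 / 12])
        assert report.lift_empirical == pytest.approx(report.top1_accuracy / (p**2).sum())
        assert report.lift == report.lift_empirical

    def test_monotone_in_k(self, rng):
        X, y = _toy_clusters(rng, n_classes=5, per_class=4, sep=1.5, noise=1.0)
        report = loocv(X, y)
        assert report.top5_accuracy >= report.top1_accuracy

    def test_confusion_row_sums(self, rng):
        X, y = _toy_clusters(rng, n_classes=3, per_class=7)
        report = loocv(X, y)
        counts = report.confusion.sum(axis=1)
        for cid in report.confusion.index:
            assert counts[cid] == (y == cid).sum()

    def test_no_leakage_from_held_out_row(self, rng):
        # perturbing the held-out row must not change its fold's model
        X, y = _toy_clusters(rng, n_classes=3, per_class=4)
        i = 5
        mask = np.ones(len(y), bool)
        mask[i] = False
        model_a = fit(X[mask], y[mask])
        X2 = X.copy()
        X2[i] += 1e6
        model_b = fit(X2[mask], y[mask])
        np.testing.assert_array_equal(model_a.class_means, model_b.class_means)
        np.testing.assert_array_equal(
            model_a.pooled_covariance_shrunk, model_b.pooled_covariance_shrunk
        )
        np.testing.assert_array_equal(model_a.imputation_means, model_b.imputation_means)
        assert model_a.shrinkage_intensity == model_b.shrinkage_intensity

    def test_singletons_excluded_but_candidates(self, rng):
        X = np.vstack([_toy_clusters(rng, n_classes=2, per_class=5)[0], [[50.0, 50.0]]])
        y = np.array(["A"] * 5 + ["B"] * 5 + ["Z"])
        with pytest.warns(UserWarning, match="singleton"):
            report = loocv(X, y)
        assert report.n_tested == 10
        assert "Z" in report.confusion.columns


class TestDiscriminantAxes:
    def test_two_classes_one_axis(self, rng):
        X, y = _toy_clusters(rng, n_classes=2)
        model = fit(X, y)
        axes = discriminant_axes(model, n_axes=2)
        assert axes.shape == (2, 2)
        np.testing.assert_array_equal(axes[:, 1], 0.0)

    def test_axes_separate_classes(self, rng):
        X, y = _toy_clusters(rng, n_classes=3, sep=10.0, noise=0.3)
        model = fit(X, y)
        axes = discriminant_axes(model, n_axes=2)
        proj = X @ axes[:, 0]
        within = np.mean([proj[y == c].std() for c in np.unique(y)])
        between = proj.std()
        assert between > 3 * within
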