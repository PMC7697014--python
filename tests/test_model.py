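import numpy as np
import pytest
from scipy.stats import multivariate_normal
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis

from lungsound_dx.audio_io import FeatureTable
from lungsound_dx.model import (
    ConfusionMatrix,
    compute_metrics,
    confusion_from_predictions,
    cross_validate,
    holdout_validate,
    predict_batch,
    qda_fit,
    qda_predict,
)


def table_from(x, labels, names=None):
    names = names or [f"f{i}" for i in range(np.atleast_2d(x).shape[1])]
    return FeatureTable(np.atleast_2d(np.asarray(x, float)), np.asarray(labels, dtype=object), names)


def gaussian_fixture(rng, n_classes=3, dim=3, n=100, spread=3.0):
    means = rng.normal(0, spread, (n_classes, dim))
    covs = []
    for _ in range(n_classes):
        a = rng.normal(0, 1, (dim, dim))
        covs.append(a @ a.T + dim * np.eye(dim))
    x, y = [], []
    for k in range(n_classes):
        x.append(rng.multivariate_normal(means[k], covs[k], n))
        y += [f"c{k}"] * n
    return np.vstack(x), np.array(y, dtype=object), means, covs


class TestFit:
    def test_hand_computed_one_dimensional_fit(self):
        table = table_from([[0.0], [2.0], [10.0], [14.0]], ["COPD", "COPD", "healthy", "healthy"])
        model = qda_fit(table, reg=0.0)
        np.testing.assert_allclose(model.means.ravel(), [1.0, 12.0])
        np.testing.assert_allclose(model.covariances.ravel(), [2.0, 8.0])  # n-1 denominator
        np.testing.assert_allclose(model.priors, [0.5, 0.5])

    def test_identical_classes_get_identical_parameters(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(20, 2))
        table = table_from(np.vstack([x, x]), ["COPD"] * 20 + ["healthy"] * 20)
        model = qda_fit(table)
        np.testing.assert_allclose(model.means[0], model.means[1])
        np.testing.assert_allclose(model.covariances[0], model.covariances[1])

    def test_duplicate_feature_needs_ridge(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(15, 1))
        x = np.hstack([a, a])  # singular within-class covariance
        table = table_from(np.vstack([x, x + 5]), ["COPD"] * 15 + ["healthy"] * 15)
        model = qda_fit(table, reg=1e-6)
        for cov in model.covariances:
            assert np.all(np.linalg.eigvalsh(cov) > 0)

    def test_tiny_class_rejected(self):
        table = table_from([[0.0], [1.0], [2.0]], ["COPD", "COPD", "healthy"])
        with pytest.raises(ValueError):
            qda_fit(table)

    def test_parameter_recovery_from_large_sample(self):
        rng = np.random.default_rng(2)
        mean_a, mean_b = np.array([1.0, -2.0]), np.array([4.0, 3.0])
        cov_a = np.array([[2.0, 0.5], [0.5, 1.0]])
        cov_b = np.array([[1.0, -0.3], [-0.3, 2.0]])
        xa = rng.multivariate_normal(mean_a, cov_a, 10_000)
        xb = rng.multivariate_normal(mean_b, cov_b, 10_000)
        table = table_from(np.vstack([xa, xb]), ["COPD"] * 10_000 + ["healthy"] * 10_000)
        model = qda_fit(table, reg=0.0)
        assert np.linalg.norm(model.means[0] - mean_a) / np.linalg.norm(mean_a) < 0.02
        assert np.linalg.norm(model.covariances[0] - cov_a) / np.linalg.norm(cov_a) < 0.05
        assert np.linalg.norm(model.covariances[1] - cov_b) / np.linalg.norm(cov_b) < 0.05


class TestPredict:
    def test_equal_spherical_covariances_reduce_to_nearest_mean(self):
        rng = np.random.default_rng(3)
        a = rng.normal([0, 0], 1.0, (200, 2))
        b = rng.normal([6, 6], 1.0, (200, 2))
        table = table_from(np.vstack([a, b]), ["COPD"] * 200 + ["healthy"] * 200)
        model = qda_fit(table)
        for point, want in (([0.5, 0.2], "COPD"), ([5.5, 6.1], "healthy")):
            cls, _ = qda_predict(model, point)
            assert cls == want

    def test_prior_shifts_decision_toward_high_prior_class(self):
        # 1-D, means -1/+1, equal variances, priors 0.9/0.1:
        # solving delta_a(x) = delta_b(x) gives the boundary at
        # x = var * ln(pi_a/pi_b) / 2 > 0, so x=0 -> high-prior class
        rng = np.random.default_rng(4)
        xa = rng.normal(-1.0, 1.0, 900)
        xb = rng.normal(1.0, 1.0, 100)
        table = table_from(np.r_[xa, xb][:, None], ["COPD"] * 900 + ["healthy"] * 100)
        model = qda_fit(table)
        cls, scores = qda_predict(model, [0.0])
        assert cls == "COPD"
        assert scores[0] > scores[1]

    def test_agrees_with_density_evaluation_oracle(self):
        rng = np.random.default_rng(5)
        x, y, _, _ = gaussian_fixture(rng, n_classes=2, dim=3, n=150)
        table = table_from(x, y)
        model = qda_fit(table, reg=0.0)
        test = rng.normal(0, 3, (200, 3))
        pred = predict_batch(model, test)
        # brute-force Bayes rule from full Gaussian density evaluation
        priors = model.priors
        densities = np.stack(
            [
                priors[k] * multivariate_normal(model.means[k], model.covariances[k]).pdf(test)
                for k in range(2)
            ],
            axis=1,
        )
        oracle = np.array([model.class_names[i] for i in densities.argmax(axis=1)])
        assert np.all(pred == oracle)

    def test_matches_sklearn_qda(self):
        rng = np.random.default_rng(6)
        x, y, _, _ = gaussian_fixture(rng, n_classes=3, dim=4, n=120)
        model = qda_fit(table_from(x, y), reg=0.0)
        sk = QuadraticDiscriminantAnalysis(store_covariance=True).fit(x, y)
        test = rng.normal(0, 3, (300, 4))
        agreement = np.mean(predict_batch(model, test) == sk.predict(test))
        assert agreement > 0.99

    def test_dimension_mismatch_rejected(self):
        table = table_from([[0.0, 1.0], [1.0, 2.0], [5.0, 6.0], [6.0, 7.0]],
                           ["COPD", "COPD", "healthy", "healthy"])
        model = qda_fit(table)
        with pytest.raises(ValueError):
            qda_predict(model, [1.0])


class TestMetrics:
    def test_perfect_diagonal(self):
        cm = ConfusionMatrix(np.diag([10, 20, 30]), ["COPD", "healthy", "pneumonia"])
        report = compute_metrics(cm)
        assert report.accuracy == 1.0
        assert all(v == 1.0 for v in report.tpr.values())
        assert all(v == 0.0 for v in report.fnr.values())

    def test_copd_row_sensitivity(self):
        # 628 of 631 true positives in the first row
        counts = np.array([[628, 2, 1], [0, 100, 0], [0, 0, 100]])
        report = compute_metrics(ConfusionMatrix(counts, ["COPD", "healthy", "pneumonia"]))
        assert report.tpr["COPD"] == pytest.approx(628 / 631)
        assert report.tpr["COPD"] > 0.99

    def test_hand_computed_two_by_two(self):
        report = compute_metrics(ConfusionMatrix([[8, 2], [3, 7]], ["a", "b"]))
        assert report.accuracy == pytest.approx(0.75)
        assert report.tpr["a"] == pytest.approx(0.8)
        assert report.ppv["a"] == pytest.approx(8 / 11)

    def test_identities_on_random_matrices(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            k = rng.integers(2, 5)
            counts = rng.integers(0, 50, (k, k))
            if counts.sum() == 0:
                continue
            names = [f"c{i}" for i in range(k)]
            report = compute_metrics(ConfusionMatrix(counts, names))
            for c in names:
                if report.tpr[c] is not None:
                    assert report.tpr[c] + report.fnr[c] == pytest.approx(1.0, abs=1e-12)
                if report.ppv[c] is not None:
                    assert report.ppv[c] + report.fdr[c] == pytest.approx(1.0, abs=1e-12)
            assert report.accuracy == pytest.approx(np.trace(counts) / counts.sum())

    def test_empty_true_class_reported_missing(self):
        report = compute_metrics(ConfusionMatrix([[5, 0], [0, 0]], ["a", "b"]))
        assert report.tpr["b"] is None
        assert report.fnr["b"] is None


class TestValidation:
    def test_separable_clusters_give_perfect_pooled_accuracy(self):
        rng = np.random.default_rng(8)
        a = rng.normal([0, 0], 0.3, (30, 2))
        b = rng.normal([10, 10], 0.3, (30, 2))
        table = table_from(np.vstack([a, b]), ["COPD"] * 30 + ["healthy"] * 30)
        for folds in (2, 5, 10):
            report, per_fold = cross_validate(table, folds=folds, seed=0)
            assert report.accuracy == 1.0
            assert len(per_fold) == folds

    def test_same_seed_reproduces_metrics(self):
        rng = np.random.default_rng(9)
        x, y, _, _ = gaussian_fixture(rng, n_classes=3, dim=2, n=40, spread=1.5)
        table = table_from(x, y)
        r1, _ = cross_validate(table, folds=5, seed=3)
        r2, _ = cross_validate(table, folds=5, seed=3)
        np.testing.assert_array_equal(r1.confusion.counts, r2.confusion.counts)

    def test_label_permutation_scores_at_chance(self):
        rng = np.random.default_rng(10)
        accs = []
        for seed in range(10):
            x = rng.normal(size=(90, 3))
            y = np.array((["a"] * 30 + ["b"] * 30 + ["c"] * 30), dtype=object)
            rng.shuffle(y)
            report, _ = cross_validate(table_from(x, y), folds=3, seed=seed)
            accs.append(report.accuracy)
        assert np.mean(accs) == pytest.approx(1 / 3, abs=0.06)

    def test_small_class_vs_folds_rejected(self):
        table = table_from(np.random.default_rng(0).normal(size=(8, 2)),
                           ["COPD"] * 5 + ["healthy"] * 3)
        with pytest.raises(ValueError, match="healthy"):
            cross_validate(table, folds=4)

    def test_holdout_is_stratified(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=(100, 2))
        x[60:] += 8.0
        y = np.array(["COPD"] * 60 + ["healthy"] * 40, dtype=object)
        report = holdout_validate(table_from(x, y), test_fraction=0.2, seed=1)
        assert report.confusion.counts.sum() == 20
        row_sums = report.confusion.counts.sum(axis=1)
        assert list(row_sums) == [12, 8]  # class ratio preserved
        assert report.accuracy == 1.0

    def test_in_fold_balancing_runs_on_imbalanced_data(self):
        rng = np.random.default_rng(12)
        a = rng.normal([0, 0], 1.0, (60, 2))
        b = rng.normal([5, 5], 1.0, (20, 2))
        table = table_from(np.vstack([a, b]), ["COPD"] * 60 + ["healthy"] * 20)
        report, _ = cross_validate(table, folds=2, seed=0, balance_in_fold=True)
        assert report.accuracy > 0.9
        # test folds contain only the 80 original rows
        assert report.confusion.counts.sum() == 80

    def test_confusion_from_predictions_counts_rows_as_true(self):
        cm = confusion_from_predictions(
            np.array(["a", "a", "b"]), np.array(["a", "b", "b"]), ["a", "b"]
        )
        np.testing.assert_array_equal(cm.counts, [[1, 1], [0, 1]])
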