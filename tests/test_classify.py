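"""PCA, QDA, LOOCV, ROC and confusion-metric tests."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from embryoraman import classify, synthetic
from embryoraman.classify import (
    ConfusionMetrics,
    confusion_metrics,
    format_percent,
    loocv,
    pca_fit,
    qda_fit,
    region_matrix,
    roc_analysis,
)
from embryoraman.errors import RamanPipelineError
from embryoraman.io_formats import LabeledCohort, Spectrum
from embryoraman.synthetic import SimConfig


def _two_cluster_scores(rng, n1=10, n2=10, sep=6.0, cov=None):
    cov = np.eye(2) if cov is None else cov
    a = rng.multivariate_normal([sep / 2, 0], cov, n1)
    b = rng.multivariate_normal([-sep / 2, 0], cov, n2)
    scores = np.vstack([a, b])
    labels = np.array([True] * n1 + [False] * n2)
    return scores, labels


class TestRegionMatrix:
    def test_sixty_channels_at_unit_step(self, default_cohort):
        _, cohort, _, _, _ = default_cohort
        X = region_matrix(cohort, 890.0, 950.0)
        assert X.shape == (31, 60)

    def test_empty_region_raises(self, default_cohort):
        _, cohort, _, _, _ = default_cohort
        with pytest.raises(RamanPipelineError):
            region_matrix(cohort, 900.0, 900.0)

    def test_identical_spectra_identical_rows(self, axis):
        y = np.exp(-((axis - 920.0) ** 2) / 200.0)
        spectra = [Spectrum("a", axis, y), Spectrum("b", axis, y)]
        cohort = LabeledCohort(spectra, {"a": "pregnant", "b": "nonpregnant"}, axis)
        X = region_matrix(cohort)
        np.testing.assert_array_equal(X[0], X[1])


class TestPCA:
    def test_collinear_samples_have_unit_first_variance(self):
        rng = np.random.default_rng(0)
        direction = rng.normal(size=30)
        X = np.outer(rng.normal(size=8), direction)
        model, scores = pca_fit(X, k=1)
        assert model.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-10)

    def test_rank_below_k_raises(self):
        rng = np.random.default_rng(0)
        X = np.outer(rng.normal(size=8), rng.normal(size=30))
        with pytest.raises(RamanPipelineError, match="rank"):
            pca_fit(X, k=2)

    def test_scores_are_decorrelated(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 15))
        _, scores = pca_fit(X, k=2)
        cov = np.cov(scores, rowvar=False)
        assert abs(cov[0, 1]) < 1e-8 * max(cov[0, 0], cov[1, 1])

    def test_rank_two_reconstruction(self):
        rng = np.random.default_rng(2)
        basis = np.linalg.qr(rng.normal(size=(15, 2)))[0].T
        coords = rng.normal(size=(12, 2)) * [5.0, 2.0]
        X = 3.0 + coords @ basis
        model, scores = pca_fit(X, k=2)
        recon = model.mean + scores @ model.components
        np.testing.assert_allclose(recon, X, atol=1e-8)

    def test_loadings_orthonormal_and_sign_fixed(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(25, 40))
        model, _ = pca_fit(X, k=2)
        np.testing.assert_allclose(model.components @ model.components.T, np.eye(2), atol=1e-10)
        for row in model.components:
            assert row[np.argmax(np.abs(row))] > 0

    def test_matches_sklearn_subspace(self):
        sklearn = pytest.importorskip("sklearn.decomposition")
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 12))
        model, scores = pca_fit(X, k=2)
        sk = sklearn.PCA(n_components=2).fit(X)
        np.testing.assert_allclose(
            np.abs(model.components @ sk.components_.T), np.eye(2), atol=1e-8
        )
        np.testing.assert_allclose(
            model.explained_variance_ratio, sk.explained_variance_ratio_, atol=1e-10
        )


class TestQDA:
    def test_posterior_near_one_at_class_mean(self):
        rng = np.random.default_rng(5)
        scores, labels = _two_cluster_scores(rng, sep=8.0)
        model = qda_fit(scores, labels)
        assert model.posterior(model.means["pregnant"][None, :])[0] > 0.99
        assert model.posterior(model.means["nonpregnant"][None, :])[0] < 0.01

    def test_posterior_matches_gaussian_density_oracle(self):
        rng = np.random.default_rng(6)
        scores, labels = _two_cluster_scores(rng, sep=3.0)
        model = qda_fit(scores, labels)
        pts = rng.normal(size=(50, 2)) * 3
        num = multivariate_normal(model.means["pregnant"], model.covariances["pregnant"]).pdf(pts) * model.priors["pregnant"]
        den = num + multivariate_normal(
            model.means["nonpregnant"], model.covariances["nonpregnant"]
        ).pdf(pts) * model.priors["nonpregnant"]
        np.testing.assert_allclose(model.posterior(pts), num / den, atol=1e-12)

    def test_equal_covariances_reduce_to_linear_boundary(self):
        sklearn_da = pytest.importorskip("sklearn.discriminant_analysis")
        rng = np.random.default_rng(7)
        base = rng.multivariate_normal([0, 0], [[1.0, 0.3], [0.3, 0.5]], 12)
        scores = np.vstack([base + [2.0, 1.0], base - [2.0, 1.0]])
        labels = np.array([True] * 12 + [False] * 12)
        model = qda_fit(scores, labels, regularization=0.0)
        lda = sklearn_da.LinearDiscriminantAnalysis().fit(scores, labels)
        g = np.stack(
            np.meshgrid(np.linspace(-5, 5, 41), np.linspace(-4, 4, 41)), -1
        ).reshape(-1, 2)
        margin = np.abs(lda.decision_function(g))
        ours = model.predict(g)
        theirs = lda.predict(g).astype(bool)
        agree = ours == theirs
        assert np.all(agree[margin > 0.1])

    def test_tied_posterior_predicts_nonpregnant(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(6, 2))
        scores = np.vstack([pts, pts])  # identical class clouds, priors 0.5
        labels = np.array([True] * 6 + [False] * 6)
        model = qda_fit(scores, labels)
        assert not model.predict(np.array([[0.2, -0.3]]))[0]

    def test_small_class_raises(self):
        scores = np.random.default_rng(9).normal(size=(5, 2))
        labels = np.array([True, True, False, False, False])
        with pytest.raises(RamanPipelineError, match="need >= 3"):
            qda_fit(scores, labels)


class TestLOOCV:
    def test_separable_cohort_is_perfect(self):
        cfg = SimConfig(seed=21, effect_size=3.0, noise_sd=0.005,
                        baseline_coeffs=(0, 0, 0, 0), water_profile=(), spike_rate=0.0)
        cohort, _ = synthetic.generate_cohort(cfg)
        cv = loocv(cohort)
        assert cv.sensitivity == 1.0
        assert cv.specificity == 1.0

    def test_confusion_identities(self, default_cohort):
        _, cohort, _, toluene, water = default_cohort
        from embryoraman.preprocess import run_chain

        processed, _ = run_chain(cohort, toluene, water)
        cv = loocv(processed)
        cm = cv.confusion
        assert cm.tp + cm.fn == int(cv.labels.sum())
        assert cm.tn + cm.fp == int((~cv.labels).sum())

    def test_no_leakage_from_held_out_label(self):
        rng = np.random.default_rng(22)
        X = rng.normal(size=(10, 6))
        X[:5] += 2.0
        y = np.array([True] * 5 + [False] * 5)
        base = loocv(X, y)
        for i in range(10):
            corrupted = y.copy()
            corrupted[i] = ~corrupted[i]
            cv = loocv(X, corrupted)
            assert cv.posterior_scores[i] == pytest.approx(base.posterior_scores[i], abs=1e-12)

    def test_minimum_viable_cohort_runs(self):
        rng = np.random.default_rng(23)
        X = rng.normal(size=(10, 4))
        X[:5, 0] += 4.0
        y = np.array([True] * 5 + [False] * 5)
        cv = loocv(X, y)
        assert len(cv.sample_ids) == 10


class TestROC:
    def test_perfect_separation(self):
        roc = roc_analysis(
            [0.1, 0.2, 0.8, 0.9], np.array([False, False, True, True])
        )
        assert roc.auc == 1.0
        assert roc.optimal_threshold == pytest.approx(0.5)
        assert roc.optimal_sensitivity == 1.0
        assert roc.optimal_specificity == 1.0

    def test_identical_scores_degenerate_half_auc(self):
        roc = roc_analysis([0.4] * 6, np.array([True] * 3 + [False] * 3))
        assert roc.degenerate
        assert roc.auc == 0.5

    def test_auc_equals_u_over_n1n2(self):
        from embryoraman.stats_screen import mann_whitney

        rng = np.random.default_rng(24)
        for _ in range(50):
            n1, n2 = rng.integers(2, 15, 2)
            x = rng.normal(0.5, 1, n1)
            y = rng.normal(0, 1, n2)
            scores = np.concatenate([x, y])
            labels = np.array([True] * n1 + [False] * n2)
            roc = roc_analysis(scores, labels, positive_higher=True)
            u = mann_whitney(x, y).u_statistic
            assert roc.auc == pytest.approx(u / (n1 * n2), abs=1e-12)

    def test_orientation_autoflip_logged(self):
        scores = [0.9, 0.8, 0.2, 0.1]
        labels = np.array([False, False, True, True])  # low score = positive
        roc = roc_analysis(scores, labels)
        assert roc.flipped
        assert roc.auc == 1.0

    def test_sensitivity_monotone_in_threshold(self):
        rng = np.random.default_rng(25)
        scores = rng.normal(size=20)
        labels = rng.random(20) > 0.5
        labels[0], labels[1] = True, False
        roc = roc_analysis(scores, labels, positive_higher=True)
        assert np.all(np.diff(roc.sensitivity) <= 1e-12)


class TestConfusion:
    def test_reported_tally_reproduces_published_rates(self):
        preds = np.array([True] * 14 + [False] * 1 + [False] * 10 + [True] * 6)
        labels = np.array([True] * 15 + [False] * 16)
        cm = confusion_metrics(preds, labels)
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (14, 1, 10, 6)
        assert cm.sensitivity == pytest.approx(14 / 15)
        assert cm.specificity == pytest.approx(10 / 16)
        assert format_percent(100 * cm.sensitivity) == "93"
        assert format_percent(100 * cm.specificity) == "62.5"

    def test_all_correct(self):
        labels = np.array([True] * 3 + [False] * 4)
        cm = confusion_metrics(labels.copy(), labels)
        assert cm.sensitivity == 1.0 and cm.specificity == 1.0

    def test_all_predicted_positive(self):
        labels = np.array([True] * 3 + [False] * 4)
        cm = confusion_metrics(np.ones(7, bool), labels)
        assert cm.sensitivity == 1.0 and cm.specificity == 0.0

    def test_length_mismatch_raises(self):
        with pytest.raises(RamanPipelineError):
            confusion_metrics(np.ones(3, bool), np.ones(4, bool))

    @pytest.mark.parametrize(
        "value,shown",
        [(93.3333333, "93"), (62.5, "62.5"), (100.0, "100"), (87.5, "87.5"), (0.0, "0")],
    )
    def test_format_percent(self, value, shown):
        assert format_percent(value) == shown
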