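"""PCA, NIPALS PLS1, PCR and PLS-DA against independent oracles."""

import numpy as np
import pytest

from aquanir.latent import (
    classify_plsda,
    fit_pca,
    fit_pcr,
    fit_plsda,
    fit_plsr,
    predict_regression,
)


def centered(rng, n, m):
    X = rng.normal(size=(n, m))
    return X - X.mean(axis=0)


class TestPCA:
    def test_rank_one_matrix_fully_explained(self, rng):
        t = rng.normal(size=10)
        p = rng.normal(size=20)
        X = np.outer(t - t.mean(), p)
        model = fit_pca(X, 1)
        assert model.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-10)

    def test_matches_svd_oracle_up_to_sign(self, rng):
        X = centered(rng, 20, 50)
        k = 5
        model = fit_pca(X, k)
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        for a in range(k):
            p, v = model.x_loadings[:, a], Vt[a]
            sign = np.sign(p @ v)
            np.testing.assert_allclose(p, sign * v, atol=1e-8)
            np.testing.assert_allclose(
                model.scores[:, a], sign * U[:, a] * s[a], atol=1e-8
            )

    def test_sign_convention_is_deterministic(self, rng):
        X = centered(rng, 12, 9)
        model = fit_pca(X, 4)
        peaks = np.abs(model.x_loadings).argmax(axis=0)
        assert np.all(model.x_loadings[peaks, np.arange(4)] > 0)

    def test_loadings_orthonormal_and_variance_ordered(self, rng):
        X = centered(rng, 15, 30)
        model = fit_pca(X, 6)
        gram = model.x_loadings.T @ model.x_loadings
        np.testing.assert_allclose(gram, np.eye(6), atol=1e-8)
        evr = model.explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-12) and evr.sum() <= 1 + 1e-12

    def test_k_too_large_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_pca(centered(rng, 5, 8), 5)


class TestPLSR:
    def test_exact_rank_one_fit(self, rng):
        p = rng.normal(size=30)
        t = rng.normal(size=12)
        t -= t.mean()
        X = np.outer(t, p)
        y = 3.0 * t
        model = fit_plsr(X, y, 1)
        resid = y - predict_regression(model, X)
        assert np.sum(resid**2) < 1e-12

    def test_one_factor_coefficients_proportional_to_xty(self, rng):
        X = centered(rng, 15, 8)
        y = rng.normal(size=15)
        y -= y.mean()
        b = fit_plsr(X, y, 1).regression_vector
        ref = X.T @ y
        np.testing.assert_allclose(
            b / np.linalg.norm(b), ref / np.linalg.norm(ref), atol=1e-10
        )

    @pytest.mark.parametrize("fitter", [fit_plsr, fit_pcr])
    def test_full_rank_matches_ols_pseudoinverse(self, rng, fitter):
        X = centered(rng, 15, 8)
        y = rng.normal(size=15)
        y -= y.mean()
        k = np.linalg.matrix_rank(X)
        model = fitter(X, y, k)
        yhat_ols = X @ (np.linalg.pinv(X) @ y)
        np.testing.assert_allclose(predict_regression(model, X), yhat_ols, atol=1e-6)

    def test_training_residual_non_increasing_in_k(self, rng):
        X = centered(rng, 20, 12)
        y = rng.normal(size=20)
        y -= y.mean()
        rss = [
            np.sum((y - predict_regression(fit_plsr(X, y, k), X)) ** 2)
            for k in range(1, 7)
        ]
        assert np.all(np.diff(rss) <= 1e-10)

    def test_zero_variance_y_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_plsr(centered(rng, 6, 4), np.zeros(6), 1)

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_predictions_match_sklearn_pls(self, k):
        """Independent cross-check against scikit-learn's PLS1."""
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(8)
        X = rng.normal(size=(18, 25))
        y = X[:, :2] @ np.array([1.0, -1.0]) + 0.3 * rng.normal(size=18)
        Xc, yc = X - X.mean(axis=0), y - y.mean()
        ours = predict_regression(fit_plsr(Xc, yc, k), Xc)
        theirs = (
            PLSRegression(n_components=k, scale=False).fit(X, y).predict(X).ravel()
            - y.mean()
        )
        np.testing.assert_allclose(ours, theirs, atol=1e-10)

    def test_noise_free_simulation_recovers_y(self, rng):
        B = rng.normal(size=(3, 40))
        S = rng.normal(size=(25, 3))
        X = S @ B
        X -= X.mean(axis=0)
        y = S @ np.array([1.0, -0.5, 2.0])
        y -= y.mean()
        model = fit_plsr(X, y, 3)
        yhat = predict_regression(model, X)
        assert np.corrcoef(y, yhat)[0, 1] > 0.999999


class TestPCR:
    def test_y_orthogonal_to_scores_gives_null_model(self, rng):
        p = rng.normal(size=10)
        t = rng.normal(size=8)
        t -= t.mean()
        X = np.outer(t, p)  # rank 1
        y = rng.normal(size=8)
        y -= y.mean()
        y -= t * (t @ y) / (t @ t)  # orthogonal to the only score
        model = fit_pcr(X, y, 1)
        assert np.linalg.norm(model.regression_vector) < 1e-10
        np.testing.assert_allclose(predict_regression(model, X), 0.0, atol=1e-10)

    def test_pcr_equals_plsr_on_rank_one_x(self, rng):
        p = rng.normal(size=12)
        t = rng.normal(size=9)
        t -= t.mean()
        X = np.outer(t, p)
        y = 2.0 * t + 0.0
        np.testing.assert_allclose(
            fit_pcr(X, y, 1).regression_vector,
            fit_plsr(X, y, 1).regression_vector,
            atol=1e-10,
        )


class TestPredict:
    def test_mean_row_predicts_zero_centered_response(self, rng):
        X = centered(rng, 10, 6)
        y = rng.normal(size=10)
        y -= y.mean()
        model = fit_plsr(X, y, 2)
        assert predict_regression(model, np.zeros((1, 6)))[0] == pytest.approx(0.0)

    def test_grid_mismatch_rejected(self, rng):
        model = fit_plsr(centered(rng, 8, 5), rng.normal(size=8), 1)
        with pytest.raises(ValueError):
            predict_regression(model, np.zeros((1, 6)))


class TestPLSDA:
    def _two_classes(self, seed=0, n=10, sep=10.0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(2 * n, 20))
        X[n:, 0] += sep
        labels = ["a"] * n + ["b"] * n
        Xc = X - X.mean(axis=0)
        return Xc, labels

    def test_training_sample_lands_on_its_side(self):
        Xc, labels = self._two_classes()
        model = fit_plsda(Xc, labels, 1)
        got = classify_plsda(model, Xc)
        assert got == labels

    def test_balanced_dummy_centered_at_half(self):
        Xc, labels = self._two_classes()
        model = fit_plsda(Xc, labels, 1)
        assert model.extra["dummy_mean"] == pytest.approx(0.5)

    def test_tie_at_half_is_unassigned(self):
        Xc, labels = self._two_classes()
        model = fit_plsda(Xc, labels, 1)
        # the training-mean spectrum predicts the dummy mean 0.5 exactly
        assert classify_plsda(model, np.zeros((1, Xc.shape[1])))[0] is None

    def test_more_than_two_classes_unsupported(self, rng):
        X = centered(rng, 9, 5)
        with pytest.raises(ValueError):
            fit_plsda(X, ["a", "b", "c"] * 3, 1)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_plsda(centered(rng, 4, 5), ["a"] * 4, 1)

    def test_well_separated_classes_classify_perfectly_in_cv(self):
        from aquanir.validation import loo_crossvalidate, misclassification_summary

        rng = np.random.default_rng(12)
        n = 8
        X = 0.1 * rng.normal(size=(2 * n, 15))
        X[n:, 2] += 1.0  # 10x the noise scale
        labels = ["a"] * n + ["b"] * n
        cv = loo_crossvalidate("plsda", X, labels, 1)
        pred = ["b" if v > 0.5 else ("a" if v < 0.5 else None) for v in cv[:, 0]]
        assert misclassification_summary(labels, pred).ratio_correct == 1.0
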