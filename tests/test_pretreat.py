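"""Smoothing, centering and orthogonal signal correction."""

import numpy as np
import pytest

from aquanir.latent import fit_plsr
from aquanir.pretreat import apply_osc, fit_centering, fit_osc, smooth_spectra
from aquanir.spectra import SampleMeta, SpectraSet, make_grid
from conftest import random_spectra


def spectra_from(A):
    A = np.atleast_2d(A)
    grid = make_grid(1300.0, 1300.0 + 0.5 * (A.shape[1] - 1), 0.5)
    return SpectraSet(A, grid, [SampleMeta(f"S{i}") for i in range(A.shape[0])])


class TestSmoothing:
    @pytest.mark.parametrize("method", ["moving_average", "polynomial_order2"])
    @pytest.mark.parametrize("window", [3, 21, 45])
    def test_constant_spectrum_unchanged(self, method, window):
        s = spectra_from(np.full((2, 60), 0.7))
        out = smooth_spectra(s, window, method)
        np.testing.assert_allclose(out.absorbance, 0.7, atol=1e-12)

    @pytest.mark.parametrize("method", ["moving_average", "polynomial_order2"])
    def test_linear_ramp_unchanged_at_interior(self, method):
        wl = make_grid(1300.0, 1329.5, 0.5).values
        row = 0.1 + 0.003 * wl
        s = spectra_from(row[None, :])
        out = smooth_spectra(s, 7, method)
        np.testing.assert_allclose(out.absorbance[0, 3:-3], row[3:-3], atol=1e-12)

    def test_moving_average_equals_bruteforce_windowed_mean(self):
        rng = np.random.default_rng(5)
        wl = make_grid(1300.0, 1349.5, 0.5).values
        row = np.sin(wl / 3.0) + 0.1 * rng.normal(size=wl.size)
        s = spectra_from(row[None, :])
        w = 21
        out = smooth_spectra(s, w, "moving_average").absorbance[0]
        half = w // 2
        # symmetric reflection: ...row[1], row[0] | row[0], row[1]...
        padded = np.concatenate([row[:half][::-1], row, row[-half:][::-1]])
        expected = np.array(
            [padded[i : i + w].mean() for i in range(row.size)]
        )
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_shape_preserved_and_energy_non_increasing(self):
        s = random_spectra(seed=9, n=4, m=80)
        centered = s.absorbance - s.absorbance.mean(axis=1, keepdims=True)
        sc = spectra_from(centered)
        out = smooth_spectra(sc, 9, "moving_average")
        assert out.absorbance.shape == centered.shape
        assert np.sum(out.absorbance**2) <= np.sum(centered**2) + 1e-12

    @pytest.mark.parametrize("window", [2, 4, 101])
    def test_bad_windows_rejected(self, window):
        s = spectra_from(np.zeros((1, 50)))
        with pytest.raises(ValueError):
            smooth_spectra(s, window)


class TestCentering:
    def test_column_means_stored(self):
        model = fit_centering(np.array([[0.0, 0.0], [2.0, 2.0]]))
        np.testing.assert_allclose(model.mean_vector, [1.0, 1.0])

    def test_training_columns_centered_to_zero(self, rng):
        X = rng.normal(size=(8, 12))
        model = fit_centering(X, rng.normal(size=8))
        assert np.max(np.abs(model.transform(X).mean(axis=0))) < 1e-12

    def test_new_row_keeps_deviation_from_training_mean(self, rng):
        X = rng.normal(size=(6, 4))
        model = fit_centering(X)
        new = rng.normal(size=4)
        np.testing.assert_allclose(
            model.transform(new[None, :])[0], new - X.mean(axis=0), atol=1e-12
        )

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            fit_centering(np.ones((1, 3)))


def _confounded_data(seed, n=30, m=60, conf_scale=1.0):
    """X = yc a' + d b' + noise, with a perp b and d perp yc."""
    rng = np.random.default_rng(seed)
    a = rng.normal(size=m)
    b = rng.normal(size=m)
    b -= a * (a @ b) / (a @ a)  # a perp b
    y = rng.normal(size=n)
    d = rng.normal(size=n)
    d -= y * (y @ d) / (y @ y)  # d perp y
    yc = y - y.mean()
    X = np.outer(yc, a) + conf_scale * np.outer(d, b) + 0.01 * rng.normal(size=(n, m))
    Xc = X - X.mean(axis=0)
    return Xc, yc - yc.mean(), b / np.linalg.norm(b)


class TestOSC:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_training_scores_orthogonal_to_y(self, seed):
        Xc, yc, _ = _confounded_data(seed)
        model = fit_osc(Xc, yc, 1)
        t = Xc @ model.weight_vectors[0]
        assert abs(t @ yc) <= 1e-8 * np.linalg.norm(t) * np.linalg.norm(yc)

    def test_columns_proportional_to_y_leave_nothing_to_remove(self):
        rng = np.random.default_rng(4)
        yc = rng.normal(size=12)
        yc -= yc.mean()
        coeffs = rng.normal(size=20)
        Xc = np.outer(yc, coeffs)
        model = fit_osc(Xc, yc, 1)
        corrected = apply_osc(model, Xc)
        removed = np.sum((Xc - corrected) ** 2) / np.sum(Xc**2)
        assert removed < 1e-6

    def test_confounder_variance_reduced_by_95_percent(self):
        Xc, yc, b_hat = _confounded_data(seed=7, conf_scale=2.0)
        model = fit_osc(Xc, yc, 1)
        corrected = apply_osc(model, Xc)
        before = np.sum((Xc @ b_hat) ** 2)
        after = np.sum((corrected @ b_hat) ** 2)
        assert after < 0.05 * before

    def test_apply_on_training_reproduces_deflation(self):
        Xc, yc, _ = _confounded_data(seed=2)
        model = fit_osc(Xc, yc, 2)
        # manual sequential deflation with the stored vectors
        Z = Xc.copy()
        for w, p in zip(model.weight_vectors, model.loading_vectors):
            t = Z @ w
            Z = Z - np.outer(t, p)
        np.testing.assert_allclose(apply_osc(model, Xc), Z, atol=1e-10)

    def test_zero_matrix_maps_to_zero(self):
        Xc, yc, _ = _confounded_data(seed=3)
        model = fit_osc(Xc, yc, 1)
        out = apply_osc(model, np.zeros_like(Xc))
        np.testing.assert_allclose(out, 0.0, atol=1e-15)

    def test_new_samples_lose_removed_direction(self):
        Xc, yc, _ = _confounded_data(seed=8, n=60, conf_scale=2.0)
        train, test = Xc[:30], Xc[30:]
        model = fit_osc(train - train.mean(0), yc[:30] - yc[:30].mean(), 1)
        p = model.loading_vectors[0]
        p_hat = p / np.linalg.norm(p)
        corrected = apply_osc(model, test)
        assert np.sum((corrected @ p_hat) ** 2) < 0.05 * np.sum((test @ p_hat) ** 2)

    def test_osc_never_hurts_training_fit(self):
        """Removing an OSC component does not increase training SEC at equal k."""
        for seed in range(3):
            Xc, yc, _ = _confounded_data(seed=seed, conf_scale=3.0)
            rss = {}
            for use_osc in (False, True):
                Z = apply_osc(fit_osc(Xc, yc, 1), Xc) if use_osc else Xc
                model = fit_plsr(Z, yc, 2)
                rss[use_osc] = np.sum((yc - Z @ model.regression_vector) ** 2)
            assert rss[True] <= rss[False] + 1e-10

    def test_zero_variance_matrix_rejected(self):
        yc = np.array([-1.0, 0.0, 1.0])
        with pytest.raises(ValueError):
            fit_osc(np.zeros((3, 5)), yc, 1)

    def test_dimension_mismatch_rejected(self):
        Xc, yc, _ = _confounded_data(seed=1)
        model = fit_osc(Xc, yc, 1)
        with pytest.raises(ValueError):
            apply_osc(model, np.zeros((2, Xc.shape[1] + 1)))
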