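"""Spectral pretreatments: smoothing, mean centering, orthogonal signal
correction (OSC).

The pipeline convention is smoothing -> wavelength-range selection ->
mean centering -> OSC -> model; centering and OSC belong to the calibration
(they use the training set, and OSC uses the reference values y) and are
therefore refit inside every cross-validation fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_coeffs

from .spectra import SpectraSet

__all__ = [
    "smooth_spectra",
    "CenteringModel",
    "fit_centering",
    "OSCModel",
    "fit_osc",
    "apply_osc",
    "ConvergenceError",
]


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, n_iterations: int):
        super().__init__(message)
        self.n_iterations = n_iterations


def _smooth_matrix(A: np.ndarray, window_points: int, method: str) -> np.ndarray:
    half = window_points // 2
    if method == "moving_average":
        kernel = np.full(window_points, 1.0 / window_points)
    elif method == "polynomial_order2":
        # Savitzky-Golay quadratic smoothing weights
        kernel = savgol_coeffs(window_points, 2)
    else:
        raise ValueError(f"unknown smoothing method {method!r}")
    padded = np.pad(A, ((0, 0), (half, half)), mode="symmetric")
    out = np.empty_like(A)
    for i in range(A.shape[0]):
        out[i] = np.convolve(padded[i], kernel[::-1], mode="valid")
    return out


def smooth_spectra(
    spectra: SpectraSet, window_points: int, method: str = "moving_average"
) -> SpectraSet:
    """Windowed smoothing of each spectrum; edges use symmetric reflection.

    ``moving_average`` is a boxcar mean; ``polynomial_order2`` is quadratic
    Savitzky-Golay.  The window must be odd, >= 3 and at most the number of
    wavelengths, matching the 21- and 45-point windows typical for liquid
    NIR work.
    """
    if window_points % 2 == 0 or window_points < 3:
        raise ValueError(f"window_points must be odd and >= 3, got {window_points}")
    if window_points > spectra.n_wavelengths:
        raise ValueError(
            f"window_points {window_points} exceeds {spectra.n_wavelengths} wavelengths"
        )
    return SpectraSet(
        _smooth_matrix(spectra.absorbance, window_points, method),
        spectra.grid,
        list(spectra.meta),
    )


@dataclass
class CenteringModel:
    """Column means of the training X (and mean of y, for regression)."""

    mean_vector: np.ndarray
    y_mean: float | None = None

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.mean_vector.size:
            raise ValueError(
                f"X has {X.shape[1]} columns, centering model has {self.mean_vector.size}"
            )
        return X - self.mean_vector

    def center_y(self, y: np.ndarray) -> np.ndarray:
        if self.y_mean is None:
            raise ValueError("centering model was fit without reference values")
        return np.asarray(y, dtype=float) - self.y_mean


def fit_centering(X: np.ndarray, y: np.ndarray | None = None) -> CenteringModel:
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError(f"mean centering needs n >= 2 samples, got {X.shape[0]}")
    mean = X.mean(axis=0)
    if not np.all(np.isfinite(mean)):
        raise ValueError("non-finite column means")
    y_mean = None if y is None else float(np.mean(y))
    return CenteringModel(mean, y_mean)


@dataclass
class OSCModel:
    """Orthogonal signal correction: components orthogonal to y, removed.

    ``weight_vectors[a]`` (unit norm) maps a centered spectrum to the a-th
    removed score; ``loading_vectors[a]`` is the matched spectral loading.
    A component stored with zero vectors is inert: the training data held
    nothing orthogonal to y to remove.
    """

    weight_vectors: list[np.ndarray]
    loading_vectors: list[np.ndarray]
    n_components: int
    n_iterations: list[int] = field(default_factory=list)
    algorithm: str = "wold-ls"

    def __post_init__(self):
        if not (
            len(self.weight_vectors) == len(self.loading_vectors) == self.n_components
        ):
            raise ValueError("weights/loadings lists must both have n_components entries")


def fit_osc(
    Xc: np.ndarray,
    yc: np.ndarray,
    n_components: int = 1,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> OSCModel:
    """Fit Wold-style iterative OSC on column-centered Xc and centered yc.

    Per component: start from the leading principal-component score,
    orthogonalize it against yc, regress a weight vector mapping Xc to the
    orthogonalized score (min-norm least squares), renormalize, and iterate
    to convergence; then deflate Xc by the converged score and its loading.
    """
    X = np.array(Xc, dtype=float)
    y = np.asarray(yc, dtype=float)
    if X.shape[0] < 3:
        raise ValueError(f"OSC needs n >= 3 samples, got {X.shape[0]}")
    if X.shape[0] != y.size:
        raise ValueError("Xc and yc disagree on sample count")
    total_ss = float(np.sum(X * X))
    if total_ss <= 0:
        raise ValueError("zero-variance Xc: nothing to correct")
    yy = float(y @ y)
    if yy <= 0:
        raise ValueError("yc has zero variance")

    weights, loadings, iters = [], [], []
    for _ in range(n_components):
        # truncated SVD once per component: the weight regression X w = t
        # is solved through it, and U_r U_r' projects onto the reachable
        # score space without round-tripping through 1/s every iteration
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        keep = s > 1e-12 * s[0]
        Ur, sr, Vr = U[:, keep], s[keep], Vt[keep].T
        t = Ur[:, 0] * sr[0]  # leading PC score as starting point
        scale = np.linalg.norm(t)
        t_dir = t / scale
        n_it = 0
        degenerate = False
        for n_it in range(1, max_iter + 1):
            t_orth = t - y * (y @ t) / yy
            t = Ur @ (Ur.T @ t_orth)
            nrm = np.linalg.norm(t)
            if nrm <= 1e-10 * scale:
                degenerate = True  # nothing orthogonal to y is reachable
                break
            new_dir = t / nrm
            # score direction is determined up to sign
            delta = min(
                np.linalg.norm(new_dir - t_dir), np.linalg.norm(new_dir + t_dir)
            )
            t_dir = new_dir
            if delta < tol:
                break
        else:
            raise ConvergenceError(
                f"OSC did not converge in {max_iter} iterations", max_iter
            )
        if degenerate:
            # inert component: the training data hold nothing orthogonal to y
            weights.append(np.zeros(X.shape[1]))
            loadings.append(np.zeros(X.shape[1]))
            iters.append(n_it)
            continue
        w = Vr @ ((Ur.T @ t) / sr)
        w /= np.linalg.norm(w)
        t = X @ w
        tt = float(t @ t)
        p = X.T @ t / tt
        X = X - np.outer(t, p)
        weights.append(w)
        loadings.append(p)
        iters.append(n_it)
    return OSCModel(weights, loadings, n_components, iters)


def apply_osc(model: OSCModel, Xc: np.ndarray) -> np.ndarray:
    """Remove the stored OSC components from centered spectra."""
    X = np.array(np.atleast_2d(Xc), dtype=float)
    for w, p in zip(model.weight_vectors, model.loading_vectors):
        if X.shape[1] != w.size:
            raise ValueError(
                f"X has {X.shape[1]} columns, OSC model has {w.size}"
            )
        nw = np.linalg.norm(w)
        if nw == 0:  # inert component
            continue
        t = X @ (w / nw)
        X = X - np.outer(t, p)
    return X
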