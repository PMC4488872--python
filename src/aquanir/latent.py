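"""Latent-variable decompositions and regressions on centered spectra.

These are the numeric cores: deterministic SVD-based PCA, NIPALS PLS1
partial least squares regression (with y deflation), principal component
regression, and PLS discriminant analysis on a {0, 1} dummy response.
All functions take column-centered X (and centered y) and know nothing
about pretreatments; the calibration layer composes them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "LatentModel",
    "fit_pca",
    "fit_plsr",
    "fit_pcr",
    "fit_plsda",
    "predict_regression",
    "classify_plsda",
]


@dataclass
class LatentModel:
    """Scores/loadings/weights container for PCA, PCR, PLSR and PLS-DA.

    ``regression_vector`` maps a centered spectrum to a centered
    prediction; for PLS-DA the response is the {0, 1} class code.
    """

    kind: str  # pca | pcr | plsr | plsda
    n_factors: int
    scores: np.ndarray  # n x k
    x_loadings: np.ndarray  # m x k
    x_weights: np.ndarray | None = None  # m x k, PLS only
    y_loadings: np.ndarray | None = None  # k, regression models
    regression_vector: np.ndarray | None = None  # m, regression models
    explained_variance_ratio: np.ndarray | None = None  # k, PCA/PCR
    y_deflation: bool = True
    extra: dict[str, Any] = field(default_factory=dict)

    def regression_vectors_nested(self) -> np.ndarray:
        """m x k matrix whose a-th column is the coefficient vector using
        the first a+1 factors (NIPALS factors are nested)."""
        if self.kind in ("plsr", "plsda"):
            W, P, q = self.x_weights, self.x_loadings, self.y_loadings
            out = np.empty((W.shape[0], self.n_factors))
            for a in range(1, self.n_factors + 1):
                out[:, a - 1] = W[:, :a] @ np.linalg.solve(
                    P[:, :a].T @ W[:, :a], q[:a]
                )
            return out
        if self.kind == "pcr":
            P, coef = self.x_loadings, self.extra["score_coefficients"]
            T = self.scores
            out = np.empty((P.shape[0], self.n_factors))
            y = self.extra["yc_train"]
            for a in range(1, self.n_factors + 1):
                c, *_ = np.linalg.lstsq(T[:, :a], y, rcond=None)
                out[:, a - 1] = P[:, :a] @ c
            return out
        raise ValueError(f"{self.kind} has no regression vector")


def _check_k(k: int, n: int, m: int) -> None:
    if k < 1:
        raise ValueError(f"need at least one factor, got k={k}")
    if k > min(n - 1, m):
        raise ValueError(f"k={k} exceeds min(n-1, m) = {min(n - 1, m)} (n={n}, m={m})")


def fit_pca(Xc: np.ndarray, k: int) -> LatentModel:
    """Top-k principal components of centered Xc via SVD.

    Loadings are orthonormal, ordered by decreasing explained variance,
    with the sign fixed so each loading's largest-magnitude element is
    positive (deterministic output).
    """
    Xc = np.asarray(Xc, dtype=float)
    n, m = Xc.shape
    _check_k(k, n, m)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    P = Vt[:k].T
    # sign convention: largest |element| of each loading positive
    flip = np.sign(P[np.argmax(np.abs(P), axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    P = P * flip
    T = U[:, :k] * s[:k] * flip
    total = float(np.sum(s**2))
    evr = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    return LatentModel(
        kind="pca",
        n_factors=k,
        scores=T,
        x_loadings=P,
        explained_variance_ratio=evr,
    )


def fit_plsr(
    Xc: np.ndarray, yc: np.ndarray, k: int, kind: str = "plsr"
) -> LatentModel:
    """NIPALS PLS1: w_a prop. X_a' y_a (unit norm), t = X w, p = X't/t't,
    q = y't/t't, deflate X (and y).  regression_vector = W (P'W)^-1 q."""
    Xc = np.asarray(Xc, dtype=float)
    yc = np.asarray(yc, dtype=float)
    n, m = Xc.shape
    _check_k(k, n, m)
    if float(yc @ yc) <= 0:
        raise ValueError("reference values have zero variance")
    X = Xc.copy()
    y = yc.copy()
    W = np.empty((m, k))
    P = np.empty((m, k))
    T = np.empty((n, k))
    q = np.empty(k)
    for a in range(k):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw <= 1e-14 * max(np.linalg.norm(Xc), 1.0):
            raise np.linalg.LinAlgError(
                f"X and y are uncorrelated after {a} factors; cannot extract factor {a + 1}"
            )
        w /= nw
        t = X @ w
        tt = float(t @ t)
        if tt <= 0:
            raise np.linalg.LinAlgError(f"zero score variance at factor {a + 1}")
        p = X.T @ t / tt
        q[a] = float(y @ t) / tt
        X -= np.outer(t, p)
        y = y - t * q[a]
        W[:, a], P[:, a], T[:, a] = w, p, t
    try:
        b = W @ np.linalg.solve(P.T @ W, q)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"singular P'W at k={k}: {exc}") from None
    return LatentModel(
        kind=kind,
        n_factors=k,
        scores=T,
        x_loadings=P,
        x_weights=W,
        y_loadings=q,
        regression_vector=b,
        y_deflation=True,
    )


def fit_pcr(Xc: np.ndarray, yc: np.ndarray, k: int) -> LatentModel:
    """Least squares of centered y on the first k PCA scores of centered X."""
    yc = np.asarray(yc, dtype=float)
    if float(yc @ yc) <= 0:
        raise ValueError("reference values have zero variance")
    pca = fit_pca(Xc, k)
    coef, *_ = np.linalg.lstsq(pca.scores, yc, rcond=None)
    b = pca.x_loadings @ coef
    return LatentModel(
        kind="pcr",
        n_factors=k,
        scores=pca.scores,
        x_loadings=pca.x_loadings,
        y_loadings=coef,
        regression_vector=b,
        explained_variance_ratio=pca.explained_variance_ratio,
        extra={"score_coefficients": coef, "yc_train": yc.copy()},
    )


def predict_regression(model: LatentModel, Xc_new: np.ndarray) -> np.ndarray:
    """Centered predictions Xc_new . b for a fitted regression model."""
    if model.regression_vector is None:
        raise ValueError(f"{model.kind} model has no regression vector")
    Xc_new = np.atleast_2d(np.asarray(Xc_new, dtype=float))
    if Xc_new.shape[1] != model.regression_vector.size:
        raise ValueError(
            f"X has {Xc_new.shape[1]} columns, model expects {model.regression_vector.size}"
        )
    return Xc_new @ model.regression_vector


def fit_plsda(Xc: np.ndarray, labels, k: int) -> LatentModel:
    """PLS-DA: PLS1 on a centered {0, 1} dummy coding of exactly two classes.

    Class order (and hence the 0/1 coding) is sorted label order; the
    mapping is stored on the model.
    """
    labels = [str(l) for l in labels]
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise ValueError(
            f"PLS-DA here is two-class; got {len(classes)} class(es): {classes}"
        )
    counts = {c: labels.count(c) for c in classes}
    if min(counts.values()) < 2:
        raise ValueError(f"each class needs >= 2 samples, got {counts}")
    dummy = np.array([float(classes.index(l)) for l in labels])
    yc = dummy - dummy.mean()
    model = fit_plsr(Xc, yc, k, kind="plsda")
    model.extra["classes"] = classes
    model.extra["dummy_mean"] = float(dummy.mean())
    return model


def classify_plsda(model: LatentModel, Xc_new: np.ndarray) -> list[str | None]:
    """Assign the class whose {0, 1} code is nearer the predicted code;
    a prediction of exactly 0.5 is unassigned (None)."""
    if model.kind != "plsda":
        raise ValueError("model is not a PLS-DA model")
    yhat = predict_regression(model, Xc_new) + model.extra["dummy_mean"]
    classes = model.extra["classes"]
    out: list[str | None] = []
    for v in yhat:
        if v == 0.5:
            out.append(None)
        else:
            out.append(classes[1] if v > 0.5 else classes[0])
    return out
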