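"""SIMCA class modeling: one PCA submodel per class, residual-distance
classification, interclass distances and per-wavelength discriminating power.

Each class gets its own mean and principal-component subspace.  A new
sample's residual variance on class j is compared with the class's pooled
training residual variance through an F-ratio at ``critical_quantile``;
soft classification means a sample may be accepted by none, one or several
classes.  The interclass distance used here is the plain square-root
pooled-residual ratio whose null value (indistinguishable classes) is 1;
score-range (leverage) limits are not applied.  Both choices are recorded
in the model metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .latent import LatentModel, fit_pca
from .spectra import SpectraSet

__all__ = [
    "SIMCAModel",
    "SIMCAResult",
    "fit_simca",
    "classify_simca",
    "simca_interclass_distance",
    "simca_discriminating_power",
    "SIMCA",
]


@dataclass
class SIMCAModel:
    class_labels: list[str]
    class_submodels: dict[str, LatentModel]
    class_means: dict[str, np.ndarray]
    class_factors: dict[str, int]
    class_sizes: dict[str, int]
    class_residual_sd: np.ndarray  # diag of cross_residual_sd
    cross_residual_sd: np.ndarray  # [i, j] = s(i -> j)
    residual_sd_lambda: np.ndarray  # [i, j, wavelength]
    critical_quantile: float = 0.95
    n_wavelengths: int = 0
    metadata: dict = field(default_factory=dict)

    def f_threshold(self, label: str) -> float:
        """Critical residual-variance ratio for acceptance by a class."""
        j = self.class_labels.index(label)
        k, nj, m = self.class_factors[label], self.class_sizes[label], self.n_wavelengths
        df_sample = m - k
        df_class = (nj - k - 1) * (m - k)
        return float(stats.f.ppf(self.critical_quantile, df_sample, df_class))


@dataclass
class SIMCAResult:
    assignments: list[set[str]]
    nearest_class: list[str]
    residual_sd: np.ndarray  # n_samples x n_classes

    def to_dict(self) -> dict:
        return {
            "assignments": [sorted(a) for a in self.assignments],
            "nearest_class": self.nearest_class,
            "residual_sd": self.residual_sd.tolist(),
        }


def _residuals_on(model_mean, loadings, X):
    """Residual matrix of rows of X projected on a class subspace."""
    Xc = X - model_mean
    return Xc - (Xc @ loadings) @ loadings.T


def fit_simca(
    class_matrices: dict[str, np.ndarray],
    n_factors: int | dict[str, int] = 2,
    critical_quantile: float = 0.95,
) -> SIMCAModel:
    """Fit per-class PCA submodels and the cross-projection residual table.

    ``class_matrices`` maps class label -> raw (uncentered) spectra of that
    class; each class is centered on its own mean.  Residual sds:

    * self fit  s(i->i)^2 = RSS / ((n_i - k_i - 1) (m - k_i))
    * cross fit s(i->j)^2 = RSS / (n_i (m - k_j))

    and the per-wavelength analogues divide each wavelength's residual sum
    of squares by (n_i - k_i - 1) or n_i respectively.
    """
    labels = list(class_matrices)
    if len(labels) < 2:
        raise ValueError("SIMCA needs at least 2 classes")
    k_of = (
        {c: int(n_factors) for c in labels}
        if np.isscalar(n_factors)
        else dict(n_factors)
    )
    mats = {c: np.asarray(class_matrices[c], dtype=float) for c in labels}
    m = mats[labels[0]].shape[1]
    submodels, means = {}, {}
    for c in labels:
        X = mats[c]
        if X.shape[1] != m:
            raise ValueError("classes disagree on wavelength count")
        k = k_of[c]
        if X.shape[0] < k + 2:
            raise ValueError(
                f"class {c!r} has {X.shape[0]} samples; needs >= k+2 = {k + 2}"
            )
        means[c] = X.mean(axis=0)
        submodels[c] = fit_pca(X - means[c], k)

    nc = len(labels)
    s = np.zeros((nc, nc))
    s_lambda = np.zeros((nc, nc, m))
    for i, ci in enumerate(labels):
        Xi, ni = mats[ci], mats[ci].shape[0]
        for j, cj in enumerate(labels):
            kj = k_of[cj]
            R = _residuals_on(means[cj], submodels[cj].x_loadings, Xi)
            rss = float(np.sum(R * R))
            rss_lambda = np.sum(R * R, axis=0)
            if i == j:
                df = (ni - kj - 1) * (m - kj)
                df_lambda = ni - kj - 1
            else:
                df = ni * (m - kj)
                df_lambda = ni
            s[i, j] = np.sqrt(rss / df)
            s_lambda[i, j] = np.sqrt(rss_lambda / df_lambda)
    return SIMCAModel(
        class_labels=labels,
        class_submodels=submodels,
        class_means=means,
        class_factors=k_of,
        class_sizes={c: mats[c].shape[0] for c in labels},
        class_residual_sd=np.diag(s).copy(),
        cross_residual_sd=s,
        residual_sd_lambda=s_lambda,
        critical_quantile=critical_quantile,
        n_wavelengths=m,
        metadata={
            "distance_formula": "sqrt((s12^2+s21^2)/(s11^2+s22^2)), null value 1",
            "acceptance": "residual F-test, no leverage limit",
        },
    )


def classify_simca(model: SIMCAModel, X_new: np.ndarray) -> SIMCAResult:
    """Soft-classify new spectra.

    A sample is accepted by class j when its residual variance ratio
    against s(j->j)^2 is below the class F-threshold; ``nearest_class`` is
    the argmin of residual sd (ties go to the first class in model order).
    """
    X = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X.shape[1] != model.n_wavelengths:
        raise ValueError(
            f"X has {X.shape[1]} columns, model has {model.n_wavelengths}"
        )
    n = X.shape[0]
    nc = len(model.class_labels)
    sd = np.zeros((n, nc))
    accepted = np.zeros((n, nc), dtype=bool)
    for j, c in enumerate(model.class_labels):
        k = model.class_factors[c]
        R = _residuals_on(model.class_means[c], model.class_submodels[c].x_loadings, X)
        s2 = np.sum(R * R, axis=1) / (model.n_wavelengths - k)
        sd[:, j] = np.sqrt(s2)
        s_jj2 = model.cross_residual_sd[j, j] ** 2
        accepted[:, j] = s2 / s_jj2 <= model.f_threshold(c)
    assignments = [
        {model.class_labels[j] for j in np.flatnonzero(accepted[i])} for i in range(n)
    ]
    nearest = [model.class_labels[int(np.argmin(sd[i]))] for i in range(n)]
    return SIMCAResult(assignments=assignments, nearest_class=nearest, residual_sd=sd)


def simca_interclass_distance(model: SIMCAModel) -> np.ndarray:
    """d(i,j) = sqrt((s(i->j)^2 + s(j->i)^2) / (s(i->i)^2 + s(j->j)^2))."""
    s = model.cross_residual_sd
    nc = s.shape[0]
    d = np.ones((nc, nc))
    for i in range(nc):
        for j in range(nc):
            d[i, j] = np.sqrt(
                (s[i, j] ** 2 + s[j, i] ** 2) / (s[i, i] ** 2 + s[j, j] ** 2)
            )
    return d


def simca_discriminating_power(
    model: SIMCAModel, pair: tuple[str, str] | None = None
) -> np.ndarray:
    """Per-wavelength discriminating power for a class pair.

    DP(lambda) = sqrt((s_l(1->2)^2 + s_l(2->1)^2) / (s_l(1->1)^2 + s_l(2->2)^2)).
    """
    if pair is None:
        if len(model.class_labels) != 2:
            raise ValueError("specify the class pair for >2-class models")
        pair = (model.class_labels[0], model.class_labels[1])
    i = model.class_labels.index(pair[0])
    j = model.class_labels.index(pair[1])
    sl = model.residual_sd_lambda
    num = sl[i, j] ** 2 + sl[j, i] ** 2
    den = sl[i, i] ** 2 + sl[j, j] ** 2
    return np.sqrt(num / np.maximum(den, 1e-300))


class SIMCA:
    """SIMCA model built from a :class:`~aquanir.spectra.SpectraSet`.

    Parameters
    ----------
    spectra : SpectraSet
        Pretreated (smoothed, range-selected) spectra.  SIMCA applies its
        own per-class centering; OSC is not used for class modeling.
    label_column : str
        Metadata column holding the class labels.
    n_factors : int or mapping
        Shared factor count, or per-class counts.
    critical_quantile : float
        Probability level of the residual F-test acceptance threshold.
    """

    def __init__(
        self,
        spectra: SpectraSet,
        label_column: str = "class_label",
        n_factors: int | dict[str, int] = 2,
        critical_quantile: float = 0.95,
    ):
        self.spectra = spectra
        self.labels = spectra.labels(label_column)
        self.n_factors = n_factors
        self.critical_quantile = critical_quantile

    def fit(self) -> "SIMCAResults":
        order = list(dict.fromkeys(self.labels))
        mats = {
            c: self.spectra.absorbance[
                np.array([l == c for l in self.labels], dtype=bool)
            ]
            for c in order
        }
        model = fit_simca(mats, self.n_factors, self.critical_quantile)
        return SIMCAResults(model, self.spectra, self.labels)


class SIMCAResults:
    """Fitted SIMCA model with training-set classification metrics."""

    def __init__(self, model: SIMCAModel, spectra: SpectraSet, labels: list[str]):
        self.model = model
        self.spectra = spectra
        self.true_labels = labels
        self.training_result = classify_simca(model, spectra.absorbance)

    @property
    def interclass_distance(self) -> np.ndarray:
        return simca_interclass_distance(self.model)

    def discriminating_power(self, pair=None) -> np.ndarray:
        return simca_discriminating_power(self.model, pair)

    def classify(self, X_new) -> SIMCAResult:
        return classify_simca(self.model, np.asarray(X_new, dtype=float))

    def classification_summary(self):
        from .validation import misclassification_summary

        return misclassification_summary(
            self.true_labels, self.training_result.assignments
        )

    def summary(self) -> str:
        summ = self.classification_summary()
        d = self.interclass_distance
        lines = [
            "SIMCA class modeling",
            "====================",
            f"classes: {', '.join(self.model.class_labels)}",
            f"factors: {self.model.class_factors}",
            f"n wavelengths: {self.model.n_wavelengths}",
            f"ratio correctly classified: {summ.ratio_correct:.4f}",
            f"unassigned: {summ.n_unassigned}  multi-assigned: {summ.n_multi_assigned}",
            "interclass distances:",
        ]
        for i, ci in enumerate(self.model.class_labels):
            for j in range(i + 1, len(self.model.class_labels)):
                cj = self.model.class_labels[j]
                lines.append(f"  d({ci}, {cj}) = {d[i, j]:.4f}")
        return "\n".join(lines)
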