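"""Shared calibration core: centering + optional OSC + latent model.

Centering and OSC are part of the calibration (OSC uses y), so this bundle
is what cross-validation refits on every fold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .latent import (
    LatentModel,
    classify_plsda,
    fit_pcr,
    fit_plsda,
    fit_plsr,
    predict_regression,
)
from .pretreat import CenteringModel, OSCModel, apply_osc, fit_centering, fit_osc

__all__ = ["FittedCalibration", "fit_calibration"]


@dataclass
class FittedCalibration:
    """A fitted centering + OSC + latent-model chain."""

    kind: str  # plsr | pcr | plsda
    centering: CenteringModel
    osc: OSCModel | None
    model: LatentModel

    def _corrected(self, X: np.ndarray) -> np.ndarray:
        Xc = self.centering.transform(X)
        if self.osc is not None:
            Xc = apply_osc(self.osc, Xc)
        return Xc

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predictions on the reference scale (dummy-code scale for PLS-DA)."""
        yc_hat = predict_regression(self.model, self._corrected(X))
        intercept = (
            self.centering.y_mean
            if self.kind != "plsda"
            else self.model.extra["dummy_mean"]
        )
        return yc_hat + intercept

    def predict_per_factor(self, X: np.ndarray) -> np.ndarray:
        """n x k matrix: predictions using 1..k factors (nested models)."""
        B = self.model.regression_vectors_nested()
        intercept = (
            self.centering.y_mean
            if self.kind != "plsda"
            else self.model.extra["dummy_mean"]
        )
        return self._corrected(X) @ B + intercept

    def classify(self, X: np.ndarray) -> list[str | None]:
        return classify_plsda(self.model, self._corrected(X))

    @property
    def regression_vector(self) -> np.ndarray:
        return self.model.regression_vector


def fit_calibration(
    X: np.ndarray,
    y,
    kind: str,
    n_factors: int,
    osc_components: int = 0,
) -> FittedCalibration:
    """Fit centering, OSC (``osc_components`` > 0) and the latent model.

    ``y`` is a numeric reference vector for plsr/pcr and a two-class label
    sequence for plsda.
    """
    X = np.asarray(X, dtype=float)
    if kind == "plsda":
        labels = [str(v) for v in y]
        classes = sorted(set(labels))
        if len(classes) != 2:
            raise ValueError(f"PLS-DA needs exactly 2 classes, got {classes}")
        y_num = np.array([float(classes.index(l)) for l in labels])
    elif kind in ("plsr", "pcr"):
        y_num = np.asarray(y, dtype=float)
        labels = None
    else:
        raise ValueError(f"unknown calibration kind {kind!r}")

    centering = fit_centering(X, y_num)
    Xc = centering.transform(X)
    yc = y_num - centering.y_mean
    osc = None
    if osc_components:
        osc = fit_osc(Xc, yc, n_components=osc_components)
        Xc = apply_osc(osc, Xc)
    if kind == "plsr":
        model = fit_plsr(Xc, yc, n_factors)
    elif kind == "pcr":
        model = fit_pcr(Xc, yc, n_factors)
    else:
        model = fit_plsda(Xc, labels, n_factors)
    return FittedCalibration(kind=kind, centering=centering, osc=osc, model=model)
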