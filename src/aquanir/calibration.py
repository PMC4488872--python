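"""Calibration model classes in the model/results idiom.

``PLSRCalibration``, ``PCRCalibration`` and ``PLSDACalibration`` are built
from a :class:`~aquanir.spectra.SpectraSet` plus pretreatment settings;
``fit()`` runs the chain smoothing -> wavelength-range selection ->
(per fit / per CV fold) mean centering -> OSC -> latent model, selects the
factor count by minimum SECV under the n/10 factor cap, and returns a
Results object carrying the metrics block (r Cal, SEC, r Val, SECV), the
regression vector, predictions, peak annotations, a ``summary()`` table
and plotting helpers.
"""

from __future__ import annotations

import json
from typing import Sequence

import numpy as np

from . import validation as val
from .bands import annotate_peaks, default_band_table, detect_peaks
from .core import FittedCalibration, fit_calibration
from .pretreat import smooth_spectra
from .spectra import SpectraSet, select_wavelength_range

__all__ = ["PLSRCalibration", "PCRCalibration", "PLSDACalibration", "CalibrationResults"]


class _BaseCalibration:
    kind: str = ""

    def __init__(
        self,
        spectra: SpectraSet,
        response: str | Sequence,
        *,
        wavelength_range: tuple[float, float] | None = None,
        smoothing_window: int | None = None,
        smoothing_method: str = "moving_average",
        osc_components: int = 1,
    ):
        self.raw_spectra = spectra
        self.wavelength_range = wavelength_range
        self.smoothing_window = smoothing_window
        self.smoothing_method = smoothing_method
        self.osc_components = osc_components

        work = spectra
        if smoothing_window is not None:
            work = smooth_spectra(work, smoothing_window, smoothing_method)
        if wavelength_range is not None:
            work = select_wavelength_range(work, *wavelength_range)
        self.spectra = work
        if isinstance(response, str):
            self.response_name = response
            self._y = (
                work.labels(response) if self.kind == "plsda" else work.response(response)
            )
        else:
            self.response_name = "y"
            self._y = (
                [str(v) for v in response]
                if self.kind == "plsda"
                else np.asarray(response, dtype=float)
            )

    @property
    def endog(self):
        return self._y

    @property
    def exog(self) -> np.ndarray:
        return self.spectra.absorbance

    def fit(
        self,
        n_factors: int | None = None,
        k_max: int | None = None,
        cv: str = "loo",
        groups: Sequence | None = None,
    ) -> "CalibrationResults":
        """Fit the calibration; factor count by minimum SECV unless fixed.

        ``cv`` is ``"loo"``, ``"group"`` (requires ``groups``) or ``"none"``.
        """
        X = self.exog
        n = X.shape[0]
        cap = val.max_factors(n)
        if k_max is None:
            k_max = cap if n_factors is None else n_factors
        k_max = min(k_max, min(n - 2, X.shape[1]))

        cv_matrix = None
        if cv == "loo":
            cv_matrix = val.loo_crossvalidate(
                self.kind, X, self._y, k_max, osc_components=self.osc_components
            )
        elif cv == "group":
            if groups is None:
                groups = [m.batch for m in self.spectra.meta]
            cv_matrix = val.group_holdout_validate(
                self.kind, X, self._y, groups, k_max, osc_components=self.osc_components
            )
        elif cv != "none":
            raise ValueError(f"unknown cv scheme {cv!r}")

        y_num = self._numeric_y()
        per_factor_secv = (
            val.secv_per_factor(y_num, cv_matrix) if cv_matrix is not None else None
        )
        if n_factors is None:
            if per_factor_secv is None:
                raise ValueError("factor selection needs cross-validation")
            n_factors = val.select_factors(per_factor_secv, k_max)
        fitted = fit_calibration(
            X, self._y, self.kind, n_factors, osc_components=self.osc_components
        )
        yhat_cv = cv_matrix[:, n_factors - 1] if cv_matrix is not None else None
        return CalibrationResults(
            model=self,
            fitted=fitted,
            n_factors=n_factors,
            per_factor_secv=per_factor_secv,
            predictions_cv=yhat_cv,
            cv_scheme=cv,
        )

    def _numeric_y(self) -> np.ndarray:
        if self.kind != "plsda":
            return np.asarray(self._y, dtype=float)
        classes = sorted(set(self._y))
        return np.array([float(classes.index(l)) for l in self._y])


class PLSRCalibration(_BaseCalibration):
    """NIPALS PLS1 regression calibration of a spectral data set."""

    kind = "plsr"


class PCRCalibration(_BaseCalibration):
    """Principal component regression calibration."""

    kind = "pcr"


class PLSDACalibration(_BaseCalibration):
    """Two-class PLS discriminant analysis on a {0, 1} dummy response."""

    kind = "plsda"


class CalibrationResults:
    """Fitted calibration with metrics, predictions and annotation."""

    def __init__(
        self,
        model: _BaseCalibration,
        fitted: FittedCalibration,
        n_factors: int,
        per_factor_secv: np.ndarray | None,
        predictions_cv: np.ndarray | None,
        cv_scheme: str,
    ):
        self.model = model
        self.fitted = fitted
        self.n_factors = n_factors
        self.cv_scheme = cv_scheme
        y = model._numeric_y()
        yhat_cal = fitted.predict(model.exog)
        self.metrics = val.calibration_metrics(y, yhat_cal, predictions_cv, n_factors)
        self.metrics.per_factor_secv = per_factor_secv
        self.metrics.metadata.update(
            {
                "kind": model.kind,
                "osc_components": model.osc_components,
                "cv": cv_scheme,
                "smoothing_window": model.smoothing_window,
                "wavelength_range": model.wavelength_range,
            }
        )

    # -- metric accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return self.metrics.n

    @property
    def r_cal(self) -> float:
        return self.metrics.r_cal

    @property
    def sec(self) -> float:
        return self.metrics.sec

    @property
    def r_val(self) -> float:
        return self.metrics.r_val

    @property
    def secv(self) -> float:
        return self.metrics.secv

    @property
    def per_factor_secv(self):
        return self.metrics.per_factor_secv

    @property
    def regression_vector(self) -> np.ndarray:
        return self.fitted.regression_vector

    @property
    def wavelengths(self) -> np.ndarray:
        return self.model.spectra.wavelengths

    # -- prediction -------------------------------------------------------
    def _pretreated(self, spectra: SpectraSet) -> np.ndarray:
        work = spectra
        if self.model.smoothing_window is not None:
            work = smooth_spectra(
                work, self.model.smoothing_window, self.model.smoothing_method
            )
        if self.model.wavelength_range is not None:
            work = select_wavelength_range(work, *self.model.wavelength_range)
        if not np.array_equal(work.wavelengths, self.wavelengths):
            raise ValueError("spectra grid does not match the calibration grid")
        return work.absorbance

    def predict(self, spectra: SpectraSet | np.ndarray) -> np.ndarray:
        X = (
            self._pretreated(spectra)
            if isinstance(spectra, SpectraSet)
            else np.asarray(spectra, dtype=float)
        )
        return self.fitted.predict(X)

    def classify(self, spectra: SpectraSet | np.ndarray) -> list[str | None]:
        if self.model.kind != "plsda":
            raise ValueError("classification is for PLS-DA results")
        X = (
            self._pretreated(spectra)
            if isinstance(spectra, SpectraSet)
            else np.asarray(spectra, dtype=float)
        )
        return self.fitted.classify(X)

    def cv_labels(self) -> list[str | None]:
        """Cross-validated class labels (PLS-DA): dummy-code CV predictions
        thresholded at 0.5; exactly 0.5 is unassigned."""
        if self.model.kind != "plsda":
            raise ValueError("cv_labels is for PLS-DA results")
        if self.metrics.predictions_cv is None:
            raise ValueError("no cross-validation was run")
        classes = sorted(set(self.model._y))
        out = []
        for v in self.metrics.predictions_cv:
            out.append(None if v == 0.5 else (classes[1] if v > 0.5 else classes[0]))
        return out

    def classification_summary(self, cross_validated: bool = True):
        if self.model.kind != "plsda":
            raise ValueError("classification summary is for PLS-DA results")
        labels = (
            self.cv_labels()
            if cross_validated
            else self.fitted.classify(self.model.exog)
        )
        return val.misclassification_summary(self.model._y, labels)

    # -- annotation -------------------------------------------------------
    def peaks(self, min_prominence: float = 0.1):
        return detect_peaks(
            self.regression_vector, self.model.spectra.grid, min_prominence
        )

    def annotated_peaks(self, min_prominence: float = 0.1, band_table=None):
        return annotate_peaks(self.peaks(min_prominence), band_table)

    # -- reporting --------------------------------------------------------
    def summary(self) -> str:
        m = self.metrics
        lines = [
            f"{self.model.kind.upper()} calibration for {self.model.response_name}",
            "=" * 48,
            f"N                 {m.n}",
            f"Factor #          {m.n_factors}",
            f"OSC components    {self.model.osc_components}",
            f"validation        {self.cv_scheme}",
            f"r Cal             {m.r_cal:.4f}",
            f"SEC               {m.sec:.4f}",
        ]
        if m.predictions_cv is not None:
            lines += [f"r Val             {m.r_val:.4f}", f"SECV              {m.secv:.4f}"]
        if self.model.kind == "plsda" and m.predictions_cv is not None:
            summ = self.classification_summary()
            lines.append(f"correctly classified (CV)  {100 * summ.ratio_correct:.1f}%")
        anns = self.annotated_peaks()
        if anns:
            tops = sorted(anns, key=lambda a: -a.peak.prominence)[:6]
            lines.append("regression-vector peaks (by prominence):")
            for a in tops:
                bands = ",".join(a.bands) if a.bands else "-"
                lines.append(
                    f"  {a.peak.wavelength:8.1f} nm  {a.peak.sign:8s}  bands: {bands}"
                )
        return "\n".join(lines)

    def to_json(self) -> str:
        """Versioned JSON document from which the calibration can be
        re-applied bit-identically."""
        fitted = self.fitted
        doc = {
            "format": "aquanir-calibration",
            "version": 1,
            "kind": self.model.kind,
            "n_factors": self.n_factors,
            "wavelengths": self.wavelengths.tolist(),
            "pretreatment": {
                "smoothing_window": self.model.smoothing_window,
                "smoothing_method": self.model.smoothing_method,
                "wavelength_range": self.model.wavelength_range,
                "osc_components": self.model.osc_components,
            },
            "centering_mean": fitted.centering.mean_vector.tolist(),
            "y_mean": fitted.centering.y_mean,
            "osc": None
            if fitted.osc is None
            else {
                "algorithm": fitted.osc.algorithm,
                "weights": [w.tolist() for w in fitted.osc.weight_vectors],
                "loadings": [p.tolist() for p in fitted.osc.loading_vectors],
            },
            "regression_vector": fitted.regression_vector.tolist(),
            "extra": {
                k: v
                for k, v in fitted.model.extra.items()
                if isinstance(v, (str, int, float, list))
            },
            "metrics": self.metrics.to_dict(),
        }
        return json.dumps(doc, sort_keys=True)

    # -- plotting ---------------------------------------------------------
    def plot_yfit(self, ax=None):
        """Reference vs cross-validated predictions scatter (Y-fit)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        y = self.model._numeric_y()
        ax.scatter(y, self.metrics.predictions_cal, s=18, label="calibration")
        if self.metrics.predictions_cv is not None:
            ax.scatter(
                y, self.metrics.predictions_cv, s=18, marker="x", label="cross-validation"
            )
        lims = [min(y.min(), 0), y.max() * 1.05 if y.max() > 0 else 1]
        ax.plot(lims, lims, lw=0.8, color="grey")
        ax.set_xlabel(f"reference {self.model.response_name}")
        ax.set_ylabel("predicted")
        ax.legend()
        return ax

    def plot_regression_vector(self, ax=None, band_table=None):
        """Regression vector vs wavelength with water-band overlays."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.wavelengths, self.regression_vector, lw=1.0)
        table = band_table if band_table is not None else default_band_table()
        for b in table:
            if b.lo >= self.wavelengths[0] and b.hi <= self.wavelengths[-1]:
                ax.axvspan(b.lo, b.hi, alpha=0.08)
        ax.set_xlabel("wavelength (nm)")
        ax.set_ylabel("regression coefficient")
        return ax
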