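"""Cross-validation, factor selection and calibration/classification metrics.

Conventions:

* the factor cap is one-tenth of the sample count (``max_factors``), the
  standard guard against overfitting small NIR calibration sets;
* SEC uses n - k - 1 degrees of freedom (the intercept absorbed by mean
  centering costs one), SECV uses n;
* leave-one-out refits the FULL chain (centering, OSC, model) on every
  fold, so the y-aware OSC step never sees the held-out sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import fit_calibration

__all__ = [
    "CalibrationResult",
    "ClassificationSummary",
    "max_factors",
    "loo_crossvalidate",
    "group_holdout_validate",
    "calibration_metrics",
    "select_factors",
    "misclassification_summary",
]


@dataclass
class CalibrationResult:
    """The metrics block a calibration report prints: N, Factor #, r Cal,
    SEC, r Val, SECV, plus the per-sample fitted and CV predictions."""

    n: int
    n_factors: int
    r_cal: float
    sec: float
    r_val: float
    secv: float
    predictions_cal: np.ndarray
    predictions_cv: np.ndarray | None = None
    per_factor_secv: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def _opt(v):
            return None if v is None or np.isnan(v) else float(v)

        d = {
            "n": self.n,
            "n_factors": self.n_factors,
            "r_cal": self.r_cal,
            "sec": self.sec,
            "r_val": _opt(self.r_val),
            "secv": _opt(self.secv),
            "predictions_cal": self.predictions_cal.tolist(),
        }
        if self.predictions_cv is not None:
            d["predictions_cv"] = self.predictions_cv.tolist()
        if self.per_factor_secv is not None:
            d["per_factor_secv"] = self.per_factor_secv.tolist()
        d["metadata"] = self.metadata
        return d


@dataclass
class ClassificationSummary:
    """Confusion counts plus the strict ratio of correctly classified
    samples (multi-accepted and unaccepted samples count as incorrect)."""

    n: int
    ratio_correct: float
    confusion: dict[str, dict[str, int]]
    n_unassigned: int = 0
    n_multi_assigned: int = 0

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "ratio_correct": self.ratio_correct,
            "confusion": self.confusion,
            "n_unassigned": self.n_unassigned,
            "n_multi_assigned": self.n_multi_assigned,
        }


def max_factors(n: int) -> int:
    """Factor cap: floor(n/10), at least 1."""
    return max(1, n // 10)


def _cv_predictions(
    fit_kind: str,
    X: np.ndarray,
    y,
    k_max: int,
    osc_components: int,
    fold_indices: list[np.ndarray],
) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    preds = np.full((n, k_max), np.nan)
    for held in fold_indices:
        keep = np.setdiff1d(np.arange(n), held)
        y_train = (
            [y[i] for i in keep] if fit_kind == "plsda" else np.asarray(y)[keep]
        )
        fit = fit_calibration(
            X[keep], y_train, fit_kind, k_max, osc_components=osc_components
        )
        preds[held] = fit.predict_per_factor(X[held])
    return preds


def loo_crossvalidate(
    fit_kind: str,
    X: np.ndarray,
    y,
    k_max: int,
    osc_components: int = 0,
) -> np.ndarray:
    """Leave-one-out CV predictions, one column per factor count 1..k_max.

    Every fold refits centering, OSC and the model from scratch on the
    remaining n-1 samples.  Returns an (n, k_max) array; for plsda the
    values are on the dummy-code scale.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError(f"LOO cross-validation needs n >= 3, got {n}")
    if k_max < 1 or k_max > min(n - 2, X.shape[1]):
        raise ValueError(
            f"k_max={k_max} infeasible for folds of n-1={n - 1} samples"
        )
    folds = [np.array([i]) for i in range(n)]
    return _cv_predictions(fit_kind, X, y, k_max, osc_components, folds)


def group_holdout_validate(
    fit_kind: str,
    X: np.ndarray,
    y,
    groups,
    k_max: int,
    osc_components: int = 0,
) -> np.ndarray:
    """Leave-one-group-out CV (groups = batches or class labels).

    With one group per sample this reduces exactly to leave-one-out.
    """
    groups = np.asarray([str(g) for g in groups])
    uniq = list(dict.fromkeys(groups))
    if len(uniq) < 2:
        raise ValueError("group hold-out needs at least 2 groups")
    folds = [np.flatnonzero(groups == g) for g in uniq]
    return _cv_predictions(fit_kind, np.asarray(X, float), y, k_max, osc_components, folds)


def calibration_metrics(
    y: np.ndarray,
    yhat_cal: np.ndarray,
    yhat_cv: np.ndarray | None,
    k: int,
) -> CalibrationResult:
    """r Cal / SEC and (if CV predictions given) r Val / SECV.

    SEC = sqrt(RSS_cal / (n - k - 1)); SECV = sqrt(RSS_cv / n).
    """
    y = np.asarray(y, dtype=float)
    yhat_cal = np.asarray(yhat_cal, dtype=float)
    n = y.size
    if yhat_cal.size != n or (yhat_cv is not None and len(yhat_cv) != n):
        raise ValueError("y and predictions must have equal length")
    if n <= k + 1:
        raise ValueError(f"need n > k+1 (n={n}, k={k})")
    if np.var(y) == 0:
        raise ValueError("reference values have zero variance; r undefined")

    def _r(a, b):
        if np.var(b) == 0:
            return 0.0
        return float(stats.pearsonr(a, b)[0])

    sec = float(np.sqrt(np.sum((y - yhat_cal) ** 2) / (n - k - 1)))
    r_cal = _r(y, yhat_cal)
    r_val, secv, cv = np.nan, np.nan, None
    if yhat_cv is not None:
        cv = np.asarray(yhat_cv, dtype=float)
        secv = float(np.sqrt(np.sum((y - cv) ** 2) / n))
        r_val = _r(y, cv)
    return CalibrationResult(
        n=n,
        n_factors=k,
        r_cal=r_cal,
        sec=sec,
        r_val=r_val,
        secv=secv,
        predictions_cal=yhat_cal,
        predictions_cv=cv,
        metadata={"sec_df": "n-k-1", "secv_df": "n"},
    )


def secv_per_factor(y: np.ndarray, cv_predictions: np.ndarray) -> np.ndarray:
    """SECV for each factor count from an (n, k_max) CV prediction array."""
    y = np.asarray(y, dtype=float)[:, None]
    return np.sqrt(np.mean((y - cv_predictions) ** 2, axis=0))


def select_factors(per_factor_secv: np.ndarray, k_max: int | None = None) -> int:
    """Optimum factor count: argmin SECV over 1..k_max, smallest k on ties."""
    v = np.asarray(per_factor_secv, dtype=float)
    if v.size == 0:
        raise ValueError("empty SECV vector")
    if k_max is not None:
        v = v[:k_max]
    return int(np.argmin(v)) + 1


def misclassification_summary(true_labels, predicted) -> ClassificationSummary:
    """Strict correct-classification ratio.

    ``predicted`` entries may be a single label, ``None`` (unassigned) or a
    set/list of accepted classes (SIMCA); a sample is correct only when it
    is accepted by its true class and no other.
    """
    true_labels = [str(t) for t in true_labels]
    if len(true_labels) != len(predicted):
        raise ValueError("label vectors differ in length")
    n = len(true_labels)
    confusion: dict[str, dict[str, int]] = {}
    n_unassigned = n_multi = n_correct = 0
    for t, p in zip(true_labels, predicted):
        row = confusion.setdefault(t, {})
        if isinstance(p, (set, frozenset, list, tuple)):
            accepted = [str(a) for a in p]
            if len(accepted) == 0:
                n_unassigned += 1
                row["<none>"] = row.get("<none>", 0) + 1
            elif len(accepted) > 1:
                n_multi += 1
                row["<multiple>"] = row.get("<multiple>", 0) + 1
            else:
                row[accepted[0]] = row.get(accepted[0], 0) + 1
                if accepted[0] == t:
                    n_correct += 1
        elif p is None:
            n_unassigned += 1
            row["<none>"] = row.get("<none>", 0) + 1
        else:
            p = str(p)
            row[p] = row.get(p, 0) + 1
            if p == t:
                n_correct += 1
    return ClassificationSummary(
        n=n,
        ratio_correct=n_correct / n if n else 0.0,
        confusion=confusion,
        n_unassigned=n_unassigned,
        n_multi_assigned=n_multi,
    )
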