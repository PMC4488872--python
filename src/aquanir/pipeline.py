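"""Config-driven experiment orchestration.

An experiment is a YAML-serialisable mapping: an input (a spectra table on
disk, or a synthetic-data recipe), a wavelength range, pretreatment
settings, a task (regression or discrimination) with its model menu, and
validation settings.  ``run_experiment`` executes the standard chain
smoothing -> range selection -> (centering -> OSC -> model, refit inside
every CV fold) -> metrics -> peak annotation and returns a JSON-ready
report; rerunning the same config reproduces the report byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field
from typing import Any

import numpy as np
import yaml

from .calibration import PCRCalibration, PLSDACalibration, PLSRCalibration
from .bands import annotate_peaks, default_band_table, detect_peaks
from .simca import SIMCA
from .simulate import SyntheticConfig, simulate_dataset
from .spectra import SpectraSet, read_spectra_table, write_spectra_table

__all__ = ["ExperimentConfig", "run_experiment", "write_report", "build_synthetic_config"]

REPORT_FORMAT_VERSION = 1

_TASK_MODELS = {
    "regression": {"plsr", "pcr"},
    "discrimination": {"plsda", "simca"},
}


@dataclass
class ExperimentConfig:
    """Declarative description of one analysis run."""

    task: str  # regression | discrimination
    models: list[str] = field(default_factory=lambda: ["plsr"])
    seed: int = 0
    spectra_path: str | None = None
    synthetic: dict[str, Any] | None = None
    wavelength_range: tuple[float, float] | None = (1300.0, 1600.0)
    smoothing_window: int | None = 21
    smoothing_method: str = "moving_average"
    osc_components: int = 1
    response: str = "tt_conc"
    label_column: str = "class_label"
    validation: str = "loo"
    n_factors: int | None = None
    max_factors: int | None = None
    simca_factors: int = 2
    simca_quantile: float = 0.95
    min_prominence: float = 0.1

    def __post_init__(self):
        if self.task not in _TASK_MODELS:
            raise ValueError(f"unknown task {self.task!r}")
        bad = set(self.models) - _TASK_MODELS[self.task]
        if bad:
            raise ValueError(
                f"model(s) {sorted(bad)} incompatible with task {self.task!r}"
            )
        if self.spectra_path is None and self.synthetic is None:
            raise ValueError("config needs either spectra_path or a synthetic recipe")

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "wavelength_range" in d and d["wavelength_range"] is not None:
            d["wavelength_range"] = tuple(d["wavelength_range"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def canonical_json(self) -> str:
        d = asdict(self)
        if d.get("wavelength_range") is not None:
            d["wavelength_range"] = list(d["wavelength_range"])
        return json.dumps(d, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


def build_synthetic_config(recipe: dict, seed: int) -> SyntheticConfig:
    """Turn the YAML ``synthetic`` recipe into a SyntheticConfig."""
    recipe = dict(recipe or {})
    kind = recipe.pop("layout", "factorial")
    recipe.setdefault("seed", seed)
    if kind == "dose_series":
        return SyntheticConfig.dose_series(**recipe)
    if kind == "two_class":
        return SyntheticConfig.two_class(**recipe)
    if kind == "factorial":
        if "design" in recipe:
            recipe["design"] = tuple(tuple(cell) for cell in recipe["design"])
        return SyntheticConfig(**recipe)
    raise ValueError(f"unknown synthetic layout {kind!r}")


def _load_spectra(config: ExperimentConfig) -> SpectraSet:
    if config.spectra_path is not None:
        return read_spectra_table(config.spectra_path)
    spectra, _ = simulate_dataset(build_synthetic_config(config.synthetic, config.seed))
    return spectra


def _round_floats(obj, ndigits=12):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def _annotation_block(vector, grid, min_prominence):
    peaks = detect_peaks(np.asarray(vector), grid, min_prominence)
    anns = annotate_peaks(peaks, default_band_table())
    return [
        {
            "wavelength": a.peak.wavelength,
            "amplitude": a.peak.amplitude,
            "prominence": a.peak.prominence,
            "sign": a.peak.sign,
            "bands": list(a.bands),
        }
        for a in anns
    ]


def run_experiment(config: ExperimentConfig) -> dict:
    """Execute one configured analysis and return the report mapping."""
    try:
        spectra = _load_spectra(config)
    except Exception as exc:
        raise RuntimeError(f"[input] {exc}") from exc

    report: dict[str, Any] = {
        "format": "aquanir-report",
        "version": REPORT_FORMAT_VERSION,
        "provenance": {
            "config": json.loads(config.canonical_json()),
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "flags": {
                "interclass_distance": "sqrt ratio, null value 1",
                "simca_acceptance": "residual F-test, no leverage limit",
                "sec_df": "n-k-1",
                "secv_df": "n",
            },
        },
        "models": {},
    }

    kw = dict(
        wavelength_range=config.wavelength_range,
        smoothing_window=config.smoothing_window,
        smoothing_method=config.smoothing_method,
        osc_components=config.osc_components,
    )
    cls_of = {"plsr": PLSRCalibration, "pcr": PCRCalibration, "plsda": PLSDACalibration}

    for kind in config.models:
        try:
            if kind == "simca":
                # class modeling runs without OSC, per-class centering only
                from .pretreat import smooth_spectra
                from .spectra import select_wavelength_range

                work = spectra
                if config.smoothing_window is not None:
                    work = smooth_spectra(
                        work, config.smoothing_window, config.smoothing_method
                    )
                if config.wavelength_range is not None:
                    work = select_wavelength_range(work, *config.wavelength_range)
                res = SIMCA(
                    work,
                    label_column=config.label_column,
                    n_factors=config.simca_factors,
                    critical_quantile=config.simca_quantile,
                ).fit()
                summ = res.classification_summary()
                dp = res.discriminating_power()
                report["models"]["simca"] = {
                    "classification": summ.to_dict(),
                    "interclass_distance": res.interclass_distance.tolist(),
                    "class_labels": res.model.class_labels,
                    "n_factors": res.model.class_factors,
                    "discriminating_power": dp.tolist(),
                    "dp_annotations": _annotation_block(
                        dp - 1.0, work.grid, config.min_prominence
                    ),
                }
                continue

            model = cls_of[kind](
                spectra,
                config.response if kind != "plsda" else config.label_column,
                **kw,
            )
            fit_res = model.fit(
                n_factors=config.n_factors,
                k_max=config.max_factors,
                cv=config.validation,
            )
            block = {
                "metrics": fit_res.metrics.to_dict(),
                "regression_vector": fit_res.regression_vector.tolist(),
                "wavelengths": fit_res.wavelengths.tolist(),
                "annotations": _annotation_block(
                    fit_res.regression_vector,
                    fit_res.model.spectra.grid,
                    config.min_prominence,
                ),
            }
            if kind == "plsda":
                block["classification"] = fit_res.classification_summary().to_dict()
            report["models"][kind] = block
        except Exception as exc:
            raise RuntimeError(f"[{kind}] {exc}") from exc

    return _round_floats(report)


def report_table(report: dict) -> str:
    """Plain-text table mirroring the calibration summary layout
    (N, Model, Factor #, r Cal, SEC, r Val, SECV)."""
    lines = [
        f"{'Model':8s} {'N':>4s} {'Factor #':>8s} {'r Cal':>8s} {'SEC':>9s} "
        f"{'r Val':>8s} {'SECV':>9s}"
    ]
    for kind, block in report["models"].items():
        if "metrics" not in block:
            cls = block["classification"]
            lines.append(
                f"{kind:8s} {cls['n']:>4d} {'-':>8s}  ratio correct = "
                f"{cls['ratio_correct']:.4f}"
            )
            continue
        m = block["metrics"]
        r_val = m.get("r_val")
        secv = m.get("secv")
        lines.append(
            f"{kind:8s} {m['n']:>4d} {m['n_factors']:>8d} {m['r_cal']:>8.4f} "
            f"{m['sec']:>9.4f} "
            + (f"{r_val:>8.4f} {secv:>9.4f}" if r_val is not None else f"{'-':>8s} {'-':>9s}")
        )
    return "\n".join(lines) + "\n"


def write_report(report: dict, out_dir: str) -> tuple[str, str]:
    """Atomically write report.json and report.txt; returns their paths."""
    os.makedirs(out_dir, exist_ok=True)
    json_path = os.path.join(out_dir, "report.json")
    txt_path = os.path.join(out_dir, "report.txt")
    payload = json.dumps(report, sort_keys=True, indent=1)
    table = report_table(report)
    for path, content in ((json_path, payload), (txt_path, table)):
        tmp = path + ".tmp"
        with open(tmp, "w") as fh:
            fh.write(content)
        os.replace(tmp, path)
    return json_path, txt_path


def write_synthetic(recipe: dict, seed: int, out_dir: str) -> tuple[str, str]:
    """Simulate a dataset and write spectra.csv + references.csv."""
    cfg = build_synthetic_config(recipe, seed)
    spectra, refs = simulate_dataset(cfg)
    os.makedirs(out_dir, exist_ok=True)
    spath = os.path.join(out_dir, "spectra.csv")
    rpath = os.path.join(out_dir, "references.csv")
    write_spectra_table(spectra, spath)
    refs.to_csv(rpath, index=False)
    return spath, rpath
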