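"""Seeded generator of NIR-like spectra of aqueous DNA solutions.

The generator emulates the statistical structure the analysis assumes: a
fixed water-dominated absorbance baseline over the first-overtone region,
solute- and photoproduct-dependent Gaussian perturbations localised at
named water bands, a dose-linear thymine-dimer yield, instrument noise,
per-sample baseline drift (offset + slope), and a y-independent spectral
confounder.  Every magnitude is a configurable default, not a physical
claim; the signs follow the aquaphotomics picture in which dissolved DNA
depletes strongly hydrogen-bonded water (S4, band C11) in favour of free
water (S0, band C5) while dimer formation does the reverse.

Random draws come from one ``numpy.random.default_rng(seed)`` stream in a
fixed documented order: first one truncated-Gaussian dimer-yield deviate
per sample, then per sample a drift offset, a drift slope, a confounder
amplitude and the per-wavelength noise vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bands import WaterBand, default_band_table
from .spectra import SampleMeta, SpectraSet, WavelengthGrid, make_grid

__all__ = [
    "SyntheticConfig",
    "water_baseline",
    "band_profile",
    "default_confounder_shape",
    "simulate_dose_response",
    "simulate_dataset",
]

#: factorial design mirroring the study layout: DNA 5-20 uM, UVC 0-20 kJ/m^2
DEFAULT_DESIGN = tuple(
    (dna, dose) for dna in (5.0, 10.0, 15.0, 20.0) for dose in (0.0, 5.0, 10.0, 15.0, 20.0)
)

#: signed band effects (AU per uM of the driver): DNA depletes S4/C11 water
#: and frees S0/C5 water; cyclobutane-dimer formation does the reverse.
DEFAULT_BAND_EFFECTS = {
    "dna_conc": {"C5": 2e-4, "C11": -2e-4},
    "tt_conc": {"C5": -4e-3, "C11": 4e-3},
}


@dataclass
class SyntheticConfig:
    """Generative parameters for spectra and reference values.

    Units: wavelengths nm, absorbance AU, DNA and dimer concentrations uM,
    UVC dose kJ/m^2.  ``dimer_yield`` is uM of cis-syn T<>T per
    (kJ/m^2 x uM DNA); with the defaults a 20 uM solution at 20 kJ/m^2
    carries 3 uM of dimer, matching the worked concentration range.
    """

    seed: int = 0
    grid: WavelengthGrid = field(default_factory=lambda: make_grid(1100.0, 1850.0, 0.5))
    n_per_group: int = 2
    design: tuple[tuple[float, float], ...] = DEFAULT_DESIGN
    band_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_BAND_EFFECTS.items()}
    )
    dimer_yield: float = 0.0075
    dimer_noise_sd: float = 0.25
    noise_sd: float = 1e-4
    baseline_offset_sd: float = 5e-4
    baseline_slope_sd: float = 2e-6
    confounder_amplitude_sd: float = 5e-4
    confounder_shape: np.ndarray | None = None
    n_batches: int = 8
    band_table: tuple[WaterBand, ...] = field(
        default_factory=lambda: tuple(default_band_table())
    )

    def __post_init__(self):
        for name in (
            "dimer_noise_sd",
            "noise_sd",
            "baseline_offset_sd",
            "baseline_slope_sd",
            "confounder_amplitude_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        names = {b.name for b in self.band_table}
        for driver, effects in self.band_effects.items():
            if driver not in ("dna_conc", "tt_conc"):
                raise ValueError(f"unknown effect driver {driver!r}")
            unknown = set(effects) - names
            if unknown:
                raise ValueError(f"unknown band name(s) in band_effects: {sorted(unknown)}")

    @property
    def n_samples(self) -> int:
        return len(self.design) * self.n_per_group

    @classmethod
    def dose_series(
        cls, seed: int, dna_conc: float = 20.0, n_per_group: int = 8, **kw
    ) -> "SyntheticConfig":
        """Single-concentration UVC dose series (0-20 kJ/m^2), the layout
        of the dose and dimer-concentration calibrations."""
        design = tuple((dna_conc, dose) for dose in (0.0, 5.0, 10.0, 15.0, 20.0))
        return cls(seed=seed, design=design, n_per_group=n_per_group, **kw)

    @classmethod
    def two_class(
        cls,
        seed: int,
        dna_conc: float = 20.0,
        dose: float = 20.0,
        n_per_group: int = 16,
        **kw,
    ) -> "SyntheticConfig":
        """Irradiated-vs-nonirradiated design at one DNA concentration."""
        design = ((dna_conc, 0.0), (dna_conc, dose))
        return cls(seed=seed, design=design, n_per_group=n_per_group, **kw)

    def with_(self, **kw) -> "SyntheticConfig":
        return replace(self, **kw)


def water_baseline(grid: WavelengthGrid) -> np.ndarray:
    """Deterministic pseudo-water absorbance over the first-overtone region.

    One broad Gaussian band (center 1450 nm, amplitude 1.0 AU, sd 60 nm)
    plus twelve resolvable sub-bands of amplitude 0.05 AU and sd 4 nm at
    the C1-C12 band midpoints (the midpoints are 10-24 nm apart; wider
    sub-bands would merge into single maxima).  No randomness.
    """
    wl = grid.values
    if wl[0] < 1000.0 or wl[-1] > 2000.0:
        raise ValueError(
            f"grid [{wl[0]}, {wl[-1]}] nm outside the supported 1000-2000 nm window"
        )
    v = 1.0 * np.exp(-((wl - 1450.0) ** 2) / (2 * 60.0**2))
    for band in default_band_table():
        if band.name.startswith("C"):
            v += 0.05 * np.exp(-((wl - band.midpoint) ** 2) / (2 * 4.0**2))
    return v


def band_profile(band: WaterBand, grid: WavelengthGrid) -> np.ndarray:
    """Unit-amplitude Gaussian at the band midpoint, sd = half-width / 2."""
    sd = (band.hi - band.lo) / 4.0
    return np.exp(-((grid.values - band.midpoint) ** 2) / (2 * sd**2))


def default_confounder_shape(grid: WavelengthGrid) -> np.ndarray:
    """Fixed broad differential shape (max |value| 1) used when the config
    gives none; deliberately distinct from the C5/C11 effect pattern."""
    wl = grid.values
    v = np.exp(-((wl - 1380.0) ** 2) / (2 * 50.0**2)) - np.exp(
        -((wl - 1520.0) ** 2) / (2 * 50.0**2)
    )
    return v / np.max(np.abs(v))


def _reference_records(config: SyntheticConfig, rng: np.random.Generator):
    records = []
    i = 0
    for dna, dose in config.design:
        for _ in range(config.n_per_group):
            noise = rng.normal(0.0, config.dimer_noise_sd) if config.dimer_noise_sd else 0.0
            tt = max(0.0, config.dimer_yield * dose * dna + noise)
            records.append(
                {
                    "sample_id": f"S{i:03d}",
                    "dna_conc": dna,
                    "uvc_dose": dose,
                    "tt_conc": tt,
                    "batch": f"B{i % config.n_batches + 1}",
                    "class_label": "irradiated" if dose > 0 else "nonirradiated",
                }
            )
            i += 1
    return records


def simulate_dose_response(config: SyntheticConfig) -> pd.DataFrame:
    """Reference table only: dose-linear dimer yield with truncated-at-zero
    Gaussian noise, emulating an HPLC dose-response determination."""
    rng = np.random.default_rng(config.seed)
    return pd.DataFrame(_reference_records(config, rng))


def simulate_dataset(config: SyntheticConfig) -> tuple[SpectraSet, pd.DataFrame]:
    """Spectra + reference table with the full generative structure.

    Per sample: baseline + DNA- and dimer-driven band perturbations +
    drift offset + drift slope x (lambda - midrange) + confounder +
    white noise.  Bit-reproducible for a fixed config.
    """
    rng = np.random.default_rng(config.seed)
    records = _reference_records(config, rng)
    grid = config.grid
    wl = grid.values
    lam_mid = 0.5 * (wl[0] + wl[-1])
    baseline = water_baseline(grid)
    shape = (
        np.asarray(config.confounder_shape, dtype=float)
        if config.confounder_shape is not None
        else default_confounder_shape(grid)
    )
    if shape.size != len(grid):
        raise ValueError("confounder_shape length must match the grid")
    band_of = {b.name: b for b in config.band_table}
    profiles = {
        driver: sum(
            coeff * band_profile(band_of[name], grid)
            for name, coeff in effects.items()
        )
        for driver, effects in config.band_effects.items()
    }

    n = len(records)
    A = np.empty((n, len(grid)))
    confounder_scores = np.empty(n)
    for i, rec in enumerate(records):
        # documented draw order: offset, slope, confounder amplitude, noise
        offset = rng.normal(0.0, config.baseline_offset_sd) if config.baseline_offset_sd else 0.0
        slope = rng.normal(0.0, config.baseline_slope_sd) if config.baseline_slope_sd else 0.0
        amp = (
            rng.normal(0.0, config.confounder_amplitude_sd)
            if config.confounder_amplitude_sd
            else 0.0
        )
        noise = rng.normal(0.0, config.noise_sd, len(grid)) if config.noise_sd else 0.0
        spectrum = baseline.copy()
        for driver, profile in profiles.items():
            if not np.isscalar(profile):
                spectrum = spectrum + rec[driver] * profile
        spectrum = spectrum + offset + slope * (wl - lam_mid) + amp * shape + noise
        A[i] = spectrum
        confounder_scores[i] = amp

    refs = pd.DataFrame(records)
    refs["confounder_score"] = confounder_scores
    meta = [
        SampleMeta(
            sample_id=r["sample_id"],
            class_label=r["class_label"],
            dna_conc=r["dna_conc"],
            uvc_dose=r["uvc_dose"],
            tt_conc=r["tt_conc"],
            batch=r["batch"],
        )
        for r in records
    ]
    return SpectraSet(A, grid, meta), refs
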