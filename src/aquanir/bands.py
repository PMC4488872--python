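"""Aquaphotomics water-absorbance bands and peak annotation.

The first overtone of water (1300-1600 nm) is subdivided into the
characteristic bands C1-C12 plus three auxiliary bands W1-W3.  The "S"
assignments count hydrogen bonds per water molecule: S0 is free water
(1398-1418 nm) through S4, water with four hydrogen bonds (1482-1495 nm).
Regression vectors and SIMCA discriminating-power curves are read by
locating their signed peaks and mapping each onto every band whose closed
nm range contains it (bands overlap, so a peak may carry several names).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .spectra import WavelengthGrid

__all__ = [
    "WaterBand",
    "Peak",
    "PeakAnnotation",
    "default_band_table",
    "load_band_table",
    "write_band_table",
    "detect_peaks",
    "annotate_peaks",
]


@dataclass(frozen=True)
class WaterBand:
    name: str
    lo: float  # nm
    hi: float  # nm
    assignment: str

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ValueError(f"band {self.name}: need lo < hi, got {self.lo}, {self.hi}")

    def __contains__(self, wavelength: float) -> bool:
        return self.lo <= wavelength <= self.hi

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lo + self.hi)


@dataclass(frozen=True)
class Peak:
    wavelength: float
    amplitude: float
    prominence: float
    sign: str  # "positive" | "negative"


@dataclass(frozen=True)
class PeakAnnotation:
    peak: Peak
    bands: tuple[str, ...]


_DEFAULT_BANDS = (
    ("C1", 1336.0, 1348.0, "nu3, H2O asymmetric stretching vibration"),
    ("C2", 1360.0, 1366.0, "water solvation shell, OH-(H2O)1,2,4"),
    (
        "C3",
        1370.0,
        1376.0,
        "nu1 + nu3, symmetrical stretching fundamental vibration and "
        "H2O asymmetric stretching vibration",
    ),
    (
        "C4",
        1380.0,
        1388.0,
        "water solvation shell, OH-(H2O)1,4 and superoxide, O2-(H2O)4",
    ),
    ("C5", 1398.0, 1418.0, "S0, free water and free OH-"),
    ("C6", 1421.0, 1430.0, "H-OH bend and O...O"),
    ("C7", 1432.0, 1444.0, "S1"),
    ("C8", 1448.0, 1454.0, "water solvation shell, OH-(H2O)4,5"),
    ("C9", 1458.0, 1468.0, "S2"),
    ("C10", 1472.0, 1482.0, "S3"),
    ("C11", 1482.0, 1495.0, "S4"),
    (
        "C12",
        1506.0,
        1516.0,
        "nu1, nu2, symmetrical stretching fundamental vibration, and "
        "doubly degenerate bending fundamental",
    ),
    ("W1", 1342.0, 1360.0, "H15O7, H13O6, H11O5 + free OH stretch"),
    ("W2", 1536.0, 1546.0, "H2O intermolecular bend angling"),
    ("W3", 1565.0, 1586.0, "H15O7 + H-bonded OH stretch"),
)


def default_band_table() -> list[WaterBand]:
    """The 15 first-overtone water bands C1-C12 and W1-W3."""
    return [WaterBand(*row) for row in _DEFAULT_BANDS]


def band_by_name(name: str, table: list[WaterBand] | None = None) -> WaterBand:
    table = table if table is not None else default_band_table()
    for b in table:
        if b.name == name:
            return b
    raise KeyError(f"no band named {name!r}")


def load_band_table(path, delimiter: str = ",") -> list[WaterBand]:
    """Read a 4-column (name, lo_nm, hi_nm, assignment) band table."""
    bands = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter=delimiter):
            if not row or row[0].startswith("#") or row[0] == "name":
                continue
            bands.append(WaterBand(row[0], float(row[1]), float(row[2]), row[3]))
    names = [b.name for b in bands]
    if len(set(names)) != len(names):
        raise ValueError("band names must be unique")
    return bands


def write_band_table(bands: list[WaterBand], path, delimiter: str = ",") -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(["name", "lo_nm", "hi_nm", "assignment"])
        for b in bands:
            w.writerow([b.name, b.lo, b.hi, b.assignment])


def detect_peaks(
    vector: np.ndarray,
    grid: WavelengthGrid,
    min_prominence: float = 0.1,
    smoothing_window: int | None = None,
) -> list[Peak]:
    """Signed local extrema of a per-wavelength vector.

    Maxima of the vector and of its negation are kept when their prominence
    reaches ``min_prominence`` times the vector's maximum absolute value;
    the result is sorted by wavelength.
    """
    v = np.asarray(vector, dtype=float)
    if v.size != len(grid):
        raise ValueError(f"vector length {v.size} != grid length {len(grid)}")
    if not 0 < min_prominence <= 1:
        raise ValueError("min_prominence must be in (0, 1]")
    if smoothing_window is not None:
        half = smoothing_window // 2
        padded = np.pad(v, half, mode="symmetric")
        v = np.convolve(padded, np.full(smoothing_window, 1 / smoothing_window), "valid")
    scale = float(np.max(np.abs(v)))
    if scale == 0:
        return []
    thr = min_prominence * scale
    peaks: list[Peak] = []
    for sign, vv in (("positive", v), ("negative", -v)):
        idx, props = find_peaks(vv, prominence=thr)
        for i, prom in zip(idx, props["prominences"]):
            peaks.append(
                Peak(
                    wavelength=float(grid.values[i]),
                    amplitude=float(vector[i]),
                    prominence=float(prom),
                    sign=sign,
                )
            )
    peaks.sort(key=lambda p: p.wavelength)
    return peaks


def annotate_peaks(
    peaks: list[Peak], band_table: list[WaterBand] | None = None
) -> list[PeakAnnotation]:
    """Map each peak onto every band whose closed [lo, hi] contains it."""
    table = band_table if band_table is not None else default_band_table()
    return [
        PeakAnnotation(
            peak=p, bands=tuple(b.name for b in table if p.wavelength in b)
        )
        for p in peaks
    ]
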