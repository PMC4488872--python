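"""Containers and I/O for sample x wavelength absorbance data.

Spectra are stored as plain ``log(1/T)`` absorbance matrices on a regular
wavelength grid (nm), with per-sample metadata (class label, DNA
concentration in uM, UVC dose in kJ/m^2, thymine-dimer concentration in uM,
batch id).  The on-disk format is delimited text: named metadata columns
first, then one numeric column per wavelength.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WavelengthGrid",
    "SampleMeta",
    "SpectraSet",
    "GridError",
    "SpectraParseError",
    "read_spectra_table",
    "write_spectra_table",
    "select_wavelength_range",
]

#: metadata column names recognised in spectra tables, in canonical order
META_FIELDS = ("sample_id", "class_label", "dna_conc", "uvc_dose", "tt_conc", "batch")

_GRID_SPACING_ATOL = 1e-9


class GridError(ValueError):
    """Wavelength header is non-monotone, irregular, or out of range."""


class SpectraParseError(ValueError):
    """A cell of a spectra table could not be parsed."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing, regularly spaced wavelengths in nm."""

    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 1:
            raise GridError("wavelength grid must be a non-empty 1-D array")
        if np.any(values <= 0):
            raise GridError("wavelengths must be positive (nm)")
        if values.size > 1:
            diffs = np.diff(values)
            if np.any(diffs <= 0):
                raise GridError("wavelength grid must be strictly increasing")
            if np.any(np.abs(diffs - diffs[0]) > _GRID_SPACING_ATOL):
                raise GridError(
                    "wavelength grid must be regularly spaced "
                    f"(max deviation {np.max(np.abs(diffs - diffs[0])):g} nm)"
                )

    @property
    def step(self) -> float:
        """Grid spacing in nm (0.0 for a single-point grid)."""
        if self.values.size < 2:
            return 0.0
        return float(self.values[1] - self.values[0])

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other) -> bool:
        return isinstance(other, WavelengthGrid) and np.array_equal(
            self.values, other.values
        )


def make_grid(lo: float, hi: float, step: float = 0.5) -> WavelengthGrid:
    """Regular grid covering [lo, hi] inclusive at the given nm step."""
    n = int(round((hi - lo) / step)) + 1
    return WavelengthGrid(lo + step * np.arange(n))


@dataclass
class SampleMeta:
    """Per-sample metadata; numeric fields are non-negative when present."""

    sample_id: str
    class_label: str | None = None
    dna_conc: float | None = None
    uvc_dose: float | None = None
    tt_conc: float | None = None
    batch: str | None = None

    def __post_init__(self):
        for name in ("dna_conc", "uvc_dose", "tt_conc"):
            v = getattr(self, name)
            if v is not None:
                v = float(v)
                if not np.isfinite(v) or v < 0:
                    raise ValueError(f"{name} must be finite and >= 0, got {v}")
                setattr(self, name, v)


@dataclass
class SpectraSet:
    """Absorbance matrix (n_samples x n_wavelengths) with grid and metadata."""

    absorbance: np.ndarray
    grid: WavelengthGrid
    meta: list[SampleMeta] = field(default_factory=list)

    def __post_init__(self):
        A = np.asarray(self.absorbance, dtype=float)
        if A.ndim != 2:
            raise ValueError("absorbance must be 2-D (samples x wavelengths)")
        if A.shape[1] != len(self.grid):
            raise ValueError(
                f"absorbance has {A.shape[1]} columns but grid has {len(self.grid)}"
            )
        if len(self.meta) != A.shape[0]:
            raise ValueError(
                f"{A.shape[0]} spectra but {len(self.meta)} metadata records"
            )
        if A.size and not np.all(np.isfinite(A)):
            raise ValueError("absorbance values must all be finite")
        ids = [m.sample_id for m in self.meta]
        if len(set(ids)) != len(ids):
            raise ValueError("sample_id values must be unique within a set")
        self.absorbance = A

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.absorbance.shape[1]

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid.values

    def meta_frame(self) -> pd.DataFrame:
        """Metadata as a DataFrame with the canonical column order."""
        return pd.DataFrame(
            [{f: getattr(m, f) for f in META_FIELDS} for m in self.meta],
            columns=list(META_FIELDS),
        )

    def response(self, column: str) -> np.ndarray:
        """Numeric reference values from a metadata column; raises on missing."""
        y = self.meta_frame()[column].to_numpy(dtype=float)
        if np.any(~np.isfinite(y)):
            bad = [self.meta[i].sample_id for i in np.flatnonzero(~np.isfinite(y))]
            raise ValueError(f"response '{column}' missing for samples {bad}")
        return y

    def labels(self, column: str = "class_label") -> list[str]:
        vals = self.meta_frame()[column].tolist()
        if any(v is None or (isinstance(v, float) and np.isnan(v)) for v in vals):
            raise ValueError(f"label column '{column}' has missing values")
        return [str(v) for v in vals]

    def subset(self, rows: Sequence[int] | np.ndarray) -> "SpectraSet":
        rows = np.asarray(rows)
        if rows.dtype == bool:
            rows = np.flatnonzero(rows)
        return SpectraSet(
            self.absorbance[rows], self.grid, [self.meta[i] for i in rows]
        )


def _parse_meta_value(name: str, raw):
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    s = str(raw).strip()
    if s == "" or s.lower() in ("nan", "na", "none"):
        return None
    if name in ("dna_conc", "uvc_dose", "tt_conc"):
        return float(s)
    return s


def read_spectra_table(
    path, orientation: str = "samples_as_rows", delimiter: str | None = None
) -> SpectraSet:
    """Read a delimited spectra table.

    The header holds metadata field names (any subset of ``sample_id``,
    ``class_label``, ``dna_conc``, ``uvc_dose``, ``tt_conc``, ``batch``)
    followed by wavelengths in nm.  With ``samples_as_columns`` the file is
    the transpose: wavelengths run down the first column.
    """
    if orientation not in ("samples_as_rows", "samples_as_columns"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if delimiter is None:
        with open(path) as fh:
            first = fh.readline()
        delimiter = "\t" if "\t" in first else ","
    df = pd.read_csv(path, sep=delimiter, header=0, dtype=str)
    if orientation == "samples_as_columns":
        df = df.set_index(df.columns[0]).T.reset_index(names="sample_id")

    meta_cols = [c for c in df.columns if c in META_FIELDS]
    wl_cols = [c for c in df.columns if c not in META_FIELDS]
    try:
        wavelengths = np.array([float(c) for c in wl_cols])
    except ValueError as exc:
        raise SpectraParseError(f"non-numeric wavelength header: {exc}") from None
    grid = WavelengthGrid(wavelengths)  # raises GridError if irregular

    meta = []
    for i in range(len(df)):
        fields = {name: _parse_meta_value(name, df.iloc[i][name]) for name in meta_cols}
        if fields.get("sample_id") is None:
            fields["sample_id"] = f"S{i}"
        meta.append(SampleMeta(**fields))

    A = np.empty((len(df), len(wl_cols)))
    for j, col in enumerate(wl_cols):
        try:
            A[:, j] = df[col].astype(float).to_numpy()
        except ValueError:
            for i, raw in enumerate(df[col]):
                try:
                    float(raw)
                except (TypeError, ValueError):
                    raise SpectraParseError(
                        f"non-numeric absorbance at row {i}, wavelength {col}: {raw!r}"
                    ) from None
            raise
    return SpectraSet(A, grid, meta)


def write_spectra_table(
    spectra: SpectraSet, path, delimiter: str = ","
) -> None:
    """Write the dialect :func:`read_spectra_table` accepts, full precision."""
    buf = io.StringIO()
    wl_header = [format(w, ".17g") for w in spectra.wavelengths]
    mf = spectra.meta_frame()
    present = [
        c for c in META_FIELDS if c == "sample_id" or mf[c].notna().any()
    ]
    buf.write(delimiter.join(list(present) + wl_header) + "\n")
    for i in range(spectra.n_samples):
        cells = []
        for c in present:
            v = mf.iloc[i][c]
            if v is None or (isinstance(v, float) and np.isnan(v)):
                cells.append("")
            elif isinstance(v, float):
                cells.append(format(v, ".17g"))
            else:
                cells.append(str(v))
        cells.extend(format(v, ".17g") for v in spectra.absorbance[i])
        buf.write(delimiter.join(cells) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def select_wavelength_range(spectra: SpectraSet, lo: float, hi: float) -> SpectraSet:
    """Columns with lo <= lambda <= hi (closed interval); metadata unchanged."""
    if not lo < hi:
        raise ValueError(f"need lo < hi, got ({lo}, {hi})")
    wl = spectra.wavelengths
    mask = (wl >= lo - _GRID_SPACING_ATOL) & (wl <= hi + _GRID_SPACING_ATOL)
    if not mask.any():
        raise GridError(
            f"range ({lo}, {hi}) nm does not intersect the grid "
            f"[{wl[0]}, {wl[-1]}] nm"
        )
    return SpectraSet(
        spectra.absorbance[:, mask], WavelengthGrid(wl[mask]), list(spectra.meta)
    )
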