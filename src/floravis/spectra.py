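"""Reflectance spectrum data model and file ingestion.

A reflectance "spectrogram" is a curve R(λ) giving the fraction of incident
light a surface reflects at each wavelength λ (nm).  Benchtop
spectrophotometers export these as delimited tables of percent-reflectance
against a wavelength column, typically sampled every 1 nm over 200–700 nm.
This module provides the in-memory containers (:class:`WavelengthGrid`,
:class:`ReflectanceSpectrum`), unit normalisation, resampling, band
statistics, and the four-band spectral-range binning (near-UV / blue / green
/ red-IR) used when tabulating reflectance studies.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "WavelengthGrid",
    "FloralPart",
    "ReflectanceSpectrum",
    "SpectralBin",
    "SPECTRAL_BINS",
    "parse_spectrum_table",
    "parse_spectrum_workbook",
    "normalize_units",
    "resample_to_grid",
    "mean_reflectance_in_band",
    "assign_spectral_bins",
    "spectra_to_long_frame",
    "write_long_csv",
    "plot_spectra",
]


class FloralPart(str, Enum):
    """Closed vocabulary of measured plant surfaces.

    Single-letter codes follow the usual field shorthand: P petal, A anther,
    S sepal, L upper leaf.  ``anther_sepal_disk`` is the jointly measured
    central anther-and-sepal disk (code ``A+S``), used for small flowers
    where the centre cannot be dissected cleanly.
    """

    PETAL = "petal"
    ANTHER = "anther"
    SEPAL = "sepal"
    ANTHER_SEPAL_DISK = "anther_sepal_disk"
    LEAF_UPPER = "leaf_upper"
    LEAF_LOWER = "leaf_lower"
    FULL_FLOWER = "full_flower"

    @classmethod
    def from_code(cls, code: str) -> "FloralPart":
        key = code.strip().lower().replace(" ", "")
        aliases = {
            "p": cls.PETAL,
            "petal": cls.PETAL,
            "a": cls.ANTHER,
            "anther": cls.ANTHER,
            "s": cls.SEPAL,
            "sepal": cls.SEPAL,
            "a+s": cls.ANTHER_SEPAL_DISK,
            "as": cls.ANTHER_SEPAL_DISK,
            "anther_sepal_disk": cls.ANTHER_SEPAL_DISK,
            "l": cls.LEAF_UPPER,
            "leaf": cls.LEAF_UPPER,
            "leaf_upper": cls.LEAF_UPPER,
            "leaf_lower": cls.LEAF_LOWER,
            "f": cls.FULL_FLOWER,
            "flower": cls.FULL_FLOWER,
            "full_flower": cls.FULL_FLOWER,
        }
        if key not in aliases:
            raise ValueError(f"unknown floral part code: {code!r}")
        return aliases[key]

    @property
    def code(self) -> str:
        return {
            FloralPart.PETAL: "P",
            FloralPart.ANTHER: "A",
            FloralPart.SEPAL: "S",
            FloralPart.ANTHER_SEPAL_DISK: "A+S",
            FloralPart.LEAF_UPPER: "L",
            FloralPart.LEAF_LOWER: "L_lower",
            FloralPart.FULL_FLOWER: "F",
        }[self]


@dataclass(frozen=True)
class WavelengthGrid:
    """A strictly increasing set of sample wavelengths in nm.

    Spacing may be irregular but must be positive; wavelengths must lie in
    the 200–2500 nm window a UV-VIS-NIR instrument can plausibly cover.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or vals.size < 2:
            raise ValueError("wavelength grid needs at least two 1-D samples")
        if not np.all(np.isfinite(vals)):
            raise ValueError("wavelength grid contains non-finite values")
        if np.any(np.diff(vals) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if vals[0] < 200 or vals[-1] > 2500:
            raise ValueError("wavelengths must lie within 200-2500 nm")

    @classmethod
    def regular(cls, lo: float = 300.0, hi: float = 700.0, step: float = 1.0) -> "WavelengthGrid":
        n = int(round((hi - lo) / step)) + 1
        return cls(np.linspace(lo, hi, n))

    @property
    def span(self) -> tuple[float, float]:
        return float(self.values[0]), float(self.values[-1])

    def __len__(self) -> int:
        return len(self.values)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return self.values.shape == other.values.shape and bool(
            np.array_equal(self.values, other.values)
        )


@dataclass(frozen=True)
class ReflectanceSpectrum:
    """One labelled reflectance curve R(λ) on a wavelength grid.

    Reflectance is stored as a fraction in [0, 1]; use
    :func:`normalize_units` when ingesting percent-valued exports.
    """

    grid: WavelengthGrid
    reflectance: np.ndarray
    label: str = ""
    part: FloralPart | None = None
    specimen_id: str = ""

    def __post_init__(self) -> None:
        refl = np.asarray(self.reflectance, dtype=float)
        object.__setattr__(self, "reflectance", refl)
        if refl.shape != self.grid.values.shape:
            raise ValueError("reflectance and grid lengths differ")
        if not np.all(np.isfinite(refl)):
            raise ValueError("reflectance contains non-finite values")
        if refl.min() < 0.0 or refl.max() > 1.0:
            raise ValueError("reflectance must be a fraction in [0, 1]")

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid.values

    def with_values(self, reflectance: np.ndarray) -> "ReflectanceSpectrum":
        return replace(self, reflectance=np.asarray(reflectance, dtype=float))


@dataclass(frozen=True)
class SpectralBin:
    """One of the four fixed wavelength bands used for range tabulation."""

    name: str
    lo: float
    hi: float  # math.inf for the open-ended red/IR band

    def intersects(self, lo: float, hi: float) -> bool:
        if math.isinf(self.hi):
            # red/IR is open at its lower edge: (625, inf)
            return hi > self.lo
        return max(lo, self.lo) <= min(hi, self.hi)


#: Near-UV / blue / green / red-IR band edges (nm), adjacent-integer edges.
SPECTRAL_BINS: tuple[SpectralBin, ...] = (
    SpectralBin("near_UV", 300.0, 380.0),
    SpectralBin("blue", 381.0, 520.0),
    SpectralBin("green", 521.0, 625.0),
    SpectralBin("red_IR", 625.0, math.inf),
)


def assign_spectral_bins(lo: float, hi: float) -> list[str]:
    """Return the names of every band a wavelength range [lo, hi] touches.

    Overlap is closed-interval (a range ending exactly at a band edge counts),
    except that the open-ended red/IR band starts strictly above 625 nm.
    """
    if lo > hi:
        raise ValueError(f"range lo {lo} exceeds hi {hi}")
    names = [b.name for b in SPECTRAL_BINS if b.intersects(lo, hi)]
    return names


def normalize_units(values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Convert raw reflectance values to fractions in [0, 1].

    Exported spectra may be percent (0–100) or fraction (0–1); values whose
    maximum exceeds 1.5 are treated as percent and divided by 100.  Small
    negative instrument artefacts are clipped to 0 and values above 1 are
    clipped to 1, each with a logged warning.  The operation is idempotent.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("empty reflectance column")
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite reflectance values")
    if vals.max() > 1.5:
        vals = vals / 100.0
    if vals.min() < 0.0:
        logger.warning("clipping %d negative reflectance values to 0", int((vals < 0).sum()))
        vals = np.where(vals < 0.0, 0.0, vals)
    if vals.max() > 1.0:
        logger.warning("clipping %d reflectance values above 1 to 1", int((vals > 1).sum()))
        vals = np.where(vals > 1.0, 1.0, vals)
    return vals


def _strictly_monotone(col: pd.Series) -> bool:
    d = np.diff(col.to_numpy(dtype=float))
    return bool(np.all(d > 0) or np.all(d < 0))


def _looks_like_wavelength_header(name: str) -> bool:
    low = str(name).lower()
    return "nm" in low or "wavelength" in low


def _detect_wavelength_column(frame: pd.DataFrame) -> str:
    named = [c for c in frame.columns if _looks_like_wavelength_header(c)]
    if named:
        col = named[0]
        dupes = frame.index[frame[col].duplicated()].tolist()
        if dupes:
            raise ValueError(f"duplicate wavelengths at rows {dupes}")
        if not _strictly_monotone(frame[col]):
            raise ValueError(f"wavelength column {col!r} is not monotone")
        return col
    candidates = [c for c in frame.columns if _strictly_monotone(frame[c])]
    if not candidates:
        raise ValueError("no strictly monotone numeric column to use as wavelength")
    return candidates[0]


def _infer_part(header: str) -> FloralPart | None:
    try:
        return FloralPart.from_code(str(header))
    except ValueError:
        return None


def _frame_to_spectra(frame: pd.DataFrame, label: str = "") -> list[ReflectanceSpectrum]:
    if frame.empty or frame.shape[1] < 2:
        raise ValueError("spectral table needs a wavelength column and >=1 reflectance columns")
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & frame.notna()
    if bad.to_numpy().any():
        rows = sorted(set(bad.index[bad.any(axis=1)].tolist()))
        raise ValueError(f"non-numeric cells in rows {rows}")
    if numeric.isna().to_numpy().any():
        rows = sorted(set(numeric.index[numeric.isna().any(axis=1)].tolist()))
        raise ValueError(f"missing values in rows {rows}")
    wl_col = _detect_wavelength_column(numeric)
    wl = numeric[wl_col].to_numpy(dtype=float)
    dupes = pd.Series(wl)[pd.Series(wl).duplicated()].index.tolist()
    if dupes:
        raise ValueError(f"duplicate wavelengths at rows {dupes}")
    order = np.argsort(wl)
    spectra = []
    for col in numeric.columns:
        if col == wl_col:
            continue
        refl = normalize_units(numeric[col].to_numpy(dtype=float)[order])
        spectra.append(
            ReflectanceSpectrum(
                grid=WavelengthGrid(wl[order]),
                reflectance=refl,
                label=str(col),
                part=_infer_part(str(col)),
                specimen_id=label,
            )
        )
    return spectra


def parse_spectrum_table(
    source: str | Path | io.IOBase,
    *,
    sep: str | None = None,
    label: str = "",
) -> list[ReflectanceSpectrum]:
    """Parse a delimited wavelength × reflectance table.

    ``source`` may be a path, raw text, or an open file handle.  The
    wavelength column is detected as the strictly monotone numeric column
    (header names containing "nm"/"wavelength" break ties); every other
    column becomes one spectrum, its part inferred from header codes
    (P, A, S, L, A+S, ...) when possible.  Rows may arrive in descending
    wavelength order; output grids are always ascending.
    """
    if isinstance(source, (str, Path)):
        as_path = Path(str(source))
        text = as_path.read_text() if ("\n" not in str(source) and as_path.is_file()) else str(source)
    else:
        text = source.read()
    if not text.strip():
        raise ValueError("empty spectral table")
    frame = pd.read_csv(io.StringIO(text), sep=sep, engine="python")
    return _frame_to_spectra(frame, label=label)


def parse_spectrum_workbook(path: str | Path, sheet: int | str = 0, label: str = "") -> list[ReflectanceSpectrum]:
    """Thin spreadsheet adapter over the same column-detection logic."""
    frame = pd.read_excel(path, sheet_name=sheet)
    return _frame_to_spectra(frame, label=label or Path(path).stem)


def resample_to_grid(s: ReflectanceSpectrum, grid: WavelengthGrid) -> ReflectanceSpectrum:
    """Linearly interpolate a spectrum onto a target grid.

    The target must lie within the source span; extrapolation is refused with
    the offending wavelengths named.  Resampling onto the source's own grid
    returns the values unchanged.
    """
    lo, hi = s.grid.span
    out = grid.values
    outside = out[(out < lo) | (out > hi)]
    if outside.size:
        raise ValueError(
            f"resampling would extrapolate outside [{lo}, {hi}] nm at {outside[:5].tolist()}"
        )
    if grid == s.grid:
        return replace(s, grid=grid)
    vals = np.interp(out, s.grid.values, s.reflectance)
    return replace(s, grid=grid, reflectance=vals)


def mean_reflectance_in_band(s: ReflectanceSpectrum, lo: float, hi: float) -> float:
    """Trapezoid-integrated mean of R(λ) over [lo, hi].

    Band edges falling between grid points are included by linear
    interpolation, so the result is exact for the piecewise-linear model the
    grid implies.
    """
    span_lo, span_hi = s.grid.span
    if not (span_lo <= lo < hi <= span_hi):
        raise ValueError(f"band [{lo}, {hi}] outside spectrum span [{span_lo}, {span_hi}]")
    wl = s.grid.values
    inside = wl[(wl > lo) & (wl < hi)]
    x = np.concatenate(([lo], inside, [hi]))
    y = np.interp(x, wl, s.reflectance)
    return float(np.trapezoid(y, x) / (hi - lo))


def spectra_to_long_frame(spectra: Iterable[ReflectanceSpectrum]) -> pd.DataFrame:
    """Canonical long format: specimen_id, part, wavelength_nm, reflectance_fraction."""
    chunks = []
    for s in spectra:
        chunks.append(
            pd.DataFrame(
                {
                    "specimen_id": s.specimen_id or s.label,
                    "part": s.part.value if s.part else "",
                    "wavelength_nm": s.grid.values,
                    "reflectance_fraction": s.reflectance,
                }
            )
        )
    if not chunks:
        return pd.DataFrame(
            columns=["specimen_id", "part", "wavelength_nm", "reflectance_fraction"]
        )
    return pd.concat(chunks, ignore_index=True)


def write_long_csv(spectra: Iterable[ReflectanceSpectrum], path: str | Path) -> None:
    spectra_to_long_frame(spectra).to_csv(path, index=False)


def plot_spectra(spectra: Iterable[ReflectanceSpectrum], ax=None):
    """Simple reflectance-vs-wavelength plot for a handful of spectra."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for s in spectra:
        name = s.label or (s.part.value if s.part else "spectrum")
        ax.plot(s.grid.values, 100.0 * s.reflectance, label=name)
    ax.set_xlabel("wavelength (nm)")
    ax.set_ylabel("reflectance (%)")
    ax.legend(fontsize="small")
    return ax
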