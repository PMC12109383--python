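"""Spectral data model, CSV I/O, peak detection and shift/percent arithmetic.

A :class:`Spectrum` is the universal record shared by every downstream
stage: a strictly increasing wavelength grid (nm), intensities (arbitrary
units) and free-form string metadata (sample id, temperature, Δλ, ligand
concentration).  Wavelengths are point samples; mixed grids across a
titration series are linearly interpolated onto the reference grid before
comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    DataError,
    DegeneratePeakWarning,
    DomainError,
    FormatError,
    PeakTieWarning,
)

__all__ = [
    "Spectrum",
    "PeakCall",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_spectra_long",
    "write_spectra_long",
    "find_peak",
    "peak_shift",
    "shift_label",
    "percent_change",
    "resample",
]


@dataclass(frozen=True)
class Spectrum:
    """An emission, synchronous or CD trace sampled on a wavelength grid.

    Parameters
    ----------
    wavelengths : array-like
        Sample positions in nm, strictly increasing, length >= 3.
    intensities : array-like
        Signal in arbitrary units, same length, all finite.
    meta : dict
        Free-form ``key -> str`` annotations.
    """

    wavelengths: np.ndarray
    intensities: np.ndarray
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        it = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "intensities", it)
        if wl.ndim != 1 or it.ndim != 1 or wl.size != it.size:
            raise DataError("wavelengths and intensities must be 1-D and equal length")
        if wl.size < 3:
            raise DataError(f"spectrum needs >= 3 samples, got {wl.size}")
        if not np.all(np.isfinite(wl)) or not np.all(np.isfinite(it)):
            raise DataError("spectrum contains non-finite values")
        if np.any(np.diff(wl) <= 0):
            dup = wl[np.flatnonzero(np.diff(wl) <= 0)[0] + 1]
            raise DataError(f"wavelengths not strictly increasing near {dup:g} nm")

    def __len__(self) -> int:
        return int(self.wavelengths.size)


@dataclass(frozen=True)
class PeakCall:
    """Location and height of a band maximum.

    ``method`` records how the call was made: ``"argmax"`` (grid sample)
    or ``"parabolic"`` (3-point interpolation around the argmax).
    """

    lambda_max: float
    intensity: float
    method: str = "argmax"


def read_spectrum_csv(path, dialect: dict[str, str] | None = None) -> Spectrum:
    """Read a single spectrum from a two-column CSV.

    The default header is ``wavelength_nm,intensity``; ``dialect`` may remap
    it, e.g. ``{"wavelength": "wl", "intensity": "counts"}``.  Leading
    ``# key=value`` comment lines become metadata.  Rows are sorted by
    wavelength; duplicated wavelengths are rejected.
    """
    dialect = dialect or {}
    wl_col = dialect.get("wavelength", "wavelength_nm")
    it_col = dialect.get("intensity", "intensity")

    meta: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        skip = 0
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    df = pd.read_csv(path, skiprows=skip, float_precision="round_trip")
    for col in (wl_col, it_col):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r} (have {list(df.columns)})")
    try:
        wl = df[wl_col].astype(float).to_numpy()
        it = df[it_col].astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric values in spectrum columns") from exc
    order = np.argsort(wl, kind="stable")
    wl, it = wl[order], it[order]
    dup = np.flatnonzero(np.diff(wl) == 0)
    if dup.size:
        raise DataError(f"{path}: duplicated wavelength {wl[dup[0]]:g} nm")
    return Spectrum(wl, it, meta)


def write_spectrum_csv(spectrum: Spectrum, path) -> None:
    """Write a spectrum in the format read_spectrum_csv accepts, full precision."""
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in spectrum.meta.items():
            fh.write(f"# {key}={value}\n")
        fh.write("wavelength_nm,intensity\n")
        for wl, it in zip(spectrum.wavelengths, spectrum.intensities):
            fh.write(f"{float(wl)!r},{float(it)!r}\n")


def read_spectra_long(path) -> dict[str, Spectrum]:
    """Read a long-format multi-spectrum CSV ``series_id,wavelength_nm,intensity``.

    Leading ``# series_id.key=value`` comment lines attach per-series metadata;
    plain ``# key=value`` lines attach to every series.
    """
    common: dict[str, str] = {}
    per_series: dict[str, dict[str, str]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        skip = 0
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            body = line[1:].strip()
            if "=" not in body:
                continue
            key, _, value = body.partition("=")
            key = key.strip()
            if "." in key:
                sid, _, subkey = key.partition(".")
                per_series.setdefault(sid, {})[subkey] = value.strip()
            else:
                common[key] = value.strip()
    df = pd.read_csv(path, skiprows=skip, float_precision="round_trip")
    for col in ("series_id", "wavelength_nm", "intensity"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    out: dict[str, Spectrum] = {}
    for sid, grp in df.groupby("series_id", sort=False):
        wl = grp["wavelength_nm"].astype(float).to_numpy()
        it = grp["intensity"].astype(float).to_numpy()
        order = np.argsort(wl, kind="stable")
        wl, it = wl[order], it[order]
        if np.any(np.diff(wl) == 0):
            raise DataError(f"{path}: series {sid!r} has duplicated wavelengths")
        meta = dict(common)
        meta.update(per_series.get(str(sid), {}))
        out[str(sid)] = Spectrum(wl, it, meta)
    return out


def write_spectra_long(spectra: dict[str, Spectrum], path) -> None:
    """Write several spectra to one long-format CSV (inverse of read_spectra_long)."""
    with open(path, "w", encoding="utf-8") as fh:
        for sid, s in spectra.items():
            for key, value in s.meta.items():
                fh.write(f"# {sid}.{key}={value}\n")
        fh.write("series_id,wavelength_nm,intensity\n")
        for sid, s in spectra.items():
            for wl, it in zip(s.wavelengths, s.intensities):
                fh.write(f"{sid},{float(wl)!r},{float(it)!r}\n")


def find_peak(s: Spectrum, refine: bool = False) -> PeakCall:
    """Locate the band maximum.

    The argmax over grid samples, ties broken toward the smaller wavelength
    (with a warning).  With ``refine`` a 3-point parabola is fit through the
    argmax and its neighbours, clamped to the grid at boundaries.  A flat
    spectrum triggers a degenerate-peak warning and returns the smallest
    wavelength.
    """
    it = s.intensities
    if np.ptp(it) == 0:
        warnings.warn("flat spectrum: degenerate peak", DegeneratePeakWarning, stacklevel=2)
        return PeakCall(float(s.wavelengths[0]), float(it[0]), "argmax")
    i = int(np.argmax(it))  # first occurrence = smallest wavelength
    if np.count_nonzero(it == it[i]) > 1:
        warnings.warn(
            "tied maxima; returning the smaller wavelength", PeakTieWarning, stacklevel=2
        )
    lam, height, method = float(s.wavelengths[i]), float(it[i]), "argmax"
    if refine and 0 < i < len(s) - 1:
        x0, x1, x2 = s.wavelengths[i - 1 : i + 2]
        y0, y1, y2 = it[i - 1 : i + 2]
        # Vertex of the parabola through three points (general, uneven grids).
        denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
        a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
        b = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
        if a < 0:
            xv = -b / (2 * a)
            if x0 <= xv <= x2:
                c = y1 - a * x1**2 - b * x1
                lam, height, method = float(xv), float(a * xv**2 + b * xv + c), "parabolic"
    return PeakCall(lam, height, method)


def peak_shift(reference: PeakCall, sample: PeakCall) -> float:
    """Signed band shift in nm; positive = red shift (toward longer wavelength)."""
    return sample.lambda_max - reference.lambda_max


def shift_label(shift: float, tol: float = 0.0) -> str:
    """Classify a signed shift as ``"red"``, ``"blue"`` or ``"none"``."""
    if shift > tol:
        return "red"
    if shift < -tol:
        return "blue"
    return "none"


def percent_change(reference: float, sample: float) -> float:
    """Percent decrease of ``sample`` relative to ``reference``.

    ``(reference - sample) / reference * 100``; negative when the sample
    exceeds the reference.  Rounding happens only at presentation.
    """
    if reference <= 0:
        raise DomainError(f"reference intensity must be positive, got {reference}")
    return (reference - sample) / reference * 100.0


def resample(s: Spectrum, grid: np.ndarray) -> Spectrum:
    """Linearly interpolate a spectrum onto a new strictly increasing grid."""
    grid = np.asarray(grid, dtype=float)
    if grid[0] < s.wavelengths[0] or grid[-1] > s.wavelengths[-1]:
        raise DomainError(
            f"target grid [{grid[0]:g}, {grid[-1]:g}] nm exceeds spectrum range "
            f"[{s.wavelengths[0]:g}, {s.wavelengths[-1]:g}] nm"
        )
    return Spectrum(grid, np.interp(grid, s.wavelengths, s.intensities), dict(s.meta))
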