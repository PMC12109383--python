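"""Dilution arithmetic and assembly of per-temperature quenching tables.

The titration design mirrors the common fluorometric protocol: microliter
aliquots of a concentrated ligand stock are added to a fixed cuvette volume
of protein solution, and an emission spectrum is recorded after each
addition.  Two volume conventions are supported:

``nominal``
    concentration = stock * added / base.  This is the convention the
    printed ladder (80 uL of 1e-3 M into 3.0 mL -> 26.7 uM) is consistent
    with, and the default.
``additive``
    concentration = stock * added / (base + added), accounting for the
    volume the aliquot itself adds.

Protein concentration is carried as mg/mL metadata only; no molar protein
concentration is computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import AssemblyError, DataError, DomainError, FormatError
from .spectra import Spectrum, find_peak, read_spectrum_csv

__all__ = [
    "DilutionSpec",
    "QuenchTable",
    "ligand_concentration",
    "build_quench_table",
    "read_titration_manifest",
]

LIGAND_CONC_KEY = "ligand_conc_M"


@dataclass(frozen=True)
class DilutionSpec:
    """One addition of ligand stock into the cuvette.

    Volumes are in liters, stock concentration in mol/L.
    """

    stock_conc: float
    added_volume: float
    base_volume: float
    volume_convention: str = "nominal"

    def __post_init__(self) -> None:
        if self.stock_conc < 0 or self.added_volume < 0 or self.base_volume < 0:
            raise DomainError("volumes and stock concentration must be >= 0")
        if self.volume_convention not in ("nominal", "additive"):
            raise DomainError(f"unknown volume convention {self.volume_convention!r}")


@dataclass(frozen=True)
class QuenchTable:
    """Ligand concentration vs fluorescence response at one temperature.

    ``q`` is strictly increasing with ``q[0] = 0`` (the ligand-free
    reference); ``f`` holds the aligned responses, all positive, and
    ``f0 = f[0]``.
    """

    temperature: float
    q: np.ndarray
    f: np.ndarray
    response_mode: str = "peak"
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        f = np.asarray(self.f, dtype=float)
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "f", f)
        if q.size != f.size or q.size < 2:
            raise DataError("q and f must be equal length >= 2")
        if q[0] != 0:
            raise DataError(f"first concentration must be 0, got {q[0]:g}")
        if np.any(np.diff(q) <= 0):
            raise DataError("concentrations must be strictly increasing")
        if np.any(f <= 0):
            raise DataError("all fluorescence responses must be positive")

    @property
    def f0(self) -> float:
        return float(self.f[0])

    def __len__(self) -> int:
        return int(self.q.size)


def ligand_concentration(d: DilutionSpec) -> float:
    """Molar ligand concentration in the cuvette for one dilution."""
    if d.volume_convention == "nominal":
        if d.base_volume == 0:
            raise DomainError("base_volume must be > 0 under the nominal convention")
        return d.stock_conc * d.added_volume / d.base_volume
    total = d.base_volume + d.added_volume
    if total == 0:
        raise DomainError("base_volume + added_volume must be > 0")
    return d.stock_conc * d.added_volume / total


def build_quench_table(
    spectra: list[Spectrum],
    temperature: float,
    response_mode: str = "peak",
) -> QuenchTable:
    """Assemble a quenching table from spectra annotated with ligand concentration.

    Each spectrum must carry a ``ligand_conc_M`` metadata entry.  The
    response is the per-spectrum band maximum (``"peak"``) or the
    interpolated intensity at the zero-ligand peak wavelength
    (``"fixed_wavelength"``).  The result is sorted by concentration and is
    therefore invariant to input order.
    """
    if response_mode not in ("peak", "fixed_wavelength"):
        raise DomainError(f"unknown response mode {response_mode!r}")
    if len(spectra) < 3:
        raise AssemblyError(f"need >= 3 spectra, got {len(spectra)}")
    concs = []
    for s in spectra:
        if LIGAND_CONC_KEY not in s.meta:
            raise AssemblyError(f"spectrum missing {LIGAND_CONC_KEY!r} metadata")
        concs.append(float(s.meta[LIGAND_CONC_KEY]))
    concs = np.asarray(concs)
    if np.unique(concs).size != concs.size:
        raise AssemblyError("ligand concentrations must be distinct")
    if not np.any(concs == 0):
        raise AssemblyError("missing zero-ligand reference spectrum")
    order = np.argsort(concs)
    spectra = [spectra[i] for i in order]
    concs = concs[order]

    if response_mode == "peak":
        responses = np.array([find_peak(s).intensity for s in spectra])
    else:
        lam0 = find_peak(spectra[0]).lambda_max
        responses = np.array(
            [float(np.interp(lam0, s.wavelengths, s.intensities)) for s in spectra]
        )
    if np.any(responses <= 0):
        bad = concs[responses <= 0][0]
        raise DataError(f"nonpositive response at [Q] = {bad:g} M")
    return QuenchTable(temperature, concs, responses, response_mode)


def read_titration_manifest(
    path,
    stock_conc: float,
    base_volume: float,
    volume_convention: str = "nominal",
) -> dict[float, list[Spectrum]]:
    """Load a titration manifest CSV and return spectra grouped by temperature.

    Columns: ``series_id,temperature_K,added_volume_uL,spectrum_path``.
    Spectrum paths are resolved relative to the manifest's directory; each
    loaded spectrum gains ``ligand_conc_M`` metadata computed from its
    dilution under the given convention.
    """
    df = pd.read_csv(path)
    required = {"series_id", "temperature_K", "added_volume_uL", "spectrum_path"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: manifest needs columns {sorted(required)}")
    root = Path(path).parent
    by_temp: dict[float, list[Spectrum]] = {}
    for _, row in df.iterrows():
        spec = DilutionSpec(
            stock_conc, float(row["added_volume_uL"]) * 1e-6, base_volume, volume_convention
        )
        conc = ligand_concentration(spec)
        s = read_spectrum_csv(root / str(row["spectrum_path"]))
        s.meta[LIGAND_CONC_KEY] = repr(conc)
        by_temp.setdefault(float(row["temperature_K"]), []).append(s)
    return by_temp
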