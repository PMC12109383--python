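"""Synchronous-fluorescence microenvironment analysis.

Synchronous spectra are recorded with a fixed excitation-emission offset.
At an offset of 15 nm the band reports tyrosine residues; at 60 nm,
tryptophan.  For each ligand concentration the band maximum is located,
the intensity decline relative to the ligand-free spectrum is computed,
and the net band shift (zero vs highest concentration) is classified as
red (toward longer wavelength, more polar microenvironment) or blue
(shorter wavelength, more hydrophobic).  Shift calls use integer-nm argmax
by default, matching whole-nm instrument reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ComparisonError, DataError
from .spectra import Spectrum, find_peak, peak_shift, percent_change, shift_label

__all__ = [
    "SyncSeries",
    "SyncSummary",
    "residue_for_offset",
    "analyze_sync",
    "compare_contributions",
]


def residue_for_offset(delta_lambda: float) -> str:
    """Residue probed by a synchronous offset: 15 nm -> Tyr, 60 nm -> Trp."""
    return {15.0: "Tyr", 60.0: "Trp"}.get(float(delta_lambda), "custom")


@dataclass(frozen=True)
class SyncSeries:
    """Synchronous spectra across a ligand concentration ladder at one offset."""

    delta_lambda: float
    spectra: tuple[tuple[float, Spectrum], ...]  # (ligand conc mol/L, spectrum)

    def __post_init__(self) -> None:
        items = tuple(sorted(((float(c), s) for c, s in self.spectra), key=lambda p: p[0]))
        object.__setattr__(self, "spectra", items)
        concs = [c for c, _ in items]
        if len(set(concs)) != len(concs):
            raise DataError("ligand concentrations must be distinct")
        if not concs or concs[0] != 0:
            raise DataError("series must include the zero-ligand spectrum")

    @property
    def residue_label(self) -> str:
        return residue_for_offset(self.delta_lambda)

    @property
    def concentrations(self) -> tuple[float, ...]:
        return tuple(c for c, _ in self.spectra)


@dataclass(frozen=True)
class SyncSummary:
    """Per-concentration peaks and declines plus the net shift call."""

    delta_lambda: float
    residue_label: str
    concentrations: tuple[float, ...]
    lambda_max: tuple[float, ...]  # nm, aligned with concentrations
    intensity: tuple[float, ...]  # a.u.
    percent_decline: tuple[float, ...]  # vs zero-ligand intensity
    total_shift: float  # nm, signed; positive = red
    shift_label: str
    max_decline: float = field(default=float("nan"))


def analyze_sync(series: SyncSeries) -> SyncSummary:
    """Summarize one synchronous series: peaks, declines, net shift."""
    if len(series.spectra) < 2:
        raise DataError("synchronous series needs >= 2 concentrations")
    peaks = [find_peak(s) for _, s in series.spectra]
    i0 = peaks[0]
    declines = tuple(percent_change(i0.intensity, p.intensity) for p in peaks)
    shift = peak_shift(i0, peaks[-1])
    return SyncSummary(
        delta_lambda=series.delta_lambda,
        residue_label=series.residue_label,
        concentrations=series.concentrations,
        lambda_max=tuple(p.lambda_max for p in peaks),
        intensity=tuple(p.intensity for p in peaks),
        percent_decline=declines,
        total_shift=shift,
        shift_label=shift_label(shift),
        max_decline=max(declines),
    )


def compare_contributions(trp: SyncSummary, tyr: SyncSummary) -> dict:
    """Compare Trp vs Tyr contributions on the same concentration ladder.

    Reports which residue carries the larger ligand-free intensity and the
    larger maximum decline, with the corresponding ratios.  Ladders must
    match exactly.
    """
    if trp.concentrations != tyr.concentrations:
        raise ComparisonError(
            "concentration ladders differ: "
            f"{trp.concentrations} vs {tyr.concentrations}"
        )

    def _dominant(a: float, b: float, la: str, lb: str) -> str:
        if np.isclose(a, b, rtol=0, atol=0) or a == b:
            return "tie"
        return la if a > b else lb

    f0_trp, f0_tyr = trp.intensity[0], tyr.intensity[0]
    return {
        "intensity_dominant": _dominant(f0_trp, f0_tyr, trp.residue_label, tyr.residue_label),
        "intensity_ratio": f0_trp / f0_tyr if f0_tyr != 0 else float("inf"),
        "decline_dominant": _dominant(
            trp.max_decline, tyr.max_decline, trp.residue_label, tyr.residue_label
        ),
        "decline_ratio": (
            trp.max_decline / tyr.max_decline if tyr.max_decline != 0 else float("inf")
        ),
        "max_decline": {trp.residue_label: trp.max_decline, tyr.residue_label: tyr.max_decline},
        "zero_intensity": {trp.residue_label: f0_trp, tyr.residue_label: f0_tyr},
    }
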