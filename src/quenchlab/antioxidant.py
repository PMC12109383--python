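"""ABTS / DPPH / FRAP antioxidant quantification with Trolox calibration.

Raw assay responses:

    ABTS scavenging rate (%)  = (A0 - A1) / A0 * 100
    DPPH scavenging rate (%)  = (Ab - At - Ac) / Ab * 100
    Ferric-reducing power     = At - A1 - A0        (absorbance units)

where A0/A1 (ABTS) are control/sample absorbances, Ab/At/Ac (DPPH) are
blank/sample/no-radical-control, and At/A1/A0 (FRAP) are sample/control/
blank.  Responses outside [0, 100]% are reported with a warning and never
clipped — truncation would silently hide assay failure.

Antioxidant capacity is expressed as TEAC (Trolox-equivalent antioxidant
capacity, mg/L): the raw response is converted through an ordinary
least-squares Trolox standard curve with a free intercept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import (
    CalibrationError,
    CalibrationQualityWarning,
    DataError,
    DomainError,
    NegativeRateWarning,
)

__all__ = [
    "AssayRead",
    "TroloxCurve",
    "TeacResult",
    "abts_rate",
    "dpph_rate",
    "frap_power",
    "assay_response",
    "calibrate_trolox",
    "to_teac",
]

_REQUIRED_ROLES = {
    "ABTS": frozenset({"A0", "A1"}),
    "DPPH": frozenset({"Ab", "At", "Ac"}),
    "FRAP": frozenset({"At", "A1", "A0"}),
}


@dataclass(frozen=True)
class AssayRead:
    """One sample's absorbance reads for a single assay."""

    assay: str
    absorbances: dict[str, float]
    sample_id: str = ""
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.assay not in _REQUIRED_ROLES:
            raise DataError(f"unknown assay {self.assay!r}")
        missing = _REQUIRED_ROLES[self.assay] - self.absorbances.keys()
        if missing:
            raise DataError(f"{self.assay} read missing roles {sorted(missing)}")
        if any(v < 0 for v in self.absorbances.values()):
            raise DataError("absorbances must be >= 0")


@dataclass(frozen=True)
class TroloxCurve:
    """Linear standard curve: response = slope * conc(mg/L) + intercept."""

    slope: float
    intercept: float
    r_squared: float = 1.0
    response_kind: str = "percent_rate"

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise CalibrationError("Trolox curve slope must be nonzero")


@dataclass(frozen=True)
class TeacResult:
    raw_response: float
    teac: float  # mg/L Trolox equivalents


def abts_rate(a0: float, a1: float) -> float:
    """ABTS free-radical scavenging rate in percent."""
    if a0 <= 0:
        raise DomainError(f"ABTS control absorbance must be positive, got {a0}")
    rate = (a0 - a1) / a0 * 100.0
    if rate < 0:
        warnings.warn(f"negative ABTS rate {rate:.3g}%", NegativeRateWarning, stacklevel=2)
    return rate


def dpph_rate(ab: float, at: float, ac: float) -> float:
    """DPPH free-radical scavenging rate in percent (may be negative, warned)."""
    if ab <= 0:
        raise DomainError(f"DPPH blank absorbance must be positive, got {ab}")
    rate = (ab - at - ac) / ab * 100.0
    if rate < 0:
        warnings.warn(f"negative DPPH rate {rate:.3g}%", NegativeRateWarning, stacklevel=2)
    return rate


def frap_power(at: float, a1: float, a0: float) -> float:
    """Ferric-reducing power as an absorbance difference (may be negative, warned)."""
    power = at - a1 - a0
    if power < 0:
        warnings.warn(
            f"negative reducing power {power:.3g}", NegativeRateWarning, stacklevel=2
        )
    return power


def assay_response(read: AssayRead) -> float:
    """Dispatch a read to the appropriate response formula."""
    a = read.absorbances
    if read.assay == "ABTS":
        return abts_rate(a["A0"], a["A1"])
    if read.assay == "DPPH":
        return dpph_rate(a["Ab"], a["At"], a["Ac"])
    return frap_power(a["At"], a["A1"], a["A0"])


def calibrate_trolox(
    standards: list[tuple[float, float]],
    response_kind: str = "percent_rate",
) -> TroloxCurve:
    """Fit the Trolox standard curve (OLS, free intercept).

    ``standards`` are ``(concentration mg/L, response)`` pairs; at least
    three distinct concentrations are required.  A curve with r^2 below
    0.99 is returned with a quality warning.
    """
    if len(standards) < 3:
        raise CalibrationError(f"need >= 3 Trolox standards, got {len(standards)}")
    conc = np.array([c for c, _ in standards], dtype=float)
    resp = np.array([r for _, r in standards], dtype=float)
    if np.unique(conc).size < 2:
        raise CalibrationError("Trolox standards need a nonzero concentration spread")
    res = stats.linregress(conc, resp)
    r2 = float(res.rvalue) ** 2
    if r2 < 0.99:
        warnings.warn(
            f"Trolox curve r^2 = {r2:.4f} < 0.99", CalibrationQualityWarning, stacklevel=2
        )
    return TroloxCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        response_kind=response_kind,
    )


def to_teac(response: float, curve: TroloxCurve) -> TeacResult:
    """Convert a raw assay response to mg/L Trolox equivalents."""
    return TeacResult(raw_response=response, teac=(response - curve.intercept) / curve.slope)
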