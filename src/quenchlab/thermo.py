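"""Van't Hoff thermodynamics and binding-force classification.

From apparent binding constants Ka measured at several temperatures, the
integrated Van't Hoff equation

    ln Ka = -dH/(R T) + dS/R

gives the enthalpy change dH (from the slope of ln Ka on 1/T) and the
entropy change dS (from the intercept), with R = 8.314 J mol^-1 K^-1.
The Gibbs energy follows as dG = dH - T dS; dG < 0 means spontaneous
binding.  The sign quadrant of (dH, dS) is read with the Ross-Subramanian
rules: (+,+) hydrophobic, (-,+) electrostatic, (+,-) electrostatic plus
hydrophobic, (-,-) van der Waals plus hydrogen bonding.

Internal units are J/mol and J/(mol K) throughout; the report layer is
responsible for any kJ presentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import DomainError, FitError

__all__ = [
    "GAS_CONSTANT",
    "VantHoffFit",
    "GibbsResult",
    "ForceCall",
    "vant_hoff",
    "gibbs",
    "classify_forces",
    "discrepancy_notes",
]

#: Molar gas constant, J mol^-1 K^-1.
GAS_CONSTANT = 8.314

_FORCE_LABELS = {
    (1, 1): "hydrophobic",
    (-1, 1): "electrostatic",
    (1, -1): "electrostatic+hydrophobic",
    (-1, -1): "vdw+hbond",
}


@dataclass(frozen=True)
class VantHoffFit:
    """dH/dS from the linear regression of ln Ka on 1/T."""

    dh: float  # J/mol
    ds: float  # J/(mol K)
    r_squared: float
    se_dh: float
    se_ds: float
    n_temps: int
    gas_constant: float = GAS_CONSTANT

    def predicted_ln_ka(self, temperature: float) -> float:
        """ln Ka on the fitted line at a given temperature (K)."""
        return -self.dh / (self.gas_constant * temperature) + self.ds / self.gas_constant


@dataclass(frozen=True)
class GibbsResult:
    temperature: float
    dg: float  # J/mol

    @property
    def spontaneous(self) -> bool:
        return self.dg < 0


@dataclass(frozen=True)
class ForceCall:
    """Dominant binding force inferred from the signs of dH and dS."""

    label: str
    dh_sign: int
    ds_sign: int
    epsilon_dh: float
    epsilon_ds: float


def vant_hoff(ka_by_temperature: list[tuple[float, float]]) -> VantHoffFit:
    """Regress ln Ka on 1/T; dH = -R * slope, dS = R * intercept.

    Requires >= 2 distinct temperatures and positive Ka.  With exactly two
    temperatures the line is determined and standard errors are undefined
    (NaN).
    """
    if len(ka_by_temperature) < 2:
        raise FitError("Van't Hoff regression needs >= 2 temperatures")
    temps = np.array([t for t, _ in ka_by_temperature], dtype=float)
    kas = np.array([k for _, k in ka_by_temperature], dtype=float)
    if np.unique(temps).size != temps.size:
        raise FitError("duplicate temperatures in Van't Hoff input")
    if np.any(temps <= 0):
        raise DomainError("temperatures must be positive (K)")
    if np.any(kas <= 0):
        raise DomainError("binding constants must be positive")
    x = 1.0 / temps
    y = np.log(kas)
    if len(temps) == 2:
        slope = float((y[1] - y[0]) / (x[1] - x[0]))
        intercept = float(y[0] - slope * x[0])
        return VantHoffFit(
            dh=-GAS_CONSTANT * slope,
            ds=GAS_CONSTANT * intercept,
            r_squared=1.0,
            se_dh=float("nan"),
            se_ds=float("nan"),
            n_temps=2,
        )
    res = stats.linregress(x, y)
    return VantHoffFit(
        dh=-GAS_CONSTANT * float(res.slope),
        ds=GAS_CONSTANT * float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        se_dh=GAS_CONSTANT * float(res.stderr),
        se_ds=GAS_CONSTANT * float(res.intercept_stderr),
        n_temps=len(temps),
    )


def gibbs(dh: float, ds: float, temperature: float) -> GibbsResult:
    """Gibbs energy dG = dH - T dS (J/mol) at one temperature."""
    if temperature <= 0:
        raise DomainError(f"temperature must be positive, got {temperature}")
    return GibbsResult(temperature=temperature, dg=dh - temperature * ds)


def classify_forces(
    dh: float,
    ds: float,
    epsilon_dh: float = 100.0,
    epsilon_ds: float = 1.0,
) -> ForceCall:
    """Map the (dH, dS) sign quadrant to the dominant binding force.

    Values within the zero bands (|dH| <= ``epsilon_dh`` J/mol,
    |dS| <= ``epsilon_ds`` J/(mol K)) count as sign zero, and any zero sign
    yields ``"indeterminate"``.
    """
    dh_sign = 0 if abs(dh) <= epsilon_dh else (1 if dh > 0 else -1)
    ds_sign = 0 if abs(ds) <= epsilon_ds else (1 if ds > 0 else -1)
    label = _FORCE_LABELS.get((dh_sign, ds_sign), "indeterminate")
    return ForceCall(
        label=label,
        dh_sign=dh_sign,
        ds_sign=ds_sign,
        epsilon_dh=epsilon_dh,
        epsilon_ds=epsilon_ds,
    )


def discrepancy_notes(
    fit: VantHoffFit,
    reported_dh: float | None = None,
    reported_ds: float | None = None,
) -> list[str]:
    """Compare a fitted Van't Hoff result against externally reported values.

    Returns human-readable notes whenever a reported dH or dS disagrees in
    sign with the fitted one — the situation that arises when a Ka-vs-T
    trend and a published enthalpy are mutually inconsistent.  An empty
    list means no discordance detected.
    """
    notes: list[str] = []
    if reported_dh is not None and np.sign(reported_dh) != np.sign(fit.dh):
        notes.append(
            f"discrepancy: fitted dH = {fit.dh / 1000:.2f} kJ/mol disagrees in sign "
            f"with reported dH = {reported_dh / 1000:.2f} kJ/mol; the Ka-vs-T trend "
            "and the reported enthalpy cannot both be right"
        )
    if reported_ds is not None and np.sign(reported_ds) != np.sign(fit.ds):
        notes.append(
            f"discrepancy: fitted dS = {fit.ds:.2f} J/(mol K) disagrees in sign "
            f"with reported dS = {reported_ds:.2f} J/(mol K)"
        )
    return notes
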