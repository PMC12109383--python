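"""Stern-Volmer and double-logarithmic quenching fits, mechanism classification.

The Stern-Volmer relation,

    F0 / F = 1 + Kq * tau0 * [Q] = 1 + Ksv * [Q],

links the fluorescence ratio to the quencher concentration [Q].  Its slope
Ksv (L/mol) divided by the unquenched fluorophore lifetime tau0 (taken as
1e-8 s for biopolymers) gives the bimolecular quenching rate constant Kq.
When Kq exceeds the diffusion-controlled maximum (~2e10 L mol^-1 s^-1) the
quenching cannot be collisional and a ground-state complex (static
quenching) is inferred; the temperature trend of Ksv (decreasing for
static, increasing for dynamic) serves as corroborating evidence.

The double-logarithmic plot,

    lg[(F0 - F)/F] = lg Ka + n lg[Q]     (decadic logs),

yields the apparent binding constant Ka and binding-site number n.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import isnan

import numpy as np
from scipy import stats

from .exceptions import (
    DroppedPointWarning,
    EnhancementWarning,
    FitError,
    InterceptWarning,
)
from .titration import QuenchTable

__all__ = [
    "SternVolmerFit",
    "DoubleLogFit",
    "MechanismCall",
    "stern_volmer_fit",
    "double_log_fit",
    "classify_mechanism",
    "KQ_DIFFUSION_LIMIT",
    "TAU0_DEFAULT",
]

#: Diffusion-controlled maximum dynamic quenching constant, L mol^-1 s^-1.
KQ_DIFFUSION_LIMIT = 2.0e10
#: Typical unquenched biopolymer fluorescence lifetime, s.
TAU0_DEFAULT = 1e-8


@dataclass(frozen=True)
class SternVolmerFit:
    """Result of the linear Stern-Volmer regression at one temperature."""

    temperature: float
    ksv: float
    kq: float
    tau0: float
    intercept: float
    r: float
    se_ksv: float
    n_points: int
    fixed_intercept: bool = False

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise FitError(f"Stern-Volmer fit needs >= 3 points, got {self.n_points}")
        if not (isnan(self.r) or -1.0 <= self.r <= 1.0 + 1e-12):
            raise FitError(f"correlation coefficient out of range: {self.r}")


@dataclass(frozen=True)
class DoubleLogFit:
    """Result of the double-logarithmic binding regression at one temperature."""

    temperature: float
    ka: float
    n: float
    r: float
    se_log_ka: float
    se_n: float
    n_points: int

    def __post_init__(self) -> None:
        if self.ka <= 0:
            raise FitError(f"binding constant must be positive, got {self.ka}")
        if self.n_points < 3:
            raise FitError(f"double-log fit needs >= 3 points, got {self.n_points}")


@dataclass(frozen=True)
class MechanismCall:
    """Quenching-mechanism decision with supporting evidence."""

    label: str
    min_kq: float
    kq_threshold: float
    ksv_temperature_trend: str
    evidence: tuple[str, ...] = field(default_factory=tuple)


def stern_volmer_fit(
    t: QuenchTable,
    tau0: float = TAU0_DEFAULT,
    fix_intercept: bool = False,
) -> SternVolmerFit:
    """Fit F0/F = intercept + Ksv [Q] by ordinary least squares.

    The intercept is free by default (robust to baseline error) and flagged
    with a warning when it strays more than 0.05 from the theoretical 1;
    ``fix_intercept`` pins it at 1 and fits the slope alone.  ``kq`` is
    ``ksv / tau0`` by construction.
    """
    if len(t) < 3:
        raise FitError(f"Stern-Volmer fit needs >= 3 points, got {len(t)}")
    y = t.f0 / t.f
    q = t.q
    if fix_intercept:
        # slope through (0, 1): minimize sum (y - 1 - s q)^2
        slope = float(np.dot(q, y - 1.0) / np.dot(q, q))
        intercept = 1.0
        resid = y - 1.0 - slope * q
        dof = len(t) - 1
        se = float(np.sqrt(np.sum(resid**2) / dof / np.dot(q, q))) if dof > 0 else float("nan")
        yc = y - y.mean()
        r = float(np.corrcoef(q, y)[0, 1]) if np.ptp(yc) > 0 else float("nan")
    else:
        res = stats.linregress(q, y)
        slope, intercept = float(res.slope), float(res.intercept)
        se, r = float(res.stderr), float(res.rvalue)
        if abs(intercept - 1.0) > 0.05:
            warnings.warn(
                f"Stern-Volmer intercept {intercept:.4g} deviates from 1 by > 0.05",
                InterceptWarning,
                stacklevel=2,
            )
    if slope < 0:
        warnings.warn(
            "negative Stern-Volmer slope: enhancement, not quenching",
            EnhancementWarning,
            stacklevel=2,
        )
    return SternVolmerFit(
        temperature=t.temperature,
        ksv=slope,
        kq=slope / tau0,
        tau0=tau0,
        intercept=intercept,
        r=r,
        se_ksv=se,
        n_points=len(t),
        fixed_intercept=fix_intercept,
    )


def double_log_fit(t: QuenchTable) -> DoubleLogFit:
    """Fit lg[(F0-F)/F] = lg Ka + n lg[Q] by ordinary least squares.

    Points with [Q] = 0 or F >= F0 carry no binding information under this
    transform and are dropped with a warning; fewer than 3 surviving points
    is a fit error that lists what was dropped.
    """
    valid = (t.q > 0) & (t.f < t.f0)
    dropped = np.flatnonzero(~valid & (t.q > 0))
    if dropped.size:
        warnings.warn(
            f"dropped {dropped.size} point(s) with F >= F0 at [Q] = "
            f"{[f'{t.q[i]:g}' for i in dropped]}",
            DroppedPointWarning,
            stacklevel=2,
        )
    if np.count_nonzero(valid) < 3:
        raise FitError(
            "double-log fit needs >= 3 points with [Q] > 0 and F < F0; dropped "
            f"concentrations: {[f'{t.q[i]:g}' for i in np.flatnonzero(~valid)]}"
        )
    q = t.q[valid]
    f = t.f[valid]
    x = np.log10(q)
    y = np.log10((t.f0 - f) / f)
    res = stats.linregress(x, y)
    return DoubleLogFit(
        temperature=t.temperature,
        ka=float(10.0 ** res.intercept),
        n=float(res.slope),
        r=float(res.rvalue),
        se_log_ka=float(res.intercept_stderr),
        se_n=float(res.stderr),
        n_points=int(np.count_nonzero(valid)),
    )


def classify_mechanism(
    fits: list[SternVolmerFit],
    kq_threshold: float = KQ_DIFFUSION_LIMIT,
) -> MechanismCall:
    """Decide static vs dynamic quenching from per-temperature fits.

    Primary rule: the minimum Kq across temperatures is compared with the
    diffusion-controlled threshold — above means static, at or below means
    dynamic.  Secondary evidence is the sign of the OLS slope of Ksv vs
    temperature (decreasing corroborates static, increasing dynamic); when
    it disagrees with the primary rule the label stands and a discordance
    note is appended.  ``"ambiguous"`` is returned only when the minimum Kq
    lies within +/-5% of the threshold.
    """
    if not fits:
        raise FitError("mechanism classification needs at least one fit")
    temps = np.array([f.temperature for f in fits])
    if np.unique(temps).size != temps.size:
        raise FitError("fits must be at distinct temperatures")
    kqs = np.array([f.kq for f in fits])
    ksvs = np.array([f.ksv for f in fits])
    min_kq = float(kqs.min())
    evidence = [
        f"min Kq = {min_kq:.3g} L/mol/s vs diffusion limit {kq_threshold:.3g} L/mol/s"
    ]

    if temps.size < 2:
        trend = "flat"
        evidence.append("single temperature: Ksv trend unavailable, primary rule only")
    else:
        slope = float(stats.linregress(temps, ksvs).slope)
        trend = "decreasing" if slope < 0 else ("increasing" if slope > 0 else "flat")
        evidence.append(f"Ksv vs T slope = {slope:.3g} L/mol/K ({trend})")

    if abs(min_kq - kq_threshold) <= 0.05 * kq_threshold:
        label = "ambiguous"
        evidence.append("min Kq within 5% of the diffusion limit")
    elif min_kq > kq_threshold:
        label = "static"
        if trend == "increasing":
            evidence.append("discordance: Ksv increases with T, expected decreasing for static")
    else:
        label = "dynamic"
        if trend == "decreasing":
            evidence.append("discordance: Ksv decreases with T, expected increasing for dynamic")
    return MechanismCall(
        label=label,
        min_kq=min_kq,
        kq_threshold=kq_threshold,
        ksv_temperature_trend=trend,
        evidence=tuple(evidence),
    )
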