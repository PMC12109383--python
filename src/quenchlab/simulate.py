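"""Seeded synthetic-data generators with known ground truth.

Every generator is a pure function of its parameters and seed (repeated
calls are bitwise identical), and every output satisfies the invariants of
the domain type it feeds.  The generators emulate the wet-lab study design:

* emission titrations — a single Gaussian band near 345 nm, statically
  quenched (peak amplitude F0 / (1 + Ksv [Q])) with a small saturating red
  shift (~2 nm at full complexation) and multiplicative detector noise;
* synchronous series at offsets 15/60 nm — band centers and amplitudes
  interpolated monotonically between the ligand-free and top-concentration
  targets (defaults: Trp 274 -> 270 nm, 3311 -> 1592 a.u.; Tyr fixed at
  303 nm, 746 -> 400 a.u.);
* CD spectra — linear mixtures of the four-component basis plus additive
  noise;
* antioxidant assays — responses from a linear Trolox curve inverted into
  the absorbance roles of each assay, plus a matching standard series.

They do not model lifetimes, FRET, inner-filter effects or instrument
response; see the methods note for what that implies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .antioxidant import AssayRead, TroloxCurve
from .cd import BasisSet, CDSpectrum, StructureFractions, default_basis
from .exceptions import DataError, DomainError
from .quenching import KQ_DIFFUSION_LIMIT, TAU0_DEFAULT
from .spectra import Spectrum
from .synchronous import SyncSeries
from .titration import LIGAND_CONC_KEY

__all__ = [
    "STUDY_LADDER_M",
    "STUDY_KSV_BY_T",
    "EmissionModel",
    "MechanismScenario",
    "SyncTargets",
    "simulate_titration",
    "simulate_quench_study",
    "simulate_sync_pair",
    "simulate_cd",
    "simulate_assay",
]

#: The titration ladder: 0, 20, ..., 80 uL of 1e-3 M stock into nominal 3.0 mL.
STUDY_LADDER_M = tuple(1e-3 * v * 1e-6 / 3.0e-3 for v in (0, 20, 30, 40, 50, 60, 70, 80))

#: Static-quenching Stern-Volmer constants by temperature (L/mol), decreasing in T.
STUDY_KSV_BY_T = {298.0: 0.50e5, 304.0: 0.49e5, 310.0: 0.40e5}


@dataclass(frozen=True)
class EmissionModel:
    """Ground truth for one emission titration.

    ``f0`` is the ligand-free peak amplitude (a.u.), ``lambda_center`` the
    band position (nm), ``bandwidth`` the Gaussian sigma (nm), ``ksv_true``
    the quenching constant (L/mol), ``shift_at_saturation`` the red shift
    reached at full complexation (nm), ``noise_sigma`` the relative
    multiplicative noise level.
    """

    f0: float = 5000.0
    lambda_center: float = 345.0
    bandwidth: float = 25.0
    ksv_true: float = 5.0e4
    shift_at_saturation: float = 2.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.f0 <= 0 or self.bandwidth <= 0:
            raise DomainError("f0 and bandwidth must be positive")
        if self.noise_sigma < 0:
            raise DomainError("noise_sigma must be >= 0")


@dataclass(frozen=True)
class MechanismScenario:
    """A multi-temperature quenching scenario with a known mechanism."""

    kind: str  # "static" | "dynamic"
    ksv_by_temperature: dict[float, float] = field(
        default_factory=lambda: dict(STUDY_KSV_BY_T)
    )
    tau0: float = TAU0_DEFAULT

    def __post_init__(self) -> None:
        if self.kind not in ("static", "dynamic"):
            raise DataError(f"unknown mechanism kind {self.kind!r}")
        temps = sorted(self.ksv_by_temperature)
        if len(temps) < 2:
            raise DataError("scenario needs >= 2 temperatures")
        ksvs = [self.ksv_by_temperature[t] for t in temps]
        diffs = np.diff(ksvs)
        kqs = np.array(ksvs) / self.tau0
        if self.kind == "static":
            if not (np.all(diffs < 0) and np.all(kqs > KQ_DIFFUSION_LIMIT)):
                raise DataError(
                    "static scenario requires Ksv decreasing in T and "
                    "Ksv/tau0 above the diffusion limit"
                )
        else:
            if not (np.all(diffs > 0) and np.all(kqs < KQ_DIFFUSION_LIMIT)):
                raise DataError(
                    "dynamic scenario requires Ksv increasing in T and "
                    "Ksv/tau0 below the diffusion limit"
                )


def simulate_titration(
    model: EmissionModel,
    concentrations: tuple[float, ...] = STUDY_LADDER_M,
    grid: np.ndarray | None = None,
) -> list[Spectrum]:
    """Generate one emission spectrum per ligand concentration.

    The band is Gaussian; the peak amplitude follows the static-quenching
    law F0 / (1 + Ksv [Q]) and the center red-shifts by
    ``shift_at_saturation * Ksv [Q] / (1 + Ksv [Q])``.  Multiplicative
    Gaussian noise of relative sigma ``model.noise_sigma`` is applied with
    ``model.seed``; the call is deterministic for a fixed seed.
    """
    if 0.0 not in concentrations:
        raise DomainError("concentrations must include 0 (the ligand-free reference)")
    wl = np.arange(300.0, 500.0 + 0.5, 1.0) if grid is None else np.asarray(grid, float)
    rng = np.random.default_rng(model.seed)
    out: list[Spectrum] = []
    for q in concentrations:
        x = model.ksv_true * q
        amp = model.f0 / (1.0 + x)
        center = model.lambda_center + model.shift_at_saturation * x / (1.0 + x)
        sig = amp * np.exp(-0.5 * ((wl - center) / model.bandwidth) ** 2)
        if model.noise_sigma > 0:
            sig = sig * (1.0 + model.noise_sigma * rng.standard_normal(wl.size))
        out.append(Spectrum(wl, sig, {LIGAND_CONC_KEY: repr(float(q)), "temperature_K": ""}))
    return out


def simulate_quench_study(
    scenario: MechanismScenario,
    concentrations: tuple[float, ...] = STUDY_LADDER_M,
    f0: float = 5000.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> dict[float, list[Spectrum]]:
    """Generate per-temperature titrations under one mechanism scenario."""
    study: dict[float, list[Spectrum]] = {}
    for i, (temp, ksv) in enumerate(sorted(scenario.ksv_by_temperature.items())):
        model = EmissionModel(
            f0=f0, ksv_true=ksv, noise_sigma=noise_sigma, seed=seed * 1009 + i
        )
        spectra = simulate_titration(model, concentrations)
        for s in spectra:
            s.meta["temperature_K"] = repr(float(temp))
        study[float(temp)] = spectra
    return study


@dataclass(frozen=True)
class SyncTargets:
    """Zero- and top-concentration band targets for one synchronous offset."""

    delta_lambda: float
    lambda_zero: float
    lambda_top: float
    intensity_zero: float
    intensity_top: float


#: Default targets: Trp band 274 -> 270 nm, 3311 -> 1592 a.u. at the top
#: ligand concentration; Tyr band fixed at 303 nm, 746 -> 400 a.u.
SYNC_TARGETS_TRP = SyncTargets(60.0, 274.0, 270.0, 3311.0, 1592.0)
SYNC_TARGETS_TYR = SyncTargets(15.0, 303.0, 303.0, 746.0, 400.0)


def _sync_series(
    t: SyncTargets,
    concentrations: tuple[float, ...],
    noise_sigma: float,
    rng: np.random.Generator,
    bandwidth: float = 12.0,
) -> SyncSeries:
    wl = np.arange(200.0, 350.0 + 0.5, 1.0)
    qmax = max(concentrations)
    pairs = []
    for q in concentrations:
        frac = 0.0 if qmax == 0 else q / qmax
        center = t.lambda_zero + (t.lambda_top - t.lambda_zero) * frac
        amp = t.intensity_zero + (t.intensity_top - t.intensity_zero) * frac
        sig = amp * np.exp(-0.5 * ((wl - center) / bandwidth) ** 2)
        if noise_sigma > 0:
            sig = sig * (1.0 + noise_sigma * rng.standard_normal(wl.size))
        pairs.append((q, Spectrum(wl, sig, {"delta_lambda_nm": repr(t.delta_lambda)})))
    return SyncSeries(t.delta_lambda, tuple(pairs))


def simulate_sync_pair(
    trp_targets: SyncTargets = SYNC_TARGETS_TRP,
    tyr_targets: SyncTargets = SYNC_TARGETS_TYR,
    concentrations: tuple[float, ...] = STUDY_LADDER_M,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[SyncSeries, SyncSeries]:
    """Generate matched Trp (offset 60 nm) and Tyr (offset 15 nm) series.

    Band centers and amplitudes are interpolated linearly in concentration
    between the zero and top targets, so declines are monotone and the
    endpoints are reproduced exactly in the noiseless case.
    """
    rng = np.random.default_rng(seed)
    trp = _sync_series(trp_targets, concentrations, noise_sigma, rng)
    tyr = _sync_series(tyr_targets, concentrations, noise_sigma, rng)
    return trp, tyr


def simulate_cd(
    fractions: StructureFractions,
    basis: BasisSet | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> CDSpectrum:
    """Generate a CD spectrum as a linear basis mixture plus additive noise.

    ``noise_sigma`` is relative to the peak absolute amplitude of the clean
    mixture.
    """
    basis = basis if basis is not None else default_basis()
    clean = basis.components @ fractions.as_array()
    sig = clean
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        sig = clean + noise_sigma * np.max(np.abs(clean)) * rng.standard_normal(clean.size)
    return CDSpectrum(basis.wavelengths.copy(), sig)


def simulate_assay(
    true_teac: dict[str, float],
    curve: TroloxCurve,
    assay: str = "ABTS",
    noise_sigma: float = 0.0,
    seed: int = 0,
    standard_concs: tuple[float, ...] = (5.0, 10.0, 20.0, 40.0),
) -> tuple[list[AssayRead], list[tuple[float, float]]]:
    """Generate assay reads for samples of known TEAC plus a standard series.

    Each sample's response comes off the Trolox curve and is inverted into
    the absorbance roles of the assay; noise is multiplicative on the
    responses of both samples and standards.
    """
    if assay not in ("ABTS", "DPPH", "FRAP"):
        raise DataError(f"unknown assay {assay!r}")
    rng = np.random.default_rng(seed)

    def _noisy(value: float) -> float:
        if noise_sigma <= 0:
            return value
        return value * (1.0 + noise_sigma * float(rng.standard_normal()))

    reads: list[AssayRead] = []
    for sample_id, teac in true_teac.items():
        resp = _noisy(curve.slope * teac + curve.intercept)
        if assay == "ABTS":
            a0 = 0.70
            absorb = {"A0": a0, "A1": a0 * (1.0 - resp / 100.0)}
        elif assay == "DPPH":
            ab, ac = 0.90, 0.05
            absorb = {"Ab": ab, "At": ab * (1.0 - resp / 100.0) - ac, "Ac": ac}
        else:  # FRAP: reducing power is the response itself
            a1, a0 = 0.10, 0.05
            absorb = {"At": resp + a1 + a0, "A1": a1, "A0": a0}
        reads.append(AssayRead(assay=assay, absorbances=absorb, sample_id=sample_id))
    standards = [
        (c, _noisy(curve.slope * c + curve.intercept)) for c in standard_concs
    ]
    return reads, standards
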