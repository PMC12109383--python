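"""Write a complete synthetic study dataset to disk.

The default scenario emulates the full wet-lab design: static-quenching
emission titrations at 298/304/310 K over the 0-26.7 uM ladder,
synchronous Trp/Tyr series, far-UV CD spectra across five protein:ligand
weight ratios, and ABTS/DPPH/FRAP reads with Trolox standard series.
Ground-truth parameters are fixed by the scenario so every analysis stage
is testable offline; see the methods note for the provenance of each
default.
"""

from __future__ import annotations

import csv
from pathlib import Path

from . import simulate as sim
from .antioxidant import TroloxCurve
from .cd import StructureFractions, default_basis, write_basis_csv
from .spectra import write_spectra_long, write_spectrum_csv
from .titration import LIGAND_CONC_KEY

__all__ = ["STUDY_CD_FRACTIONS", "STUDY_TEAC", "write_study_dataset"]

def _frac(helix: float, sheet: float, turn: float, coil: float) -> StructureFractions:
    """Normalize percent compositions (which need not sum to exactly 100)."""
    total = helix + sheet + turn + coil
    return StructureFractions(helix / total, sheet / total, turn / total, coil / total)


#: Ground-truth secondary-structure fractions per protein:ligand weight ratio
#: (percent compositions, renormalized to sum to one).
STUDY_CD_FRACTIONS = {
    "1to0": _frac(18.8, 31.1, 19.2, 30.5),
    "2to1": _frac(8.1, 52.7, 17.3, 28.0),
    "1to1": _frac(7.0, 52.7, 17.0, 28.6),
    "1to2": _frac(6.7, 52.9, 16.8, 28.6),
    "1to4": _frac(6.4, 52.9, 16.7, 28.8),
}

#: Ground-truth TEAC (mg/L Trolox equivalents) per assay and sample.
STUDY_TEAC = {
    "ABTS": {"WP": 9.09, "WP_MH_mid": 17.39, "WP_MH_top": 25.88},
    "DPPH": {"WP": 1.37, "WP_MH_mid": 3.00, "WP_MH_top": 4.65},
    "FRAP": {"WP": 3.75, "WP_MH_mid": 5.50, "WP_MH_top": 7.20},
}

#: Trolox standard curves the assay generator draws from.
STUDY_CURVES = {
    "ABTS": TroloxCurve(slope=1.5, intercept=2.0, response_kind="percent_rate"),
    "DPPH": TroloxCurve(slope=1.5, intercept=2.0, response_kind="percent_rate"),
    "FRAP": TroloxCurve(slope=0.02, intercept=0.05, response_kind="reducing_power"),
}


def write_study_dataset(out_dir, seed: int = 42, noise_sigma: float = 0.01) -> Path:
    """Generate and write every input CSV for a full synthetic study.

    Returns the dataset directory.  Deterministic for a fixed seed.
    """
    root = Path(out_dir)
    (root / "spectra").mkdir(parents=True, exist_ok=True)

    # Emission titrations (static scenario, Ksv decreasing with T).
    scenario = sim.MechanismScenario("static")
    study = sim.simulate_quench_study(scenario, noise_sigma=noise_sigma, seed=seed)
    rows = []
    volumes_uL = (0, 20, 30, 40, 50, 60, 70, 80)
    for temp, spectra in sorted(study.items()):
        for vol, s in zip(volumes_uL, spectra):
            name = f"spectra/em_{int(temp)}K_{vol:02d}uL.csv"
            write_spectrum_csv(s, root / name)
            rows.append((f"T{int(temp)}", temp, vol, name))
    with open(root / "titration_manifest.csv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["series_id", "temperature_K", "added_volume_uL", "spectrum_path"])
        w.writerows(rows)

    # Synchronous Trp/Tyr series.
    trp, tyr = sim.simulate_sync_pair(noise_sigma=noise_sigma, seed=seed + 1)
    for series, name in ((trp, "sync_trp.csv"), (tyr, "sync_tyr.csv")):
        spectra = {}
        for i, (conc, s) in enumerate(series.spectra):
            s.meta[LIGAND_CONC_KEY] = repr(conc)
            spectra[f"c{i}"] = s
        write_spectra_long(spectra, root / name)

    # CD spectra per weight ratio, plus the basis used to build them.
    basis = default_basis()
    write_basis_csv(basis, root / "basis.csv")
    for i, (label, frac) in enumerate(STUDY_CD_FRACTIONS.items()):
        cd = sim.simulate_cd(frac, basis, noise_sigma=noise_sigma, seed=seed + 10 + i)
        with open(root / f"cd_{label}.csv", "w", encoding="utf-8") as fh:
            fh.write("wavelength_nm,signal_mdeg\n")
            for wl, sg in zip(cd.wavelengths, cd.signal):
                fh.write(f"{float(wl)!r},{float(sg)!r}\n")

    # Antioxidant assays and standards.
    with open(root / "assay_reads.csv", "w", newline="", encoding="utf-8") as frd, open(
        root / "trolox_standards.csv", "w", newline="", encoding="utf-8"
    ) as fst:
        wr, ws = csv.writer(frd), csv.writer(fst)
        wr.writerow(["assay", "sample_id", "role", "absorbance"])
        ws.writerow(["assay", "trolox_mg_per_L", "response"])
        for j, (assay, samples) in enumerate(sorted(STUDY_TEAC.items())):
            reads, standards = sim.simulate_assay(
                samples, STUDY_CURVES[assay], assay, noise_sigma, seed + 20 + j
            )
            for read in reads:
                for role, value in sorted(read.absorbances.items()):
                    wr.writerow([assay, read.sample_id, role, repr(value)])
            for conc, resp in standards:
                ws.writerow([assay, conc, repr(resp)])
    return root
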