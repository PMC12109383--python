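"""Synchronous-fluorescence microenvironment analysis of the Trp/Tyr bands.

Peaks, per-concentration intensity declines and the net band-shift call
for the offset-60 (Trp) and offset-15 (Tyr) series, plus the residue
dominance comparison.  Writes results/synchronous.csv.
"""

import warnings
from pathlib import Path

import pandas as pd

from quenchlab.spectra import read_spectra_long
from quenchlab.synchronous import SyncSeries, analyze_sync, compare_contributions
from quenchlab.titration import LIGAND_CONC_KEY

ROOT = Path(__file__).resolve().parents[1]
DATA_DIR = ROOT / "scratch" / "study_data"
RESULTS = ROOT / "results"

if __name__ == "__main__":
    if not (DATA_DIR / "sync_trp.csv").exists():
        raise SystemExit("run analysis/01_simulate.py first")
    RESULTS.mkdir(exist_ok=True)
    summaries = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, offset in (("sync_trp.csv", 60.0), ("sync_tyr.csv", 15.0)):
            spectra = read_spectra_long(DATA_DIR / name)
            pairs = tuple(
                (float(s.meta[LIGAND_CONC_KEY]), s) for s in spectra.values()
            )
            summary = analyze_sync(SyncSeries(offset, pairs))
            summaries[summary.residue_label] = summary
    rows = []
    for label, s in summaries.items():
        for conc, lam, inten, dec in zip(
            s.concentrations, s.lambda_max, s.intensity, s.percent_decline
        ):
            rows.append(
                {
                    "residue": label,
                    "ligand_conc_M": conc,
                    "lambda_max_nm": lam,
                    "intensity_au": inten,
                    "percent_decline": dec,
                }
            )
    pd.DataFrame(rows).to_csv(RESULTS / "synchronous.csv", index=False)
    for label, s in summaries.items():
        print(
            f"{label}: max decline {s.max_decline:.2f}%, "
            f"shift {s.total_shift:+.0f} nm ({s.shift_label})"
        )
    comp = compare_contributions(summaries["Trp"], summaries["Tyr"])
    print(
        f"dominant residue: {comp['intensity_dominant']} by intensity "
        f"(ratio {comp['intensity_ratio']:.2f}), "
        f"{comp['decline_dominant']} by decline"
    )
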