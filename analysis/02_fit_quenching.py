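"""Fit the quenching analyses per temperature and classify the mechanism.

Stern-Volmer slopes give Ksv (and Kq = Ksv/tau0 with tau0 = 1e-8 s); the
double-log plot gives the binding constant Ka and site number n.  The
minimum Kq is compared against the diffusion-controlled limit 2e10
L/mol/s to call static vs dynamic quenching.  Writes
results/quenching_constants.csv and results/mechanism.json.
"""

import dataclasses
import json
import warnings
from pathlib import Path

import pandas as pd

from quenchlab.quenching import classify_mechanism, double_log_fit, stern_volmer_fit
from quenchlab.titration import build_quench_table, read_titration_manifest

ROOT = Path(__file__).resolve().parents[1]
DATA_DIR = ROOT / "scratch" / "study_data"
RESULTS = ROOT / "results"

if __name__ == "__main__":
    if not (DATA_DIR / "titration_manifest.csv").exists():
        raise SystemExit("run analysis/01_simulate.py first")
    RESULTS.mkdir(exist_ok=True)
    by_temp = read_titration_manifest(
        DATA_DIR / "titration_manifest.csv", stock_conc=1e-3, base_volume=3.0e-3
    )
    rows, sv_fits = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for temp in sorted(by_temp):
            table = build_quench_table(by_temp[temp], temp)
            sv = stern_volmer_fit(table)
            dl = double_log_fit(table)
            sv_fits.append(sv)
            rows.append(
                {
                    "temperature_K": temp,
                    "ksv_per_M": sv.ksv,
                    "kq_per_M_s": sv.kq,
                    "r_sv": sv.r,
                    "ka_per_M": dl.ka,
                    "n_sites": dl.n,
                    "r_dl": dl.r,
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "quenching_constants.csv", index=False)
    mech = classify_mechanism(sv_fits)
    (RESULTS / "mechanism.json").write_text(
        json.dumps(dataclasses.asdict(mech), indent=1) + "\n"
    )
    print(df.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
    print(
        f"\nmechanism: {mech.label} "
        f"(min Kq {mech.min_kq:.3g} L/mol/s, Ksv trend {mech.ksv_temperature_trend})"
    )
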