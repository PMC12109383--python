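"""Convert assay absorbances to Trolox-equivalent antioxidant capacities.

Calibrates one Trolox standard curve per assay (ABTS/DPPH/FRAP), computes
each sample's raw response from its absorbance roles and inverts it to
mg/L Trolox equivalents.  Writes results/teac.csv.
"""

from pathlib import Path

import pandas as pd

from quenchlab.antioxidant import AssayRead, assay_response, calibrate_trolox, to_teac

ROOT = Path(__file__).resolve().parents[1]
DATA_DIR = ROOT / "scratch" / "study_data"
RESULTS = ROOT / "results"

if __name__ == "__main__":
    reads_path = DATA_DIR / "assay_reads.csv"
    if not reads_path.exists():
        raise SystemExit("run analysis/01_simulate.py first")
    RESULTS.mkdir(exist_ok=True)
    std_df = pd.read_csv(DATA_DIR / "trolox_standards.csv")
    curves = {
        assay: calibrate_trolox(
            list(zip(grp["trolox_mg_per_L"], grp["response"])),
            "reducing_power" if assay == "FRAP" else "percent_rate",
        )
        for assay, grp in std_df.groupby("assay")
    }
    rows = []
    for (assay, sample), grp in pd.read_csv(reads_path).groupby(["assay", "sample_id"]):
        roles = dict(zip(grp["role"], grp["absorbance"].astype(float)))
        read = AssayRead(assay=assay, absorbances=roles, sample_id=sample)
        result = to_teac(assay_response(read), curves[assay])
        rows.append(
            {
                "assay": assay,
                "sample": sample,
                "raw_response": result.raw_response,
                "teac_mg_L": result.teac,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "teac.csv", index=False)
    print(df.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    for assay, curve in curves.items():
        print(f"{assay} curve: slope {curve.slope:.4g}, r^2 {curve.r_squared:.4f}")
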