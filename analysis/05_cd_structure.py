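"""Estimate secondary-structure composition across protein:ligand ratios.

Each far-UV CD spectrum is deconvolved by nonnegative least squares
against the four-component basis; the first-to-last composition change
tracks the helix-to-sheet conversion induced by ligand binding.  Writes
results/cd_fractions.csv.
"""

from pathlib import Path

import pandas as pd

from quenchlab.cd import composition_delta, deconvolve, read_basis_csv, read_cd_csv

ROOT = Path(__file__).resolve().parents[1]
DATA_DIR = ROOT / "scratch" / "study_data"
RESULTS = ROOT / "results"

if __name__ == "__main__":
    paths = sorted(DATA_DIR.glob("cd_*.csv"))
    if not paths:
        raise SystemExit("run analysis/01_simulate.py first")
    RESULTS.mkdir(exist_ok=True)
    basis = read_basis_csv(DATA_DIR / "basis.csv")
    order = ["1to0", "2to1", "1to1", "1to2", "1to4"]
    fractions = {}
    for path in paths:
        label = path.stem.removeprefix("cd_")
        fractions[label] = deconvolve(read_cd_csv(path), basis)
    rows = [
        {"ratio": label, **{k: v * 100 for k, v in fractions[label].as_dict().items()},
         "residual_norm": fractions[label].residual_norm}
        for label in order
        if label in fractions
    ]
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "cd_fractions.csv", index=False)
    print(df.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
    delta = composition_delta(fractions[order[0]], fractions[order[-1]])
    print(
        "\ncomposition change 1to0 -> 1to4 (percentage points): "
        + ", ".join(f"{k} {v:+.1f}" for k, v in delta.items())
    )
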