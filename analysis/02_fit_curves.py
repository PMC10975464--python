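#!/usr/bin/env python
"""Fit every generated flow curve and classify its saturation regime.

Reads the curves written by 01_generate_curves.py, fits the reduced logistic
to each, reports regime / rate / onset per curve, checks the monotone
plateau shift across the gelling-mixing cycles, and writes a tidy table to
results/fits.csv plus full fit records to results/fits.json.
"""

import json
from pathlib import Path

import pandas as pd

from gelkin.fitting import equilibrium_shift, fit_curve
from gelkin.io import fit_result_to_dict, read_curve

ROOT = Path(__file__).resolve().parents[1]
CURVES = ROOT / "results" / "curves"
RESULTS = ROOT / "results"


def main() -> None:
    rows, records = [], {}
    cycle_results = []
    for path in sorted(CURVES.rglob("*.csv")):
        curve = read_curve(path)
        result = fit_curve(curve)
        rel = path.relative_to(CURVES)
        records[str(rel)] = fit_result_to_dict(result)
        rows.append(
            {
                "curve": str(rel),
                "regime": result.regime,
                "k1_per_s": result.k1_hat,
                "eta_plateau_mPas": result.eta_plateau,
                "t_onset_s": result.t_onset,
                "rmse_mPas": result.rmse,
            }
        )
        if rel.parts[0] == "gelling_mixing_up":
            cycle_results.append(result)
        onset = f"{result.t_onset:7.0f} s" if result.t_onset else "     --"
        k1 = f"{result.k1_hat:.2e}/s" if result.k1_hat else "   --   "
        print(f"{str(rel):55s} {result.regime:15s} k1={k1} onset={onset}")

    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "fits.csv", index=False)
    (RESULTS / "fits.json").write_text(json.dumps(records, indent=2) + "\n")

    if len(cycle_results) >= 2:
        shift = equilibrium_shift(cycle_results)
        print(
            "\ngelling-mixing plateau sequence (mPa·s):",
            [round(p, 2) for p in shift.plateaus],
            "non-decreasing:", shift.non_decreasing,
        )
    print(f"wrote {RESULTS / 'fits.csv'} and fits.json")


if __name__ == "__main__":
    main()
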