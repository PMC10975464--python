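#!/usr/bin/env python
"""Map the dimensionless sol-gel equilibrium over size and shear.

Classifies every (cluster radius, shear rate) pair of a log grid by the sign
of We - Wi for the standard dispersion, writes the table to
results/regime_map.csv, and prints the critical radius per shear rate.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from gelkin.ripening import standard_fluid
from gelkin.weber import classify_regime, critical_radius, weber_number

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    fluid = standard_fluid()
    radii = np.logspace(-8.0, -6.0, 21)  # 10 nm .. 1 um
    shear = np.array([25.0, 50.0, 100.0, 200.0, 400.0])
    rows = []
    for nu in shear:
        for R in radii:
            We = weber_number(R, fluid.eta0, nu, fluid.gamma)
            rows.append(
                {
                    "R_m": R,
                    "nu_per_s": nu,
                    "We": We,
                    "regime": classify_regime(We, Wi=1.0).value,
                }
            )
        print(
            f"nu={nu:5.0f}/s: critical radius "
            f"R* = {critical_radius(fluid.eta0, nu, fluid.gamma):.3e} m"
        )
    table = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "regime_map.csv", index=False)
    counts = table.groupby("regime").size().to_dict()
    print("grid cells per regime:", counts)
    print(f"wrote {RESULTS / 'regime_map.csv'}")


if __name__ == "__main__":
    main()
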