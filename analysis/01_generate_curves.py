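#!/usr/bin/env python
"""Generate the synthetic Couette-viscometry campaign.

Emulates the four experiment families of the study protocol (1-h curves,
30-s sampling, 60/30 rpm) with the documented presets and writes one CSV per
curve under results/curves/<scenario>/, plus a manifest per scenario.
"""

from pathlib import Path

from gelkin.io import write_curves
from gelkin.synth import generate_scenario, preset_spec

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "curves"

SCENARIOS = {
    # sigmoidal gelation onset at 45 degC (1% agar), 60 rpm
    "single_undersaturated": preset_spec("agar1_45C", seed=101),
    # supersaturated relaxation after homogenization (1.5% agar, 50 degC)
    "single_supersaturated": preset_spec("agar1.5_50C", seed=102),
    # the same dispersion at 60 vs 30 rpm: higher shear, lower plateau
    "shear_pair_60_30rpm": preset_spec("agar1_45C", kind="shear_pair", seed=103),
    # flow - 60 min rest - flow: unbounded growth at rest, decay on resumption
    "flow_pause_flow": preset_spec("agar1_45C", kind="flow_pause_flow", seed=104),
    # four gelling-mixing cycles, free-monomer level +10% per cycle
    "gelling_mixing_up": preset_spec(
        "agar1_45C", kind="gelling_mixing_flow", seed=105, n_cycles=4
    ),
    # the hyaluronic-acid blend: kinetics identical to the agar reference
    "blend_agar_hyaluronic": preset_spec("agar1_hyal0.5_45C", seed=101),
}


def main() -> None:
    for name, spec in SCENARIOS.items():
        curves = generate_scenario(spec)
        paths = write_curves(curves, OUT / name, stem=name)
        print(f"{name}: {len(paths)} curve(s), {len(curves[0])} samples each")
    print(f"\nwrote scenario curves under {OUT}")


if __name__ == "__main__":
    main()
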