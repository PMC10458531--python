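#!/usr/bin/env python
"""Full treatment protocol for equal-volume cubic vs. spherical particles.

Runs the default scenario (40 mm diameter tumor, 10 min infusion at
C_max = 10 kg/m^3, then 20 min of field-on heating at f = 200 kHz,
H = 5 kA/m) for both particle shapes and compares peak temperature,
therapeutic-sphere radius r0 (40-45 C band) and destroyed tumor fraction.
Radial snapshots go to results/snapshots_{shape}.csv, the comparison to
results/paired_summary.csv.
"""

import json
from pathlib import Path

import pandas as pd

from ferrotherm.bioheat import simulate
from ferrotherm.scenario import preset_scenario

RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)

rows = {}
for shape in ("sphere", "cube"):
    result = simulate(preset_scenario(f"paper_default_{shape}"))
    result.to_frame().to_csv(RESULTS / f"snapshots_{shape}.csv", index=False,
                             float_format="%.8g")
    rows[shape] = result.summary()

summary = pd.DataFrame({
    shape: {
        "peak_T_C": s["peak_temperature_C"],
        "r0_mm": s["therapeutic_radius_mm"],
        "r_ablative_mm": s["ablative_radius_mm"],
        "damaged_fraction": s["damaged_volume_fraction"],
    }
    for shape, s in rows.items()
}).T
summary.index.name = "shape"
summary.to_csv(RESULTS / "paired_summary.csv")
(RESULTS / "paired_summary.json").write_text(json.dumps(rows, indent=2) + "\n")

print(summary.to_string(float_format=lambda x: f"{x:.3f}"))
print()
cube, sphere = rows["cube"], rows["sphere"]
print("At the same dose and field, the cubic particles heat the tumor to "
      f"{cube['peak_temperature_C']:.1f} C and cover a therapeutic sphere of "
      f"r0 = {cube['therapeutic_radius_mm']:.1f} mm, destroying "
      f"{100 * cube['damaged_volume_fraction']:.1f}% of the tumor volume; "
      "the equal-volume spheres reach only "
      f"{sphere['peak_temperature_C']:.1f} C "
      f"(r0 = {sphere['therapeutic_radius_mm']:.1f} mm).")
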