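#!/usr/bin/env python
"""Therapeutic-sphere radius versus nanoparticle dose, per particle shape.

Sweeps the infusate concentration over dose ratios C/C_max in {0.2 .. 1.0}
for spherical and equal-volume cubic magnetite particles, running the full
infusion + heating protocol at each point, and checks the monotone growth
of r0 with dose.  Table to results/dose_response.csv, checks to
results/dose_monotonicity.json.
"""

import json
from pathlib import Path

import numpy as np

from ferrotherm.metrics import dose_sweep
from ferrotherm.scenario import preset_scenario

RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)

DOSES = [0.2, 0.4, 0.6, 0.8, 1.0]

table = dose_sweep(preset_scenario("paper_default_sphere"), DOSES)
table.to_csv(RESULTS / "dose_response.csv")
checks = table.monotone_in_dose()
(RESULTS / "dose_monotonicity.json").write_text(
    json.dumps({"r0_non_decreasing_in_dose": checks}, indent=2) + "\n")

frame = table.to_frame()
print(frame.to_string(index=False, float_format=lambda x: f"{x:.3f}"))
print()
print(f"r0 non-decreasing with dose: {checks}")
cube_r0 = table.r0[:, table.shapes.index("cube")]
sphere_r0 = table.r0[:, table.shapes.index("sphere")]
print("Cubes dominate spheres at every dose "
      f"(cube r0 >= sphere r0: {bool(np.all(cube_r0 >= sphere_r0))}); "
      "the lowest dose at which the cube reaches the therapeutic band is "
      f"{table.dose_ratios[np.argmax(cube_r0 > 0)]:.1f} C_max, while the "
      "sphere stays below the band at every dose tested."
      if sphere_r0.max() == 0 else "")
if table.failures:
    print("failed runs:", table.failures)
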