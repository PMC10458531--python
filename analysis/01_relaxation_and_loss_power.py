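#!/usr/bin/env python
"""Relaxation channels and loss-power maps for equal-volume cubes vs. spheres.

For the default magnetite particles (8 nm sphere radius, 12.9 nm cube edge)
this script tabulates the Brown/Neel/effective relaxation times and sweeps
the volumetric loss power P(f, H) over the studied field envelope
(100-650 kHz, 0-15 kA/m).  Findings are printed; the dense maps go to
results/slp_map_{sphere,cube}.csv and the relaxation summary to
results/relaxation_summary.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ferrotherm.magnetics import loss_power_density, relaxation_breakdown, slp_map
from ferrotherm.scenario import FieldSpec, preset_scenario

RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)

T_REF = 310.15  # K

scenarios = {shape: preset_scenario(f"paper_default_{shape}")
             for shape in ("sphere", "cube")}

rows = []
for shape, s in scenarios.items():
    rb = relaxation_breakdown(s.particle, T_REF)
    p_clinical = loss_power_density(s.particle, FieldSpec(5e3, 200e3), T_REF)
    rows.append({
        "shape": shape,
        "size_m": s.particle.characteristic_size,
        "tau_brown_s": rb.tau_brown,
        "tau_neel_s": rb.tau_neel,
        "tau_effective_s": rb.tau_effective,
        "two_pi_f_tau_at_200kHz": 2 * np.pi * 200e3 * rb.tau_effective,
        "P_at_200kHz_5kApm_W_per_m3": p_clinical,
    })
summary = pd.DataFrame(rows)
summary.to_csv(RESULTS / "relaxation_summary.csv", index=False)

freqs = np.linspace(100e3, 650e3, 56)
amps = np.linspace(0.0, 15e3, 31)
maps = {shape: slp_map(s.particle, freqs, amps, T_REF)
        for shape, s in scenarios.items()}
for shape, m in maps.items():
    m.to_csv(RESULTS / f"slp_map_{shape}.csv")

ratio = maps["cube"].values[:, 1:] / maps["sphere"].values[:, 1:]
print(summary.to_string(index=False, float_format=lambda x: f"{x:.4g}"))
print()
print("The cube's effective relaxation time sits near the linear-response "
      "optimum at 200 kHz (2*pi*f*tau = "
      f"{summary.loc[summary['shape'] == 'cube', 'two_pi_f_tau_at_200kHz'].iloc[0]:.2f}), "
      "while the sphere relaxes too fast "
      f"(2*pi*f*tau = {summary.loc[summary['shape'] == 'sphere', 'two_pi_f_tau_at_200kHz'].iloc[0]:.3f}).")
print(f"Loss-power advantage cube/sphere over the full map: "
      f"min {ratio.min():.1f}x, max {ratio.max():.1f}x "
      f"(entrywise cube >= sphere: {bool(np.all(ratio >= 1.0))}).")
print(f"Wrote {RESULTS / 'relaxation_summary.csv'} and the two loss-power maps.")
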