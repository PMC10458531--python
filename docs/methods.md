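# Methods

`ferrotherm` simulates magnetic-nanoparticle (MNP) hyperthermia of a
spherical tumor (radius R1) embedded concentrically in healthy tissue
(outer radius R2), with a needle cavity of radius r_n at the centre.  The
model couples five stages, each implemented in its own module and each
individually testable against a degenerate closed form.

## 1. Interstitial flow (`flow`)

The interstitium is a porous medium with Kozeny–Carman permeability
K = ε³d_p²/(180(1−ε)²), where d_p = 10⁻⁴ m is the cellular grain diameter
and ε the interstitial porosity.  Darcy's law εv = −(K/μ)∇P combined with
fluid mass balance ∇·(εv) = Φ_B − Φ_L gives one elliptic equation for the
interstitial pressure P.  Fluid enters across the capillary walls by
Starling filtration

    Φ_B = L_p (S/V) [P_b − P − σ_s (π_b − π_i)]

and leaves through lymphatics, Φ_L = (L_PL S_L/V)(P − P_L), in healthy
tissue only — tumors lack functional lymphatics, which together with their
high L_p produces the characteristic elevated tumor interstitial pressure
(the solver reproduces the exact two-region sinh/cosh closed form to <1%).
A config switch `lymphatic_driver: interstitial|blood` selects the pressure
that drives drainage; the interstitial form is the default, with the
drainage clamped at zero where P < P_L (handled by active-set iteration on
one banded linear solve).  During infusion the needle cavity imposes a
Darcy flux U = Q_v/(π r_n²) on the r_n sphere; note that because U is
defined on the needle cross-section while the cavity area is 4π r_n², the
delivered volume rate is 4 Q_v.  The outer boundary is impermeable.  The
flow equations carry no time derivative, so the field is quasi-steady:
solved once per protocol phase (inlet on / off) and frozen in between.

## 2. Nanoparticle transport (`transport`)

Concentration obeys ∂(εC)/∂t + ∇·(εvC) = ∇·(D*∇C).  The effective
diffusivity ladder:

* bulk Stokes–Einstein D₀ = k_BT/(6πηR), with R the volume-equivalent
  core radius (so equal-volume cubes and spheres share D₀);
* Renkin-type hindrance (1−λ)²(1 − 2.1044λ + 2.089λ³ − 0.948λ⁵) in pores of
  effective diameter d_pore = 100 nm, λ = 2R_H/d_pore ≈ 0.2 with R_H the
  coated radius; divided by the tortuosity τ(ε) = 1/[1 − (2/3)(1+ε)(1−ε)^{2/3}];
* a porosity partition factor 2ε/(3−ε).

Both the (1−λ)² and the (1−λ²) reading of the partition factor are
selectable (`partition_form`), and an extra multiplicative hindrance hook
(`hindrance_extra_factor`) is exposed; defaults are (1−λ)² and 1.  The
tortuosity expression is non-monotone below ε ≈ 0.2 (a shallow maximum);
over the physiological range ε ∈ [0.2, 1] it decreases toward 1.
Boundary conditions: C = C_max at the needle while infusing (configurable
to hold for the whole run), C = 0 at R2, concentration and diffusive-flux
continuity at R1 (automatic from the harmonic-mean face diffusivities).

## 3. Shape-dependent heating (`magnetics`)

Single-domain MNPs in an AC field H cos(2πft) dissipate

    P = μ₀ π f χ″ H²,   χ″ = [μ₀M_s²V/(3k_BT)] · 2πfτ / (1 + (2πfτ)²),

per unit core volume (linear response; no hysteresis or Stoner–Wohlfarth
physics).  The effective relaxation time τ = τ_Nτ_B/(τ_N+τ_B) combines

* Néel reversal τ_N = τ₀(√π/2)e^Γ/√Γ, Γ = KV/(k_BT), and
* Brownian rotation τ_B = 3ηV_H/(k_BT), V_H = V(1+δ/R)³.

Cubes and spheres are compared at equal core volume V: a cube of edge
L = R(4π/3)^{1/3} (≈13 nm for R = 8 nm, ≈16 nm for R = 10 nm) matches the
sphere of radius R.  Shape enters only through (a) the volume-equivalent
radius used in V_H and D₀ and (b) a shape-specific effective anisotropy
constant; no facet-resolved micromagnetics is attempted.  The tissue heat
source is Q = Φ·P with Φ = C/ρ_MNP the local particle volume fraction.
By default P is evaluated at a fixed 310.15 K (reproducibility); a
`slp_temperature: local` switch re-evaluates χ″ at the evolving local
temperature each coupling step.

## 4. Bioheat and damage (`bioheat`)

Pennes equation per region,

    ρc ∂T/∂t = ∇·(k∇T) + ρ_b c_b ω_b (T_art − T) + Q_met + Q,

with T and k∂T/∂r continuous at R1, T = 37 °C fixed at R2, zero heat flux
at the needle cavity, and T_art = 310.15 K.  Thermal damage accumulates as
the Arrhenius integral Ω(t) = ∫A e^{−E_a/(R_gas T)}dt′; θ = e^{−Ω} is the
surviving tissue fraction and perfusion shuts down with damage,
ω_b = ω₀e^{−Ω}, so heat clearance fails where tissue dies — a positive
feedback on heating.  The damage clock starts when the field turns on:
the shipped liver kinetics pair is fast enough that integrating it from
the infusion start would report appreciable "damage" at baseline body
temperature with no field applied, which is not the quantity of interest.

## 5. Metrics (`metrics`)

The therapeutic sphere radius r0 is the outer radius of the contiguous
region, starting at the needle, whose temperature lies in the hyperthermic
band 40–45 °C at the end of heating.  If a supra-band core (T > 45 °C)
exists it is excluded and reported separately as r_ablative, keeping r0
well defined; `r0_mode: ge_lower` instead defines r0 by T ≥ 40 °C alone.
Crossings are located by linear interpolation between cell centres.  The
damaged volume fraction integrates the θ < 0.5 region (threshold
configurable) exactly over the interpolated profile, relative to the tumor
volume minus the needle cavity.  `dose_sweep` scales C_max by dose ratios
in (0, 1] and repeats the full protocol per (dose, shape).

## Parameter defaults and provenance

Vascular/thermal constants are standard liver-tissue literature values:
L_p = 2.8×10⁻⁷ (tumor) / 0.36×10⁻⁷ (healthy) cm·mmHg⁻¹s⁻¹, lymphatic
coefficient 5×10⁻⁵ mmHg⁻¹s⁻¹ (healthy only), P_b = 15.6 mmHg,
π_i = 15/10 mmHg, σ_s = 0.82/0.91, P_L = 0; ρ = 1160/1060 kg/m³,
c = 3600 J/(kg·K), k = 0.4692/0.512 W/(m·K), Q_met = 5790/700 W/m³,
ω₀ = 0.0064 s⁻¹, blood ρ_b = 1000, c_b = 4180.  1 mmHg = 133.322 Pa
everywhere; converters live in `constants.py` and nowhere else.

Values the source tables do not pin down are set once here, all
configurable:

* **Porosities** ε₁ = 0.40 (tumor), ε₂ = 0.20 (healthy) — typical
  interstitial volume fractions in tumor-transport modelling.
* **Plasma oncotic pressure** π_b = 20 mmHg; **S/V** = 200 cm⁻¹ both
  regions — standard values for perfused soft tissue.
* **Magnetite magnetics**: M_s = 4.46×10⁵ A/m, τ₀ = 10⁻⁹ s, δ = 2 nm,
  η = 10⁻³ Pa·s, ρ_MNP = 5180 kg/m³.  Sphere anisotropy K = 9×10³ J/m³
  (bulk magnetocrystalline value); cube effective anisotropy
  K = 1.6×10⁴ J/m³, i.e. the shape/surface-enhanced barrier placed near
  the linear-response optimum at the clinical frequency: with the default
  8 nm core it puts 2πfτ ≈ 0.9 at 200 kHz, against 0.047 for the sphere.
  This is what makes the equal-volume cube the stronger heater across the
  whole 100–650 kHz band (entrywise, verified by sweep) — the physical
  narrative being that nanocube synthesis tunes the effective barrier into
  the useful window while small spheres relax too fast.
* **Core size**: sphere radius R = 8 nm, the lower end of the 8–10 nm
  design range.  At R = 10 nm the *sphere* already sits at the
  susceptibility optimum at 200 kHz, and no larger cube anisotropy can
  improve on it within linear response; the cube-advantage regime that
  motivates the comparison exists for the smaller core.
* **Arrhenius kinetics**: A = 7.39×10³⁹ s⁻¹, E_a = 2.577×10⁵ J/mol — the
  standard liver protein-denaturation pair (half-survival ≈ 355 s at 43 °C).
* **Infusion protocol**: Q_v = 5 µL/min through a r_n = 0.2 mm needle for
  600 s at C_max = 10 kg/m³ (= 10 mg/cm³, the maximum clinically accepted
  concentration), followed by 1200 s of field-on heating at f = 200 kHz,
  H = 5 kA/m.  Geometry R1 = 20 mm, R2 = 60 mm (far field, fixed 37 °C).

## Discretization and numerics

One conservative finite-volume grid on [r_n, R2] serves all fields: cells
are spherical shells, near-uniform, with a face placed exactly at R1 so
every cell has uniform material properties; face coefficients use
distance-weighted harmonic means, which makes flux/temperature continuity
at the interface a property of the scheme rather than an extra condition.
Default 300 cells.

Time stepping is fixed-substep backward Euler (banded solves) with
first-order upwinded convection: an M-matrix scheme, so C ≥ 0 for any step
size, the discrete maximum principle holds for T, and interior mass/energy
budgets close to round-off.  Default substeps: 1 s for transport, 0.25 s
for temperature.  The thermal substep follows from the truncation error of
backward Euler on the perfusion relaxation time ρc/(ρ_b c_b ω₀) ≈ 156 s:
the relative error ≈ 2.5·dt/τ stays below 0.1%, comfortably inside the
0.5% oracle band.  The stages are operator-split per coupling interval
(default 5 s): transport → heat source → temperature → damage, with
perfusion frozen at ω₀e^{−Ω} of the incoming state.  The flow problem is
one banded linear solve (plus active-set iteration if the lymphatic clamp
engages, capped at 50 sweeps); when no pressure-dependent term exists the
singular pure-Neumann system is pinned by a zero reference pressure at the
outer cell.  Measured spatial orders (Richardson triplets): 2.0 for
conduction and the pressure field, 1.9 for transient diffusion, ≈1.4
pre-asymptotic (limit 1) for upwinded advection.  Everything is
deterministic: identical scenarios give bit-identical results.

Problem sizes used by the shipped analyses and tests — 300 cells, 600 s
infusion, 1200 s heating, 5-dose × 2-shape sweeps — run in seconds on one
CPU; they are the package's chosen desk scale, and all resolution and
duration knobs live in the `numerics` config block.

## What the synthetic fixtures do and do not show

The fixtures module generates every test input: analytic conduction
profiles (verified to satisfy their PDE symbolically, residual < 10⁻¹⁰),
Gaussian concentration pulses with closed-form masses, and a switch-off
matrix of degenerate scenarios (no flow / no diffusion / no perfusion /
no field / no damage / uniform medium).  Passing these suites shows the
solvers integrate the stated equations correctly and that the qualitative
orderings follow from the model at the shipped defaults.  It does not
validate the model against tissue: real tumors are not spherically
symmetric, perfusion is heterogeneous, particles aggregate and bind
(neither is modelled), magnetophoresis under the applied field is
neglected, and the linear-response loss power underestimates heating of
strongly hysteretic particles at high field amplitude.

## Known limitations

* Strict 1-D spherical symmetry; no patient geometry, no discrete vessels.
* Linear-response magnetics only; invalid where μ₀M_sVH/(k_BT) ≳ 1.
* No particle binding, uptake, aggregation, or field-driven drift.
* Constant tissue properties; no temperature dependence of k or μ, no
  phase change above 45 °C.
* The loss-power magnitudes depend on anisotropy constants that are
  material- and synthesis-specific; the shipped values support shape
  *comparisons*, not absolute dosimetry for a particular particle batch.
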