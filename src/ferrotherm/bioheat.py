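"""Pennes bioheat transfer with nanoparticle heating and Arrhenius damage.

Temperature in each tissue region obeys the Pennes equation

    rho_i c_i dT/dt = div(k_i grad T) + rho_b c_b omega_ib (T_art - T)
                      + Q_met,i + Q_i,

where the nanoparticle source is Q = Phi * P: the local particle volume
fraction times the volumetric loss power of the particle material in the
applied AC field.  Thermal damage accumulates as the Arrhenius integral
Omega(t) = int A exp(-E_a / (R T)) dt'; theta = exp(-Omega) is the surviving
(undamaged) tissue fraction, and perfusion shuts down with damage as
omega_ib = omega_i0 exp(-Omega) - heat clearance fails where tissue dies.

The spatial scheme is the same conservative finite-volume discretization as
the transport module (harmonic-mean face conductivities, so temperature and
flux continuity at the tissue interface hold by construction); time
stepping is fixed-substep backward Euler, which preserves the discrete
maximum principle.  `simulate` runs the full two-phase treatment protocol:
ferrofluid infusion (field off), then AC-field heating with continued
diffusion, damage accumulation and perfusion feedback.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve_banded

from .constants import kelvin_to_celsius
from .flow import solve_flow
from .grid import RadialGrid
from .magnetics import loss_power_density
from .scenario import DamageParams, Scenario, validate_scenario
from .transport import (
    ConcentrationState,
    advance_concentration,
    diffusivity_set,
    volume_fraction,
)

__all__ = [
    "ThermalState",
    "SimulationResult",
    "mnp_heat_source",
    "arrhenius_rate",
    "update_damage",
    "damage_adjusted_perfusion",
    "advance_temperature",
    "steady_temperature",
    "simulate",
]


@dataclass
class ThermalState:
    grid: RadialGrid
    temperature: np.ndarray  # K per cell
    damage: np.ndarray  # Omega, dimensionless per cell
    time: float  # s

    @property
    def undamaged_fraction(self) -> np.ndarray:
        """theta = exp(-Omega), the surviving tissue fraction."""
        return np.exp(-self.damage)


def mnp_heat_source(phi, loss_power) -> np.ndarray:
    """Tissue heat source Q = Phi * P (W/m^3)."""
    phi = np.asarray(phi, dtype=float)
    if np.any(phi < 0) or np.any(np.asarray(loss_power) < 0):
        raise ValueError("volume fraction and loss power must be non-negative")
    return phi * loss_power


def arrhenius_rate(damage: DamageParams, temperature):
    """Damage accumulation rate k(T) = A exp(-E_a / (R T)), 1/s."""
    t = np.asarray(temperature, dtype=float)
    if np.any(t <= 0):
        raise ValueError("temperature must be positive")
    return damage.frequency_factor * np.exp(
        -damage.activation_energy / (damage.gas_constant * t))


def update_damage(state: ThermalState, damage: DamageParams, dt: float) -> ThermalState:
    """Rectangle-rule step of the Arrhenius integral: Omega += k(T) dt."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    new_omega = state.damage + arrhenius_rate(damage, state.temperature) * dt
    return ThermalState(grid=state.grid, temperature=state.temperature,
                        damage=new_omega, time=state.time + dt)


def damage_adjusted_perfusion(baseline_rate, damage_index):
    """Perfusion with thermal shutdown: omega = omega_0 exp(-Omega)."""
    omega0 = np.asarray(baseline_rate, dtype=float)
    if np.any(omega0 < 0):
        raise ValueError("baseline perfusion rate must be non-negative")
    return omega0 * np.exp(-np.asarray(damage_index, dtype=float))


# --------------------------------------------------------------------------
# Pennes finite-volume system
# --------------------------------------------------------------------------

class _PennesSystem:
    """Precomputed geometry/material arrays for the radial Pennes operator."""

    def __init__(self, scenario: Scenario, grid: RadialGrid):
        self.grid = grid
        self.scenario = scenario
        tt, ht = scenario.tumor.thermal, scenario.healthy.thermal
        self.rho_c = grid.per_cell(tt.mass_density * tt.specific_heat,
                                   ht.mass_density * ht.specific_heat)
        self.k_cells = grid.per_cell(tt.thermal_conductivity, ht.thermal_conductivity)
        self.q_met = grid.per_cell(tt.metabolic_heat, ht.metabolic_heat)
        self.omega0 = grid.per_cell(tt.baseline_perfusion_rate,
                                    ht.baseline_perfusion_rate)
        self.rho_cb = scenario.blood.mass_density * scenario.blood.specific_heat
        self.t_art = scenario.blood.arterial_temperature
        self.t_boundary = scenario.blood.arterial_temperature  # outer Dirichlet

        c, e = grid.centers, grid.edges
        areas = grid.face_areas
        d_left = e[1:-1] - c[:-1]
        d_right = c[1:] - e[1:-1]
        with np.errstate(divide="ignore"):
            resist = (np.where(self.k_cells[:-1] > 0,
                               d_left / np.where(self.k_cells[:-1] > 0,
                                                 self.k_cells[:-1], 1.0), np.inf)
                      + np.where(self.k_cells[1:] > 0,
                                 d_right / np.where(self.k_cells[1:] > 0,
                                                    self.k_cells[1:], 1.0), np.inf))
        self.g_face = np.where(np.isfinite(resist), areas[1:-1] / resist, 0.0)
        self.g_outer = (areas[-1] * self.k_cells[-1] / (e[-1] - c[-1])
                        if self.k_cells[-1] > 0 else 0.0)
        self.volumes = grid.cell_volumes

    def step(self, temperature: np.ndarray, heat_source: np.ndarray,
             perfusion: np.ndarray, dt: float, n_substeps: int) -> np.ndarray:
        """Backward-Euler march of n_substeps over dt (total)."""
        n = self.grid.n_cells
        sub_dt = dt / n_substeps
        vol = self.volumes
        cap = self.rho_c * vol / sub_dt
        perf = self.rho_cb * perfusion * vol

        diag = cap.copy()
        lower = np.zeros(n)
        upper = np.zeros(n)
        diag[:-1] += self.g_face
        diag[1:] += self.g_face
        upper[1:] = -self.g_face
        lower[:-1] = -self.g_face
        diag += perf
        diag[-1] += self.g_outer
        rhs_const = (perf * self.t_art + vol * (self.q_met + heat_source))
        rhs_const[-1] += self.g_outer * self.t_boundary
        ab = np.zeros((3, n))
        ab[0], ab[1], ab[2] = upper, diag, lower

        t = temperature.astype(float).copy()
        for _ in range(n_substeps):
            t = solve_banded((1, 1), ab, cap * t + rhs_const)
        return t

    def steady(self, heat_source: np.ndarray, perfusion: np.ndarray) -> np.ndarray:
        """Direct steady-state solve (time-derivative term dropped)."""
        n = self.grid.n_cells
        vol = self.volumes
        perf = self.rho_cb * perfusion * vol
        diag = np.zeros(n)
        lower = np.zeros(n)
        upper = np.zeros(n)
        diag[:-1] += self.g_face
        diag[1:] += self.g_face
        upper[1:] = -self.g_face
        lower[:-1] = -self.g_face
        diag += perf
        diag[-1] += self.g_outer
        rhs = perf * self.t_art + vol * (self.q_met + heat_source)
        rhs[-1] += self.g_outer * self.t_boundary
        if np.all(diag == 0.0):
            raise RuntimeError("steady thermal system is singular")
        ab = np.zeros((3, n))
        ab[0], ab[1], ab[2] = upper, diag, lower
        return solve_banded((1, 1), ab, rhs)


def advance_temperature(state: ThermalState, heat_source, scenario: Scenario,
                        dt: float) -> ThermalState:
    """Advance T by dt with frozen source and damage-adjusted perfusion.

    Substep size is `scenario.numerics.thermal_dt`; perfusion uses the
    damage index of the incoming state, frozen over the step (the damage
    integral advances separately via :func:`update_damage`).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    q = np.broadcast_to(np.asarray(heat_source, dtype=float),
                        (state.grid.n_cells,))
    system = _PennesSystem(scenario, state.grid)
    omega = damage_adjusted_perfusion(system.omega0, state.damage)
    n_sub = max(1, math.ceil(dt / scenario.numerics.thermal_dt))
    t_new = system.step(state.temperature, q, omega, dt, n_sub)
    return ThermalState(grid=state.grid, temperature=t_new,
                        damage=state.damage, time=state.time + dt)


def steady_temperature(scenario: Scenario, grid: RadialGrid, heat_source=0.0,
                       damage_index=0.0) -> np.ndarray:
    """Steady Pennes temperature for a frozen source and damage field."""
    system = _PennesSystem(scenario, grid)
    q = np.broadcast_to(np.asarray(heat_source, dtype=float), (grid.n_cells,))
    omega = damage_adjusted_perfusion(
        system.omega0, np.broadcast_to(np.asarray(damage_index, dtype=float),
                                       (grid.n_cells,)))
    return system.steady(q, omega)


# --------------------------------------------------------------------------
# full treatment simulation
# --------------------------------------------------------------------------

@dataclass
class SimulationResult:
    scenario: Scenario
    grid: RadialGrid
    snapshot_times: np.ndarray  # s
    temperature: np.ndarray  # (n_snapshots, n_cells), K
    concentration: np.ndarray  # (n_snapshots, n_cells), kg/m^3
    undamaged_fraction: np.ndarray  # (n_snapshots, n_cells)
    peak_temperature: float  # K, max over space and time
    therapeutic_radius: float  # r0, m, at end of heating
    ablative_radius: float  # m
    damaged_fraction: float  # of tumor volume
    r0_series: np.ndarray = field(default=None)  # r0 at each snapshot, m

    @property
    def final_temperature(self) -> np.ndarray:
        return self.temperature[-1]

    def to_frame(self) -> pd.DataFrame:
        """Long-format radial snapshots: time_s, r_m, T_C, C_kg_per_m3, theta."""
        frames = []
        for i, t in enumerate(self.snapshot_times):
            frames.append(pd.DataFrame({
                "time_s": t,
                "r_m": self.grid.centers,
                "T_C": kelvin_to_celsius(self.temperature[i]),
                "C_kg_per_m3": self.concentration[i],
                "theta": self.undamaged_fraction[i],
            }))
        return pd.concat(frames, ignore_index=True)

    def summary(self) -> dict:
        return {
            "peak_temperature_C": kelvin_to_celsius(self.peak_temperature),
            "therapeutic_radius_mm": self.therapeutic_radius * 1e3,
            "ablative_radius_mm": self.ablative_radius * 1e3,
            "damaged_volume_fraction": self.damaged_fraction,
            "r0_series_mm": [float(r) * 1e3 for r in self.r0_series],
            "snapshot_times_s": [float(t) for t in self.snapshot_times],
        }


def _loss_power_field(scenario: Scenario, temperature: np.ndarray) -> np.ndarray:
    """P per cell: fixed-temperature scalar by default, local-T otherwise."""
    num = scenario.numerics
    if num.slp_temperature == "fixed":
        p = loss_power_density(scenario.particle, scenario.field,
                               num.slp_fixed_temperature)
        return np.full_like(temperature, p)
    return np.array([
        loss_power_density(scenario.particle, scenario.field, t)
        for t in temperature
    ])


def simulate(scenario: Scenario) -> SimulationResult:
    """Run the two-phase treatment protocol and derive the summary metrics.

    Phase 1 (infusion, field off): quasi-steady flow with the needle inlet
    active; concentration advances by convection-diffusion with C = C_max
    held at the needle; temperature relaxes with no particle source; no
    damage accumulates.  Phase 2 (heating): inlet off, flow re-solved;
    particles keep diffusing; each coupling step computes Q = Phi*P,
    advances T, then the Arrhenius damage and the perfusion shutdown.
    Deterministic: identical scenarios produce identical results.
    """
    problems = validate_scenario(scenario)
    if problems:
        raise ValueError("invalid scenario: " + "; ".join(problems))
    from . import metrics  # lazy: metrics.dose_sweep drives simulate

    num = scenario.numerics
    grid = RadialGrid.make(scenario.infusion.needle_radius, scenario.tumor_radius,
                           scenario.domain_radius, num.cell_count)
    eps_cells = grid.per_cell(scenario.tumor.vascular.porosity,
                              scenario.healthy.vascular.porosity)
    diff = diffusivity_set(scenario)
    d_cells = grid.per_cell(diff.effective_tumor, diff.effective_healthy)
    system = _PennesSystem(scenario, grid)

    t_now = 0.0
    conc = ConcentrationState(grid=grid, concentration=np.zeros(grid.n_cells), time=0.0)
    thermal = ThermalState(grid=grid,
                           temperature=np.full(grid.n_cells,
                                               scenario.blood.arterial_temperature),
                           damage=np.zeros(grid.n_cells), time=0.0)

    snap_times = [0.0]
    snap_t = [thermal.temperature.copy()]
    snap_c = [conc.concentration.copy()]
    snap_theta = [thermal.undamaged_fraction.copy()]
    r0_series = [0.0]
    peak = float(thermal.temperature.max())

    def record(force=False):
        nonlocal peak
        peak = max(peak, float(thermal.temperature.max()))
        due = (t_now - snap_times[-1]) >= num.snapshot_interval - 1e-9
        if force or due:
            snap_times.append(t_now)
            snap_t.append(thermal.temperature.copy())
            snap_c.append(conc.concentration.copy())
            snap_theta.append(thermal.undamaged_fraction.copy())
            r0, _ = metrics.therapeutic_radius(
                grid.centers, thermal.temperature, scenario.therapeutic_band,
                inner_radius=grid.inner_radius, mode=num.r0_mode)
            r0_series.append(r0)

    def run_phase(duration, flow, inner_value, heating):
        nonlocal t_now, conc, thermal
        if duration <= 0:
            return
        remaining = duration
        loss_p = None
        while remaining > 1e-9:
            dt = min(num.coupling_dt, remaining)
            n_sub_c = max(1, math.ceil(dt / num.transport_dt))
            conc = advance_concentration(conc, flow, d_cells, eps_cells, dt,
                                         inner_dirichlet_value=inner_value,
                                         outer_dirichlet_value=0.0,
                                         n_substeps=n_sub_c)
            if heating and scenario.field.amplitude > 0:
                if loss_p is None or num.slp_temperature == "local":
                    loss_p = _loss_power_field(scenario, thermal.temperature)
                q = mnp_heat_source(
                    volume_fraction(conc.concentration, scenario.particle), loss_p)
            else:
                q = np.zeros(grid.n_cells)
            omega = damage_adjusted_perfusion(system.omega0, thermal.damage)
            n_sub_t = max(1, math.ceil(dt / num.thermal_dt))
            t_new = system.step(thermal.temperature, q, omega, dt, n_sub_t)
            new_damage = thermal.damage
            if heating:
                new_damage = thermal.damage + arrhenius_rate(
                    scenario.damage, t_new) * dt
            thermal = ThermalState(grid=grid, temperature=t_new,
                                   damage=new_damage, time=thermal.time + dt)
            t_now += dt
            remaining -= dt
            record()

    # phase 1: infusion
    if scenario.infusion.infusion_duration > 0:
        flow_inf = solve_flow(scenario, grid, infusing=True)
        run_phase(scenario.infusion.infusion_duration, flow_inf,
                  inner_value=scenario.infusion.max_concentration, heating=False)
        record(force=t_now > snap_times[-1])

    # phase 2: heating (inlet off); particles keep diffusing
    flow_heat = solve_flow(scenario, grid, infusing=False)
    inner_value = (scenario.infusion.max_concentration
                   if num.inner_dirichlet == "always" else None)
    run_phase(num.heating_duration, flow_heat, inner_value=inner_value, heating=True)
    record(force=t_now > snap_times[-1])

    r0, r_abl = metrics.therapeutic_radius(
        grid.centers, thermal.temperature, scenario.therapeutic_band,
        inner_radius=grid.inner_radius, mode=num.r0_mode)
    damaged = metrics.damaged_volume_fraction(
        thermal.undamaged_fraction, grid, num.damage_threshold,
        scenario.tumor_radius)

    return SimulationResult(
        scenario=scenario, grid=grid,
        snapshot_times=np.asarray(snap_times),
        temperature=np.vstack(snap_t),
        concentration=np.vstack(snap_c),
        undamaged_fraction=np.vstack(snap_theta),
        peak_temperature=peak,
        therapeutic_radius=r0,
        ablative_radius=r_abl,
        damaged_fraction=damaged,
        r0_series=np.asarray(r0_series),
    )
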