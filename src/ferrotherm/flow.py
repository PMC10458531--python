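"""Quasi-steady interstitial Darcy flow with Starling filtration.

The interstitium is a porous medium: Darcy's law links the interstitial
fluid velocity v to the pressure gradient through the permeability
K = eps^3 d_p^2 / (180 (1-eps)^2) (Kozeny-Carman, with d_p the cellular
grain diameter).  Fluid is produced by transvascular Starling filtration

    Phi_B = L_p (S/V) [P_b - P - sigma_s (pi_b - pi_i)]

and removed by lymphatic drainage (healthy tissue only; tumors lack
functional lymphatics).  Mass balance div(eps v) = Phi_B - Phi_L with
eps v = -(K/mu) grad P gives one linear elliptic equation for P; during
infusion the needle cavity drives a prescribed Darcy flux, and the outer
boundary is impermeable.

Because the flow equations carry no time derivative the field is
quasi-steady: it is solved once per protocol phase (infusing / not) and
frozen in between.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import solve_banded

from .grid import RadialGrid
from .scenario import InfusionSpec, Scenario, VascularParams

__all__ = [
    "FlowField",
    "permeability",
    "starling_source",
    "lymphatic_sink",
    "needle_inlet_velocity",
    "solve_flow",
]

_MAX_CLAMP_ITERATIONS = 50


def permeability(porosity: float, grain_diameter: float) -> float:
    """Kozeny-Carman permeability K = eps^3 d_p^2 / (180 (1 - eps)^2), m^2."""
    if not 0.0 < porosity < 1.0:
        raise ValueError(f"porosity must lie in (0, 1) (got {porosity})")
    if grain_diameter <= 0:
        raise ValueError(f"grain diameter must be positive (got {grain_diameter})")
    return porosity**3 * grain_diameter**2 / (180.0 * (1.0 - porosity) ** 2)


def starling_source(vascular: VascularParams, pressure):
    """Transvascular filtration rate Phi_B in 1/s; negative = reabsorption."""
    lp_sv = vascular.hydraulic_conductivity * vascular.vessel_area_density
    drive = (vascular.blood_pressure - np.asarray(pressure, dtype=float)
             - vascular.reflection_coefficient
             * (vascular.plasma_oncotic_pressure
                - vascular.interstitial_oncotic_pressure))
    return lp_sv * drive


def lymphatic_sink(vascular: VascularParams, pressure, driver: str = "interstitial"):
    """Lymphatic drainage rate Phi_L in 1/s (zero wherever lymphatics are absent).

    ``driver`` selects the pressure that drives drainage: the local
    interstitial pressure (``"interstitial"``, clamped at zero so lymphatics
    never act as a source) or the printed constant blood-pressure form
    (``"blood"``).
    """
    p = np.asarray(pressure, dtype=float)
    if vascular.lymphatic_coefficient == 0.0:
        return np.zeros_like(p)
    if driver == "interstitial":
        return vascular.lymphatic_coefficient * np.maximum(
            p - vascular.lymphatic_pressure, 0.0)
    if driver == "blood":
        return np.full_like(p, vascular.lymphatic_coefficient
                            * (vascular.blood_pressure - vascular.lymphatic_pressure))
    raise ValueError(f"unknown lymphatic driver {driver!r}")


def needle_inlet_velocity(infusion: InfusionSpec) -> float:
    """Inlet velocity U = Q_v / (pi r_n^2), m/s."""
    if infusion.needle_radius <= 0:
        raise ValueError("needle radius must be positive")
    if infusion.infusion_rate < 0:
        raise ValueError("infusion rate must be non-negative")
    return infusion.infusion_rate / (np.pi * infusion.needle_radius**2)


@dataclass
class FlowField:
    """Solved interstitial pressure/velocity state on a radial grid.

    ``darcy_flux`` is the superficial flux q = eps*v at every face (positive
    outward); it is the quantity that is continuous across the tissue
    interface and the one the transport solver advects with.
    """

    grid: RadialGrid
    pressure: np.ndarray  # Pa, per cell
    darcy_flux: np.ndarray  # m/s, per face (N+1)
    source: np.ndarray  # 1/s, per cell: Phi_B - Phi_L at the solution

    @property
    def velocity(self) -> np.ndarray:
        """Interstitial velocity v = q/eps at faces, using the inner-side cell."""
        eps = self._eps
        face_eps = np.concatenate([[eps[0]], eps])
        return self.darcy_flux / face_eps

    _eps: np.ndarray = None  # per-cell porosity, set by solve_flow

    def mass_balance_residual(self) -> float:
        """Global conservation defect, relative to the total source activity.

        Net volumetric outflow through the boundaries minus the integrated
        interior source, scaled by the total absolute source strength (or
        the inlet rate when sources vanish).
        """
        areas = self.grid.face_areas
        boundary_net = (self.darcy_flux[-1] * areas[-1]
                        - self.darcy_flux[0] * areas[0])
        integrated = float(np.sum(self.source * self.grid.cell_volumes))
        scale = max(float(np.sum(np.abs(self.source) * self.grid.cell_volumes)),
                    abs(self.darcy_flux[0] * areas[0]), 1e-300)
        return abs(boundary_net - integrated) / scale

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "r_m": self.grid.centers,
            "P_Pa": self.pressure,
            "v_m_per_s": 0.5 * (self.velocity[:-1] + self.velocity[1:]),
            "source_per_s": self.source,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _cell_properties(scenario: Scenario, grid: RadialGrid):
    tum, hea = scenario.tumor.vascular, scenario.healthy.vascular
    mu = (scenario.numerics.flow_viscosity
          if scenario.numerics.flow_viscosity is not None
          else scenario.particle.carrier_viscosity)
    k_cells = grid.per_cell(permeability(tum.porosity, tum.grain_diameter),
                            permeability(hea.porosity, hea.grain_diameter))
    eps_cells = grid.per_cell(tum.porosity, hea.porosity)
    return k_cells / mu, eps_cells


def _face_transmissibility(grid: RadialGrid, mobility_cells: np.ndarray) -> np.ndarray:
    """Two-point flux coefficients at interior faces: flux = T (P_i - P_{i+1})."""
    c, e, areas = grid.centers, grid.edges, grid.face_areas
    d_left = e[1:-1] - c[:-1]
    d_right = c[1:] - e[1:-1]
    resistance = d_left / mobility_cells[:-1] + d_right / mobility_cells[1:]
    return areas[1:-1] / resistance


def solve_flow(scenario: Scenario, grid: RadialGrid, infusing: bool = True) -> FlowField:
    """Solve the quasi-steady pressure problem and return the flow field.

    The Starling term is linear in P, so the problem is one banded linear
    solve; the lymphatic clamp (drainage shuts off where P < P_L) is handled
    by active-set iteration, which almost always converges in one pass.
    With no pressure-dependent terms at all the operator is singular up to a
    constant; the outer cell is then pinned to a zero reference pressure.
    """
    n = grid.n_cells
    mobility, eps_cells = _cell_properties(scenario, grid)
    trans = _face_transmissibility(grid, mobility)
    volumes = grid.cell_volumes
    areas = grid.face_areas
    tumor_mask = grid.tumor_mask
    driver = scenario.numerics.lymphatic_driver

    vas = [scenario.tumor.vascular, scenario.healthy.vascular]
    lp_sv = grid.per_cell(*[v.hydraulic_conductivity * v.vessel_area_density for v in vas])
    starling_const = grid.per_cell(*[
        v.hydraulic_conductivity * v.vessel_area_density
        * (v.blood_pressure - v.reflection_coefficient
           * (v.plasma_oncotic_pressure - v.interstitial_oncotic_pressure))
        for v in vas])
    lym_coeff = grid.per_cell(*[v.lymphatic_coefficient for v in vas])
    lym_pressure = grid.per_cell(*[v.lymphatic_pressure for v in vas])

    inlet_flux = needle_inlet_velocity(scenario.infusion) if infusing else 0.0
    inflow = inlet_flux * areas[0]

    def assemble_and_solve(lym_active: np.ndarray) -> np.ndarray:
        lower = np.zeros(n)
        diag = np.zeros(n)
        upper = np.zeros(n)
        rhs = np.zeros(n)
        diag[:-1] += trans
        diag[1:] += trans
        upper[1:] = -trans  # solve_banded layout: upper[j] couples row j-1 to j
        lower[:-1] = -trans
        diag += volumes * lp_sv
        rhs += volumes * starling_const + 0.0
        rhs[0] += inflow
        if driver == "interstitial":
            diag += volumes * lym_coeff * lym_active
            rhs += volumes * lym_coeff * lym_active * lym_pressure
        else:  # constant blood-driven drainage
            rhs -= volumes * lym_coeff * (
                grid.per_cell(vas[0].blood_pressure, vas[1].blood_pressure)
                - lym_pressure)
        reaction = volumes * lp_sv + (volumes * lym_coeff * lym_active
                                      if driver == "interstitial" else np.zeros(n))
        if np.all(reaction == 0.0):
            # pure Neumann problem: pin the outer cell to the reference pressure
            diag[-1] += 1.0
        ab = np.zeros((3, n))
        ab[0] = upper
        ab[1] = diag
        ab[2] = lower
        if np.all(ab[1] == 0.0):
            raise RuntimeError("singular flow system: all conductances are zero")
        return solve_banded((1, 1), ab, rhs)

    active = np.ones(n)
    pressure = assemble_and_solve(active)
    if driver == "interstitial" and np.any(lym_coeff > 0):
        for _ in range(_MAX_CLAMP_ITERATIONS):
            new_active = ((pressure >= lym_pressure) | (lym_coeff == 0.0)).astype(float)
            if np.array_equal(new_active, active):
                break
            active = new_active
            pressure = assemble_and_solve(active)
        else:
            raise RuntimeError("lymphatic clamp iteration did not converge")

    flux = np.zeros(n + 1)
    flux[0] = inlet_flux
    flux[1:-1] = trans * (pressure[:-1] - pressure[1:]) / areas[1:-1]
    flux[-1] = 0.0  # impermeable outer boundary (v = 0 at R2)

    source = np.where(
        tumor_mask,
        starling_source(vas[0], pressure) - lymphatic_sink(vas[0], pressure, driver),
        starling_source(vas[1], pressure) - lymphatic_sink(vas[1], pressure, driver),
    )

    field = FlowField(grid=grid, pressure=pressure, darcy_flux=flux, source=source)
    field._eps = eps_cells
    return field
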