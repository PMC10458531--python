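"""Nanoparticle convection-diffusion with hindered, tortuous diffusivity.

The concentration C(r, t) of nanoparticles in the interstitium obeys

    d(eps C)/dt + div(eps v C) = div(D* grad C),

advected by the interstitial Darcy flow and spread by an effective
diffusivity built in three stages:

  * bulk Stokes-Einstein value D0 = kB T / (6 pi eta R_H);
  * Renkin-type hindrance in pores of diameter d_pore, parametrized by the
    particle-to-pore size ratio lambda, divided by the porous-medium
    tortuosity tau(eps);
  * a porosity partition factor 2 eps / (3 - eps).

The update is a conservative finite-volume backward-Euler step with
first-order upwinded convection: an M-matrix scheme, so concentrations stay
non-negative for any step size and interior mass is exact to round-off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import solve_banded

from .constants import BOLTZMANN
from .flow import FlowField
from .grid import RadialGrid
from .scenario import ParticleSpec, Scenario

__all__ = [
    "ConcentrationState",
    "DiffusivitySet",
    "bulk_diffusivity",
    "tortuosity",
    "hindered_diffusivity",
    "diffusivity_set",
    "advance_concentration",
    "volume_fraction",
]


def bulk_diffusivity(temperature: float, viscosity: float, particle_radius: float) -> float:
    """Stokes-Einstein bulk diffusivity D0 = kB T / (6 pi eta R), m^2/s."""
    if temperature <= 0 or viscosity <= 0 or particle_radius <= 0:
        raise ValueError("temperature, viscosity and radius must be positive")
    return BOLTZMANN * temperature / (6.0 * math.pi * viscosity * particle_radius)


def tortuosity(porosity: float) -> float:
    """Porous-medium tortuosity tau >= 1.

    tau = 1 / [1 - (2/3)(1 + eps)(1 - eps)^(2/3)]; equals 1 in the free-fluid
    limit eps = 1 and grows as the pore space closes.
    """
    if not 0.0 < porosity <= 1.0:
        raise ValueError(f"porosity must lie in (0, 1] (got {porosity})")
    denom = 1.0 - (2.0 / 3.0) * (1.0 + porosity) * (1.0 - porosity) ** (2.0 / 3.0)
    if denom <= 0.0:
        raise ValueError(
            f"tortuosity expression breaks down at porosity {porosity} "
            f"(denominator {denom} <= 0)")
    return 1.0 / denom


def _hindrance_polynomial(lam: float, partition_form: str) -> float:
    if not 0.0 <= lam < 1.0:
        raise ValueError(f"size ratio lambda must lie in [0, 1) (got {lam})")
    if partition_form == "squared":
        partition = (1.0 - lam) ** 2
    elif partition_form == "one_minus_sq":
        partition = 1.0 - lam**2
    else:
        raise ValueError(f"unknown partition form {partition_form!r}")
    poly = 1.0 - 2.1044 * lam + 2.089 * lam**3 - 0.948 * lam**5
    return partition * poly


def hindered_diffusivity(bulk: float, lam: float, porosity: float,
                         partition_form: str = "squared",
                         extra_factor: float = 1.0) -> float:
    """Effective interstitial diffusivity D*.

    D_f = partition(lambda) * Renkin(lambda) * D0 / tau(eps) * extra_factor,
    D*  = D_f * 2 eps / (3 - eps).
    """
    d_fluid = _hindrance_polynomial(lam, partition_form) * bulk / tortuosity(porosity)
    d_fluid *= extra_factor
    return d_fluid * 2.0 * porosity / (3.0 - porosity)


@dataclass
class DiffusivitySet:
    """Bulk, fluid-phase and effective diffusivity for both regions (m^2/s)."""

    bulk: float
    fluid_tumor: float
    fluid_healthy: float
    effective_tumor: float
    effective_healthy: float
    size_ratio: float  # lambda actually used


def diffusivity_set(scenario: Scenario, temperature: float | None = None) -> DiffusivitySet:
    """Assemble the diffusivity ladder from a scenario.

    ``lambda`` defaults to 2 R_H / d_pore with R_H the hydrodynamic
    (coated, volume-equivalent) particle radius, unless overridden in the
    numerics block.  ``temperature`` defaults to arterial blood temperature
    (weak thermal coupling of transport).
    """
    num = scenario.numerics
    p = scenario.particle
    if temperature is None:
        temperature = scenario.blood.arterial_temperature
    r_h = p.volume_equivalent_radius + p.surfactant_thickness
    lam = (num.hindrance_lambda if num.hindrance_lambda is not None
           else min(2.0 * r_h / num.pore_diameter, 0.999999))
    bulk = bulk_diffusivity(temperature, p.carrier_viscosity, p.volume_equivalent_radius)

    def fluid(eps):
        return (_hindrance_polynomial(lam, num.partition_form) * bulk
                / tortuosity(eps) * num.hindrance_extra_factor)

    eps_t = scenario.tumor.vascular.porosity
    eps_h = scenario.healthy.vascular.porosity
    ft, fh = fluid(eps_t), fluid(eps_h)
    return DiffusivitySet(
        bulk=bulk,
        fluid_tumor=ft,
        fluid_healthy=fh,
        effective_tumor=ft * 2.0 * eps_t / (3.0 - eps_t),
        effective_healthy=fh * 2.0 * eps_h / (3.0 - eps_h),
        size_ratio=lam,
    )


@dataclass
class ConcentrationState:
    grid: RadialGrid
    concentration: np.ndarray  # kg/m^3 per cell
    time: float  # s

    def total_mass(self, porosity_cells: np.ndarray) -> float:
        """Diagnostic integral of eps*C over the domain, kg."""
        return float(np.sum(porosity_cells * self.concentration
                            * self.grid.cell_volumes))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.time,
            "r_m": self.grid.centers,
            "C_kg_per_m3": self.concentration,
        })


def volume_fraction(concentration, particle: ParticleSpec) -> np.ndarray:
    """Particle volume fraction Phi = C / rho_MNP (dimensionless)."""
    c = np.asarray(concentration, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    return c / particle.mass_density


def advance_concentration(state: ConcentrationState, flow: FlowField,
                          effective_diffusivity: np.ndarray,
                          porosity_cells: np.ndarray,
                          dt: float,
                          inner_dirichlet_value: float | None = None,
                          outer_dirichlet_value: float | None = 0.0,
                          n_substeps: int = 1) -> ConcentrationState:
    """One conservative implicit upwind step (optionally substepped).

    Boundary handling: when ``inner_dirichlet_value`` is given, the needle
    surface holds that concentration (the infusate), feeding both the
    advective inflow q*C_max and a diffusive half-cell flux; when ``None``
    the inner face is sealed.  The outer face is held at
    ``outer_dirichlet_value`` (the far-field sink) unless ``None`` (sealed).
    """
    if dt <= 0 or n_substeps < 1:
        raise ValueError("dt must be positive and n_substeps >= 1")
    grid = state.grid
    n = grid.n_cells
    d_cells = np.broadcast_to(np.asarray(effective_diffusivity, dtype=float), (n,))
    eps = np.asarray(porosity_cells, dtype=float)
    areas = grid.face_areas
    volumes = grid.cell_volumes
    centers, edges = grid.centers, grid.edges

    # interior faces: advective volumetric rate and diffusive conductance
    f_adv = flow.darcy_flux[1:-1] * areas[1:-1]  # m^3/s, positive outward
    d_left = edges[1:-1] - centers[:-1]
    d_right = centers[1:] - edges[1:-1]
    with np.errstate(divide="ignore"):
        resist = np.where(d_cells[:-1] > 0, d_left / np.where(d_cells[:-1] > 0, d_cells[:-1], 1.0), np.inf) \
            + np.where(d_cells[1:] > 0, d_right / np.where(d_cells[1:] > 0, d_cells[1:], 1.0), np.inf)
    g_diff = np.where(np.isfinite(resist), areas[1:-1] / np.where(resist > 0, resist, np.inf), 0.0)

    # boundary conductances
    if inner_dirichlet_value is not None:
        g_in = areas[0] * d_cells[0] / (centers[0] - edges[0]) if d_cells[0] > 0 else 0.0
        f_in = flow.darcy_flux[0] * areas[0]  # inflow rate (>= 0 expected)
    else:
        g_in, f_in = 0.0, 0.0
    if outer_dirichlet_value is not None:
        g_out = areas[-1] * d_cells[-1] / (edges[-1] - centers[-1]) if d_cells[-1] > 0 else 0.0
        f_out = flow.darcy_flux[-1] * areas[-1]
    else:
        g_out, f_out = 0.0, 0.0

    sub_dt = dt / n_substeps
    c = state.concentration.astype(float).copy()

    # assemble the backward-Euler matrix once; it is step-size dependent only
    lower = np.zeros(n)
    diag = eps * volumes / sub_dt
    upper = np.zeros(n)
    up_pos = np.maximum(f_adv, 0.0)  # upwind split
    up_neg = np.minimum(f_adv, 0.0)
    diag[:-1] += up_pos + g_diff
    upper[1:] = up_neg - g_diff
    diag[1:] += -up_neg + g_diff
    lower[:-1] = -up_pos - g_diff
    rhs_const = np.zeros(n)
    if inner_dirichlet_value is not None:
        diag[0] += g_in + np.maximum(-f_in, 0.0)
        rhs_const[0] += (g_in + np.maximum(f_in, 0.0)) * inner_dirichlet_value
    if outer_dirichlet_value is not None:
        diag[-1] += g_out + np.maximum(f_out, 0.0)
        rhs_const[-1] += (g_out + np.maximum(-f_out, 0.0)) * outer_dirichlet_value
    ab = np.zeros((3, n))
    ab[0] = upper
    ab[1] = diag
    ab[2] = lower

    for _ in range(n_substeps):
        rhs = eps * volumes / sub_dt * c + rhs_const
        c = solve_banded((1, 1), ab, rhs)
    return ConcentrationState(grid=grid, concentration=c, time=state.time + dt)
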