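"""Analytic-solution fixtures and degenerate scenarios for verification.

Everything the test suites need is generated here, with no external data:
closed-form solutions of degenerate limits of the governing equations
(checked symbolically against the PDE they solve), synthetic concentration
profiles with known integrals, and a matrix of switch-off scenarios.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .grid import RadialGrid
from .scenario import Scenario, preset_scenario
from .transport import ConcentrationState

__all__ = [
    "AnalyticFixture",
    "conduction_sphere_fixture",
    "gaussian_concentration",
    "degenerate_scenarios",
]


@dataclass
class AnalyticFixture:
    """A degenerate scenario paired with the closed form its PDE admits."""

    scenario: Scenario
    closed_form: Callable[[np.ndarray], np.ndarray]
    tolerance: float  # max-norm acceptance bound for a solver comparison
    description: str

    residual: Callable[[int], float] = None
    """residual(n_samples) -> max |PDE residual| of the closed form."""


def conduction_sphere_fixture(source: float, source_radius: float,
                              outer_radius: float, conductivity: float,
                              boundary_temperature: float = 310.15,
                              tolerance: float = 0.01) -> AnalyticFixture:
    """Steady conduction with a uniform source inside radius ``a``.

    With perfusion, metabolic heat and flow all off, the Pennes equation
    reduces to (k/r^2) d/dr(r^2 dT/dr) + Q*[r<a] = 0 with T(R2) fixed and a
    symmetric centre.  The classical solution is quadratic inside the
    source and ~1/r outside:

        T(r) = T_out + Q a^3/(3k) (1/r - 1/R2),            a <= r <= R2
        T(r) = T(a) + Q (a^2 - r^2) / (6k),                 r <= a

    The fixture's ``residual`` substitutes the closed form into the PDE by
    symbolic differentiation (sympy) and evaluates the residual, normalized
    by Q, at sample radii.
    """
    if not 0 < source_radius < outer_radius:
        raise ValueError("need 0 < a < R2")
    q, a, r2, k, t_out = (float(source), float(source_radius),
                          float(outer_radius), float(conductivity),
                          float(boundary_temperature))

    t_at_a = t_out + q * a**3 / (3.0 * k) * (1.0 / a - 1.0 / r2)

    def closed_form(r):
        r = np.asarray(r, dtype=float)
        outer = t_out + q * a**3 / (3.0 * k) * (1.0 / np.maximum(r, a) - 1.0 / r2)
        inner = t_at_a + q * (a**2 - np.minimum(r, a) ** 2) / (6.0 * k)
        return np.where(r < a, inner, outer)

    def residual(n_samples: int = 1000) -> float:
        import sympy as sp

        r = sp.symbols("r", positive=True)
        t_in = t_at_a + q * (a**2 - r**2) / (6 * k)
        t_out_expr = t_out + q * a**3 / (3 * k) * (1 / r - sp.Rational(1) / r2)
        worst = 0.0
        for expr, lo, hi, src in ((t_in, 1e-6 * a, a, q), (t_out_expr, a, r2, 0.0)):
            res = k / r**2 * sp.diff(r**2 * sp.diff(expr, r), r) + src
            fn = sp.lambdify(r, sp.simplify(res), "numpy")
            samples = np.linspace(lo, hi, n_samples // 2)
            vals = np.abs(np.atleast_1d(fn(samples)).astype(float))
            worst = max(worst, float(np.max(vals)) / max(abs(q), 1.0))
        return worst

    scenario = preset_scenario("conduction_fixture")
    scenario = scenario.replace(domain_radius=r2, tumor_radius=a)
    for region in (scenario.tumor, scenario.healthy):
        region.thermal.thermal_conductivity = k
    scenario.blood.arterial_temperature = t_out

    fixture = AnalyticFixture(scenario=scenario, closed_form=closed_form,
                              tolerance=tolerance,
                              description="steady conduction, uniform source in r<a")
    fixture.residual = residual
    return fixture


def gaussian_concentration(amplitude: float, width: float,
                           grid: RadialGrid) -> ConcentrationState:
    """Gaussian radial profile C(r) = A exp(-r^2 / (2 w^2)) sampled on the grid."""
    if width <= 0:
        raise ValueError("width must be positive")
    c = amplitude * np.exp(-grid.centers**2 / (2.0 * width**2))
    return ConcentrationState(grid=grid, concentration=c, time=0.0)


def gaussian_mass(amplitude: float, width: float, inner_radius: float,
                  outer_radius: float, porosity: float = 1.0) -> float:
    """Closed-form eps * integral of the Gaussian over the spherical shell.

    int A e^{-r^2/2w^2} 4 pi r^2 dr evaluated with the error function.
    """
    from scipy.special import erf

    def antideriv(r):
        # int_0^r x^2 e^{-x^2/(2 w^2)} dx
        s = width
        return (np.sqrt(np.pi / 2.0) * s**3 * erf(r / (np.sqrt(2) * s))
                - s**2 * r * np.exp(-r**2 / (2 * s**2)))

    return float(porosity * amplitude * 4.0 * np.pi
                 * (antideriv(outer_radius) - antideriv(inner_radius)))


def degenerate_scenarios() -> dict[str, Scenario]:
    """The switch-off matrix used by the property suites.

    Each entry disables one transport/heating mechanism of the default
    treatment; ``uniform`` additionally copies the tumor parameters onto
    the healthy region so the tissue interface becomes invisible.
    """
    base = preset_scenario("paper_default_sphere")

    def clone() -> Scenario:
        return Scenario.from_dict(base.to_dict())

    out: dict[str, Scenario] = {}

    s = clone()  # no interstitial flow: no filtration, no lymph, no inlet
    for region in (s.tumor, s.healthy):
        region.vascular.hydraulic_conductivity = 0.0
        region.vascular.lymphatic_coefficient = 0.0
    s.infusion = dataclasses.replace(s.infusion, infusion_rate=0.0)
    out["no_flow"] = s

    s = clone()  # no diffusion (hindrance factor zero kills D*)
    s.numerics.hindrance_extra_factor = 0.0
    out["no_diffusion"] = s

    s = clone()  # no perfusion heat exchange
    for region in (s.tumor, s.healthy):
        region.thermal.baseline_perfusion_rate = 0.0
    out["no_perfusion"] = s

    s = clone()  # field off
    s.field.amplitude = 0.0
    out["no_field"] = s

    s = clone()  # damage kinetics frozen (vanishing frequency factor)
    s.damage = dataclasses.replace(s.damage, frequency_factor=1e-300)
    out["no_damage"] = s

    s = clone()  # uniform medium: interface invisible
    s.healthy = dataclasses.replace(
        s.healthy,
        thermal=dataclasses.replace(s.tumor.thermal),
        vascular=dataclasses.replace(s.tumor.vascular),
    )
    out["uniform"] = s

    return out
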