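"""Shape-aware specific-loss-power physics in the linear-response regime.

Single-domain magnetic nanoparticles dissipate heat in an AC field through
the out-of-phase part chi'' of their susceptibility.  Two relaxation
channels compete: Neel reversal over the anisotropy barrier K*V and
Brownian rotation of the whole particle in the carrier fluid; the effective
time is their harmonic combination.  The volumetric loss power is

    P = mu0 * pi * f * chi''(f) * H^2,      chi'' = chi0 * x / (1 + x^2),

with x = 2*pi*f*tau and the equilibrium amplitude chi0 = mu0 Ms^2 V/(3 kB T).
P is per unit core volume of magnetic material; multiplying by the local
particle volume fraction gives the tissue heat source.

Cubes and spheres are compared at equal core volume: a cube of edge
L = R (4 pi / 3)^(1/3) has the volume of a sphere of radius R.  Shape enters
through (a) the volume-equivalent radius used for hydrodynamics and
(b) a shape-specific effective anisotropy constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import BOLTZMANN, MU0
from .scenario import FieldSpec, ParticleSpec

__all__ = [
    "RelaxationBreakdown",
    "LossPowerMap",
    "equal_volume_cube_edge",
    "brown_time",
    "neel_time",
    "effective_relaxation_time",
    "relaxation_breakdown",
    "out_of_phase_susceptibility",
    "loss_power_density",
    "slp_map",
    "cube_variant",
]

_EQUAL_VOLUME_FACTOR = (4.0 * math.pi / 3.0) ** (1.0 / 3.0)
_GAMMA_OVERFLOW = 700.0


def equal_volume_cube_edge(radius: float) -> float:
    """Edge L of the cube with the volume of a sphere of radius R.

    L = R (4 pi / 3)^(1/3) ~ 1.612 R.
    """
    if radius <= 0:
        raise ValueError(f"sphere radius must be positive (got {radius})")
    return radius * _EQUAL_VOLUME_FACTOR


def brown_time(particle: ParticleSpec, temperature: float) -> float:
    """Brownian rotational relaxation time tau_B = 3 eta V_H / (kB T).

    The hydrodynamic volume V_H = V (1 + delta/R)^3 uses the
    volume-equivalent radius R, so equal-volume cubes and spheres with the
    same coating share tau_B.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be positive (got {temperature})")
    return (3.0 * particle.carrier_viscosity * particle.hydrodynamic_volume
            / (BOLTZMANN * temperature))


def neel_time(particle: ParticleSpec, temperature: float) -> float:
    """Neel relaxation time tau_N = tau_0 (sqrt(pi)/2) e^Gamma / sqrt(Gamma).

    Gamma = K V / (kB T) is the anisotropy barrier in thermal units.  For
    Gamma above ~700 the exponential overflows double precision; the barrier
    is then effectively infinite and +inf is returned (the harmonic
    combination handles it gracefully).
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be positive (got {temperature})")
    gamma = (particle.anisotropy_constant * particle.core_volume
             / (BOLTZMANN * temperature))
    if gamma <= 0:
        raise ValueError(f"anisotropy barrier must be positive (got Gamma={gamma})")
    if gamma > _GAMMA_OVERFLOW:
        return math.inf
    return (particle.attempt_time * (math.sqrt(math.pi) / 2.0)
            * math.exp(gamma) / math.sqrt(gamma))


def effective_relaxation_time(tau_n: float, tau_b: float) -> float:
    """Harmonic combination tau = tau_N tau_B / (tau_N + tau_B)."""
    if tau_n <= 0 or tau_b <= 0:
        raise ValueError("relaxation times must be positive")
    if math.isinf(tau_n):
        return tau_b
    if math.isinf(tau_b):
        return tau_n
    return tau_n * tau_b / (tau_n + tau_b)


@dataclass
class RelaxationBreakdown:
    tau_brown: float
    tau_neel: float
    tau_effective: float


def relaxation_breakdown(particle: ParticleSpec, temperature: float) -> RelaxationBreakdown:
    tb = brown_time(particle, temperature)
    tn = neel_time(particle, temperature)
    return RelaxationBreakdown(tau_brown=tb, tau_neel=tn,
                               tau_effective=effective_relaxation_time(tn, tb))


def out_of_phase_susceptibility(particle: ParticleSpec, field: FieldSpec,
                                temperature: float) -> float:
    """chi'' = [mu0 Ms^2 V / (3 kB T)] * x / (1 + x^2), x = 2 pi f tau.

    Peaks at x = 1 with value chi0/2; this Lorentzian-in-log-f shape is what
    makes the relaxation time the tuning knob of hyperthermia heating.
    """
    if temperature <= 0 or field.frequency <= 0:
        raise ValueError("temperature and frequency must be positive")
    tau = relaxation_breakdown(particle, temperature).tau_effective
    chi0 = (MU0 * particle.saturation_magnetization**2 * particle.core_volume
            / (3.0 * BOLTZMANN * temperature))
    x = 2.0 * math.pi * field.frequency * tau
    return chi0 * x / (1.0 + x * x)


def loss_power_density(particle: ParticleSpec, field: FieldSpec,
                       temperature: float) -> float:
    """Volumetric loss power P = mu0 pi f chi'' H^2 (W per m^3 of core)."""
    if field.amplitude < 0:
        raise ValueError("field amplitude must be non-negative")
    chi = out_of_phase_susceptibility(particle, field, temperature)
    return MU0 * math.pi * field.frequency * chi * field.amplitude**2


def cube_variant(particle: ParticleSpec, anisotropy_constant: float | None = None) -> ParticleSpec:
    """The equal-volume cubic counterpart of a spherical particle.

    Keeps Ms, coating and carrier; swaps shape/size by the equal-volume
    mapping and (optionally) the effective anisotropy constant.
    """
    import dataclasses

    if particle.shape != "sphere":
        raise ValueError("cube_variant expects a spherical particle")
    return dataclasses.replace(
        particle,
        shape="cube",
        characteristic_size=equal_volume_cube_edge(particle.characteristic_size),
        anisotropy_constant=(particle.anisotropy_constant
                             if anisotropy_constant is None else anisotropy_constant),
    )


@dataclass
class LossPowerMap:
    """Dense P(f, H) sweep for one particle shape (the field-map object)."""

    frequencies: np.ndarray  # Hz, shape (nf,)
    amplitudes: np.ndarray  # A/m, shape (nh,)
    values: np.ndarray  # W/m^3, shape (nf, nh)
    shape_label: str

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: f_Hz, H_A_per_m, P_W_per_m3, shape."""
        ff, hh = np.meshgrid(self.frequencies, self.amplitudes, indexing="ij")
        return pd.DataFrame({
            "f_Hz": ff.ravel(),
            "H_A_per_m": hh.ravel(),
            "P_W_per_m3": self.values.ravel(),
            "shape": self.shape_label,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def slp_map(particle: ParticleSpec, frequencies, amplitudes,
            temperature: float = 310.15) -> LossPowerMap:
    """Dense loss-power map over a frequency x amplitude grid.

    tau and chi0 depend on f only through x = 2 pi f tau, and P is exactly
    quadratic in H, so the sweep factorizes into one pass over f and an
    outer product with H^2.
    """
    f = np.atleast_1d(np.asarray(frequencies, dtype=float))
    h = np.atleast_1d(np.asarray(amplitudes, dtype=float))
    if f.size == 0 or h.size == 0:
        raise ValueError("frequency and amplitude ranges must be non-empty")
    per_f = np.array([
        loss_power_density(particle, FieldSpec(amplitude=1.0, frequency=fi), temperature)
        for fi in f
    ])
    values = np.outer(per_f, h**2)
    return LossPowerMap(frequencies=f, amplitudes=h, values=values,
                        shape_label=particle.shape)
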