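"""Scenario description: domain types, validation, presets and config I/O.

A :class:`Scenario` is the single input every solver consumes.  It describes
one magnetic-hyperthermia treatment of a spherical tumor (radius ``R1``)
embedded concentrically in healthy tissue (outer radius ``R2``): tissue
thermal and vascular properties per region, blood, one nanoparticle type,
the applied AC field, the ferrofluid infusion protocol, Arrhenius damage
kinetics, and solver controls.

All stored quantities are SI (pressures in Pa, temperatures in K, rates in
1/s).  Converters in :mod:`ferrotherm.constants` translate the clinical
units (mmHg, uL/min, cm^-1) used by config files and the literature.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any

import yaml

from .constants import (
    CELSIUS_OFFSET,
    GAS_CONSTANT,
    convert_area_density,
    convert_hydraulic_conductivity,
    convert_infusion_rate,
    convert_lymphatic_coefficient,
    convert_pressure_units,
)

__all__ = [
    "convert_pressure_units",
    "convert_infusion_rate",
    "TissueThermal",
    "BloodProperties",
    "VascularParams",
    "ParticleSpec",
    "FieldSpec",
    "InfusionSpec",
    "DamageParams",
    "Numerics",
    "TissueRegion",
    "Scenario",
    "preset_scenario",
    "validate_scenario",
    "PRESET_NAMES",
]


@dataclass
class TissueThermal:
    """Thermal properties of one tissue region (tumor or healthy)."""

    mass_density: float  # kg/m^3
    specific_heat: float  # J/(kg K)
    thermal_conductivity: float  # W/(m K)
    metabolic_heat: float  # W/m^3
    baseline_perfusion_rate: float  # 1/s


@dataclass
class BloodProperties:
    mass_density: float = 1000.0  # kg/m^3
    specific_heat: float = 4180.0  # J/(kg K)
    arterial_temperature: float = 310.15  # K


@dataclass
class VascularParams:
    """Starling filtration / lymphatic drainage parameters of one region.

    ``hydraulic_conductivity`` is L_p in m/(Pa s); ``lymphatic_coefficient``
    is the lumped L_PL*S_L/V in 1/(Pa s) and is 0 in tumors, which lack
    functional lymphatics.
    """

    hydraulic_conductivity: float  # L_p, m/(Pa s)
    vessel_area_density: float  # S/V, 1/m
    blood_pressure: float  # P_b, Pa
    plasma_oncotic_pressure: float  # pi_b, Pa
    interstitial_oncotic_pressure: float  # pi_i, Pa
    reflection_coefficient: float  # sigma_s, [0, 1]
    lymphatic_coefficient: float  # L_PL S_L / V, 1/(Pa s)
    lymphatic_pressure: float  # P_L, Pa
    porosity: float  # eps, (0, 1)
    grain_diameter: float = 1e-4  # d_p, m


@dataclass
class ParticleSpec:
    """One magnetic-nanoparticle type.

    ``characteristic_size`` is the core radius R for spheres and the edge
    length L for cubes.  Shape enters the physics through the core volume,
    the volume-equivalent radius (hydrodynamics, Stokes-Einstein) and the
    effective anisotropy constant.
    """

    shape: str  # "sphere" | "cube"
    characteristic_size: float  # m
    saturation_magnetization: float  # M_s, A/m
    anisotropy_constant: float  # K, J/m^3
    mass_density: float  # kg/m^3
    attempt_time: float = 1e-9  # tau_0, s
    surfactant_thickness: float = 2e-9  # delta, m
    carrier_viscosity: float = 1e-3  # eta, Pa s

    @property
    def core_volume(self) -> float:
        """Magnetic core volume V in m^3."""
        if self.shape == "sphere":
            return 4.0 / 3.0 * math.pi * self.characteristic_size**3
        if self.shape == "cube":
            return self.characteristic_size**3
        raise ValueError(f"unknown particle shape {self.shape!r}")

    @property
    def volume_equivalent_radius(self) -> float:
        """Radius of the sphere with the same core volume (equals R for spheres)."""
        return (3.0 * self.core_volume / (4.0 * math.pi)) ** (1.0 / 3.0)

    @property
    def hydrodynamic_volume(self) -> float:
        """V_H = V (1 + delta/R)^3 with R the volume-equivalent radius."""
        r = self.volume_equivalent_radius
        return self.core_volume * (1.0 + self.surfactant_thickness / r) ** 3


@dataclass
class FieldSpec:
    amplitude: float  # H, A/m
    frequency: float  # f, Hz

    # envelope studied in the source experiments; outside -> warning not error
    FREQ_RANGE = (100e3, 650e3)
    AMP_RANGE = (0.0, 15e3)


@dataclass
class InfusionSpec:
    infusion_rate: float  # Q_v, m^3/s
    needle_radius: float  # r_n, m
    max_concentration: float  # C_max, kg/m^3
    infusion_duration: float  # s


@dataclass
class DamageParams:
    frequency_factor: float  # A, 1/s
    activation_energy: float  # E_a, J/mol
    gas_constant: float = GAS_CONSTANT  # J/(mol K)


@dataclass
class Numerics:
    """Discretization, stepping and model-switch controls.

    The model switches live here (rather than with the physics they modify)
    so a config file can flip them without redefining tissue or particle
    parameters.
    """

    cell_count: int = 300
    transport_dt: float = 1.0  # s, backward-Euler substep for C
    thermal_dt: float = 0.25  # s, backward-Euler substep for T
    coupling_dt: float = 5.0  # s, operator-splitting interval in the heating phase
    heating_duration: float = 1200.0  # s of field-on time
    snapshot_interval: float = 60.0  # s between recorded radial snapshots
    flow_tolerance: float = 1e-10  # relative, for the lymphatic clamp fixed point
    # --- transport model switches ---
    pore_diameter: float = 100e-9  # m, effective interstitial pore size
    hindrance_lambda: float | None = None  # direct lambda override; None -> 2 R_H / d_pore
    partition_form: str = "squared"  # "(1-lambda)^2" ("squared") or "1-lambda^2" ("one_minus_sq")
    hindrance_extra_factor: float = 1.0  # optional extra multiplicative hindrance
    diffusion_temperature: str = "arterial"  # "arterial" | "local"
    inner_dirichlet: str = "infusion"  # hold C = C_max at needle: "infusion" | "always"
    # --- flow model switches ---
    lymphatic_driver: str = "interstitial"  # "interstitial" (P - P_L) | "blood" (P_b - P_L)
    flow_viscosity: float | None = None  # Pa s; None -> particle.carrier_viscosity
    # --- magnetics switch ---
    slp_temperature: str = "fixed"  # "fixed" (310.15 K) | "local"
    slp_fixed_temperature: float = 310.15  # K
    # --- metrics ---
    r0_mode: str = "band_shell"  # "band_shell" | "ge_lower"
    damage_threshold: float = 0.5  # theta below this counts as destroyed


@dataclass
class TissueRegion:
    thermal: TissueThermal
    vascular: VascularParams


@dataclass
class Scenario:
    tumor_radius: float  # R1, m
    domain_radius: float  # R2, m
    tumor: TissueRegion
    healthy: TissueRegion
    blood: BloodProperties
    particle: ParticleSpec
    field: FieldSpec
    infusion: InfusionSpec
    damage: DamageParams
    numerics: Numerics = field(default_factory=Numerics)
    therapeutic_band: tuple[float, float] = (313.15, 318.15)  # K, 40-45 C

    # ------------------------------------------------------------------ I/O
    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["therapeutic_band"] = list(d["therapeutic_band"])
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "Scenario":
        data = dict(data)
        band = data.pop("therapeutic_band", (313.15, 318.15))

        def build(klass, payload, label):
            if not isinstance(payload, dict):
                raise ValueError(f"section {label!r} must be a mapping")
            known = {f.name for f in dataclasses.fields(klass)}
            unknown = set(payload) - known
            if unknown:
                raise ValueError(
                    f"unknown keys in section {label!r}: {sorted(unknown)}"
                )
            return klass(**payload)

        def region(payload, label):
            if not isinstance(payload, dict) or set(payload) - {"thermal", "vascular"}:
                raise ValueError(
                    f"section {label!r} must contain exactly 'thermal' and 'vascular'"
                )
            return TissueRegion(
                thermal=build(TissueThermal, payload["thermal"], f"{label}.thermal"),
                vascular=build(VascularParams, payload["vascular"], f"{label}.vascular"),
            )

        sections = {
            "tumor_radius": None,
            "domain_radius": None,
            "tumor": None,
            "healthy": None,
            "blood": BloodProperties,
            "particle": ParticleSpec,
            "field": FieldSpec,
            "infusion": InfusionSpec,
            "damage": DamageParams,
            "numerics": Numerics,
        }
        unknown = set(data) - set(sections)
        if unknown:
            raise ValueError(f"unknown top-level keys: {sorted(unknown)}")
        missing = {k for k in sections if k not in data and k != "numerics"}
        if missing:
            raise ValueError(f"missing required sections: {sorted(missing)}")

        return cls(
            tumor_radius=float(data["tumor_radius"]),
            domain_radius=float(data["domain_radius"]),
            tumor=region(data["tumor"], "tumor"),
            healthy=region(data["healthy"], "healthy"),
            blood=build(BloodProperties, data["blood"], "blood"),
            particle=build(ParticleSpec, data["particle"], "particle"),
            field=build(FieldSpec, data["field"], "field"),
            infusion=build(InfusionSpec, data["infusion"], "infusion"),
            damage=build(DamageParams, data["damage"], "damage"),
            numerics=build(Numerics, data.get("numerics", {}), "numerics"),
            therapeutic_band=(float(band[0]), float(band[1])),
        )

    @classmethod
    def from_yaml(cls, path) -> "Scenario":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
        return cls.from_dict(data)

    def replace(self, **kwargs) -> "Scenario":
        return dataclasses.replace(self, **kwargs)


# --------------------------------------------------------------------------
# validation
# --------------------------------------------------------------------------

def _positive(violations, label, value, allow_zero=False):
    if not math.isfinite(value):
        violations.append(f"{label} must be finite (got {value})")
    elif value < 0 or (value == 0 and not allow_zero):
        kind = "non-negative" if allow_zero else "strictly positive"
        violations.append(f"{label} must be {kind} (got {value})")


def validate_scenario(s: Scenario) -> list[str]:
    """Return a list of human-readable invariant violations; empty iff valid."""
    v: list[str] = []
    if not (0 < s.tumor_radius < s.domain_radius):
        v.append(
            "geometry: tumor_radius R1 must satisfy 0 < R1 < R2 "
            f"(got R1={s.tumor_radius}, R2={s.domain_radius})"
        )
    if not s.infusion.needle_radius < s.tumor_radius:
        v.append("geometry: needle_radius must be smaller than tumor_radius")

    for region_name in ("tumor", "healthy"):
        region: TissueRegion = getattr(s, region_name)
        t = region.thermal
        _positive(v, f"{region_name}.thermal.mass_density", t.mass_density)
        _positive(v, f"{region_name}.thermal.specific_heat", t.specific_heat)
        _positive(v, f"{region_name}.thermal.thermal_conductivity", t.thermal_conductivity)
        _positive(v, f"{region_name}.thermal.metabolic_heat", t.metabolic_heat, allow_zero=True)
        _positive(v, f"{region_name}.thermal.baseline_perfusion_rate",
                  t.baseline_perfusion_rate, allow_zero=True)
        vas = region.vascular
        _positive(v, f"{region_name}.vascular.hydraulic_conductivity",
                  vas.hydraulic_conductivity, allow_zero=True)
        _positive(v, f"{region_name}.vascular.vessel_area_density",
                  vas.vessel_area_density, allow_zero=True)
        _positive(v, f"{region_name}.vascular.lymphatic_coefficient",
                  vas.lymphatic_coefficient, allow_zero=True)
        _positive(v, f"{region_name}.vascular.grain_diameter", vas.grain_diameter)
        for pname in ("blood_pressure", "plasma_oncotic_pressure",
                      "interstitial_oncotic_pressure", "lymphatic_pressure"):
            if not math.isfinite(getattr(vas, pname)):
                v.append(f"{region_name}.vascular.{pname} must be finite")
        if not 0.0 <= vas.reflection_coefficient <= 1.0:
            v.append(
                f"{region_name}.vascular.reflection_coefficient sigma_s must lie in "
                f"[0, 1] (got {vas.reflection_coefficient})"
            )
        if not 0.0 < vas.porosity < 1.0:
            v.append(
                f"{region_name}.vascular.porosity eps must lie in (0, 1) "
                f"(got {vas.porosity})"
            )

    b = s.blood
    _positive(v, "blood.mass_density", b.mass_density)
    _positive(v, "blood.specific_heat", b.specific_heat)
    _positive(v, "blood.arterial_temperature", b.arterial_temperature)

    p = s.particle
    if p.shape not in ("sphere", "cube"):
        v.append(f"particle.shape must be 'sphere' or 'cube' (got {p.shape!r})")
    else:
        _positive(v, "particle.characteristic_size", p.characteristic_size)
        if p.characteristic_size > 0 and p.hydrodynamic_volume < p.core_volume:
            v.append("particle: hydrodynamic volume V_H must be >= core volume V")
    _positive(v, "particle.saturation_magnetization", p.saturation_magnetization)
    _positive(v, "particle.anisotropy_constant", p.anisotropy_constant)
    _positive(v, "particle.mass_density", p.mass_density)
    _positive(v, "particle.attempt_time", p.attempt_time)
    _positive(v, "particle.surfactant_thickness", p.surfactant_thickness, allow_zero=True)
    _positive(v, "particle.carrier_viscosity", p.carrier_viscosity)

    _positive(v, "field.amplitude", s.field.amplitude, allow_zero=True)
    _positive(v, "field.frequency", s.field.frequency)

    i = s.infusion
    _positive(v, "infusion.infusion_rate", i.infusion_rate, allow_zero=True)
    _positive(v, "infusion.needle_radius", i.needle_radius)
    _positive(v, "infusion.max_concentration", i.max_concentration, allow_zero=True)
    _positive(v, "infusion.infusion_duration", i.infusion_duration, allow_zero=True)

    _positive(v, "damage.frequency_factor", s.damage.frequency_factor)
    _positive(v, "damage.activation_energy", s.damage.activation_energy)
    _positive(v, "damage.gas_constant", s.damage.gas_constant)

    n = s.numerics
    if n.cell_count < 4:
        v.append(f"numerics.cell_count must be >= 4 (got {n.cell_count})")
    for name in ("transport_dt", "thermal_dt", "coupling_dt"):
        _positive(v, f"numerics.{name}", getattr(n, name))
    _positive(v, "numerics.heating_duration", n.heating_duration, allow_zero=True)
    if n.partition_form not in ("squared", "one_minus_sq"):
        v.append("numerics.partition_form must be 'squared' or 'one_minus_sq'")
    if n.lymphatic_driver not in ("interstitial", "blood"):
        v.append("numerics.lymphatic_driver must be 'interstitial' or 'blood'")
    if n.slp_temperature not in ("fixed", "local"):
        v.append("numerics.slp_temperature must be 'fixed' or 'local'")
    if n.inner_dirichlet not in ("infusion", "always"):
        v.append("numerics.inner_dirichlet must be 'infusion' or 'always'")
    if n.r0_mode not in ("band_shell", "ge_lower"):
        v.append("numerics.r0_mode must be 'band_shell' or 'ge_lower'")
    if not 0.0 < n.damage_threshold < 1.0:
        v.append("numerics.damage_threshold must lie in (0, 1)")
    if n.hindrance_lambda is not None and not 0.0 <= n.hindrance_lambda < 1.0:
        v.append("numerics.hindrance_lambda must lie in [0, 1)")

    lo, hi = s.therapeutic_band
    if not lo < hi:
        v.append(f"therapeutic_band must be ordered (got {s.therapeutic_band})")
    return v


def field_warnings(spec: FieldSpec) -> list[str]:
    """Non-fatal warnings when the field lies outside the studied envelope."""
    w = []
    flo, fhi = FieldSpec.FREQ_RANGE
    alo, ahi = FieldSpec.AMP_RANGE
    if not flo <= spec.frequency <= fhi:
        w.append(
            f"field.frequency {spec.frequency:.3g} Hz outside studied range "
            f"{flo:.3g}-{fhi:.3g} Hz"
        )
    if not alo <= spec.amplitude <= ahi:
        w.append(
            f"field.amplitude {spec.amplitude:.3g} A/m outside studied range "
            f"{alo:.3g}-{ahi:.3g} A/m"
        )
    return w


# --------------------------------------------------------------------------
# presets
# --------------------------------------------------------------------------

PRESET_NAMES = (
    "paper_default_sphere",
    "paper_default_cube",
    "conduction_fixture",
    "zero_field",
)

# Liver-tissue literature values (see docs/methods.md for provenance of the
# cells the source tables leave blank: porosities, pi_b, S/V, magnetic and
# Arrhenius constants, infusion protocol).
_TUMOR_THERMAL = dict(mass_density=1160.0, specific_heat=3600.0,
                      thermal_conductivity=0.4692, metabolic_heat=5790.0,
                      baseline_perfusion_rate=0.0064)
_HEALTHY_THERMAL = dict(mass_density=1060.0, specific_heat=3600.0,
                        thermal_conductivity=0.512, metabolic_heat=700.0,
                        baseline_perfusion_rate=0.0064)

_SPHERE_RADIUS = 8e-9  # m; lower end of the 8-10 nm design range
_K_SPHERE = 9e3  # J/m^3, magnetocrystalline anisotropy of magnetite spheres
_K_CUBE = 1.6e4  # J/m^3, effective (shape-enhanced) anisotropy for nanocubes
_M_S = 4.46e5  # A/m, magnetite saturation magnetization


def _default_vascular(tumor: bool) -> VascularParams:
    return VascularParams(
        hydraulic_conductivity=convert_hydraulic_conductivity(
            2.8e-7 if tumor else 0.36e-7),
        vessel_area_density=convert_area_density(200.0),
        blood_pressure=convert_pressure_units(15.6),
        plasma_oncotic_pressure=convert_pressure_units(20.0),
        interstitial_oncotic_pressure=convert_pressure_units(15.0 if tumor else 10.0),
        reflection_coefficient=0.82 if tumor else 0.91,
        lymphatic_coefficient=0.0 if tumor else convert_lymphatic_coefficient(5e-5),
        lymphatic_pressure=0.0,
        porosity=0.40 if tumor else 0.20,
        grain_diameter=1e-4,
    )


def _default_particle(shape: str) -> ParticleSpec:
    if shape == "sphere":
        size, k_aniso = _SPHERE_RADIUS, _K_SPHERE
    else:
        from .magnetics import equal_volume_cube_edge

        size, k_aniso = equal_volume_cube_edge(_SPHERE_RADIUS), _K_CUBE
    return ParticleSpec(
        shape=shape,
        characteristic_size=size,
        saturation_magnetization=_M_S,
        anisotropy_constant=k_aniso,
        mass_density=5180.0,
        attempt_time=1e-9,
        surfactant_thickness=2e-9,
        carrier_viscosity=1e-3,
    )


def _paper_default(shape: str) -> Scenario:
    return Scenario(
        tumor_radius=20e-3,
        domain_radius=60e-3,
        tumor=TissueRegion(thermal=TissueThermal(**_TUMOR_THERMAL),
                           vascular=_default_vascular(tumor=True)),
        healthy=TissueRegion(thermal=TissueThermal(**_HEALTHY_THERMAL),
                             vascular=_default_vascular(tumor=False)),
        blood=BloodProperties(),
        particle=_default_particle(shape),
        field=FieldSpec(amplitude=5e3, frequency=200e3),
        infusion=InfusionSpec(
            infusion_rate=convert_infusion_rate(5.0),
            needle_radius=0.2e-3,
            max_concentration=10.0,  # 10 mg/cm^3 = 10 kg/m^3
            infusion_duration=600.0,
        ),
        damage=DamageParams(frequency_factor=7.39e39, activation_energy=2.577e5),
        numerics=Numerics(),
    )


def preset_scenario(name: str) -> Scenario:
    """Return one of the shipped, fully validated scenarios.

    ``paper_default_sphere`` / ``paper_default_cube``: the headline treatment
    configuration (40 mm diameter liver tumor, f = 200 kHz, H = 5 kA/m,
    C_max = 10 kg/m^3) with equal-volume sphere/cube magnetite particles.
    ``zero_field``: same but H = 0 (no heating control).
    ``conduction_fixture``: uniform conduction-only medium on a small domain
    with perfusion, metabolic heat, infusion and field all switched off;
    the base scenario for analytic oracles.
    """
    if name == "paper_default_sphere":
        return _paper_default("sphere")
    if name == "paper_default_cube":
        return _paper_default("cube")
    if name == "zero_field":
        s = _paper_default("sphere")
        s.field.amplitude = 0.0
        return s
    if name == "conduction_fixture":
        s = _paper_default("sphere")
        thermal = dict(_TUMOR_THERMAL, metabolic_heat=0.0, baseline_perfusion_rate=0.0)
        vascular = dataclasses.replace(
            _default_vascular(tumor=True), hydraulic_conductivity=0.0,
            lymphatic_coefficient=0.0)
        region = TissueRegion(thermal=TissueThermal(**thermal), vascular=vascular)
        uniform = Scenario(
            tumor_radius=5e-3,
            domain_radius=10e-3,
            tumor=region,
            healthy=dataclasses.replace(region,
                                        thermal=TissueThermal(**thermal),
                                        vascular=dataclasses.replace(vascular)),
            blood=BloodProperties(),
            particle=s.particle,
            field=FieldSpec(amplitude=0.0, frequency=200e3),
            infusion=InfusionSpec(infusion_rate=0.0, needle_radius=0.05e-3,
                                  max_concentration=0.0, infusion_duration=0.0),
            damage=s.damage,
            numerics=Numerics(),
        )
        return uniform
    raise ValueError(
        f"unknown preset {name!r}; available presets: {', '.join(PRESET_NAMES)}"
    )
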