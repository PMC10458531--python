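"""Physical constants and unit-conversion factors.

All internal computation is in SI. The converters below are the only place
unit factors appear; config readers call them, solvers never do.
"""

# CODATA values, truncated to the precision the model can use
BOLTZMANN = 1.380649e-23  # J/K
MU0 = 1.25663706212e-6  # vacuum permeability, N/A^2
GAS_CONSTANT = 8.314462618  # J/(mol K)

MMHG_TO_PA = 133.322  # 1 mmHg in Pa
CELSIUS_OFFSET = 273.15


def convert_pressure_units(value_mmhg: float) -> float:
    """mmHg -> Pa."""
    return value_mmhg * MMHG_TO_PA


def convert_hydraulic_conductivity(value_cm_per_mmhg_s: float) -> float:
    """cm mmHg^-1 s^-1 -> m Pa^-1 s^-1."""
    return value_cm_per_mmhg_s * 1e-2 / MMHG_TO_PA


def convert_lymphatic_coefficient(value_per_mmhg_s: float) -> float:
    """mmHg^-1 s^-1 -> Pa^-1 s^-1."""
    return value_per_mmhg_s / MMHG_TO_PA


def convert_area_density(value_per_cm: float) -> float:
    """cm^-1 -> m^-1."""
    return value_per_cm * 1e2


def convert_infusion_rate(value_ul_per_min: float) -> float:
    """microlitre/min -> m^3/s."""
    return value_ul_per_min * 1e-9 / 60.0


def celsius_to_kelvin(value_c: float) -> float:
    return value_c + CELSIUS_OFFSET


def kelvin_to_celsius(value_k: float) -> float:
    return value_k - CELSIUS_OFFSET
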