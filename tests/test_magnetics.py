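import dataclasses
import math

import numpy as np
import pytest

from ferrotherm.constants import BOLTZMANN, MU0
from ferrotherm.magnetics import (
    brown_time,
    cube_variant,
    effective_relaxation_time,
    equal_volume_cube_edge,
    loss_power_density,
    neel_time,
    out_of_phase_susceptibility,
    relaxation_breakdown,
    slp_map,
)
from ferrotherm.scenario import FieldSpec, ParticleSpec


def make_sphere(radius=10e-9, k_aniso=9e3, m_s=4.46e5, delta=2e-9, eta=1e-3):
    return ParticleSpec(shape="sphere", characteristic_size=radius,
                        saturation_magnetization=m_s, anisotropy_constant=k_aniso,
                        mass_density=5180.0, attempt_time=1e-9,
                        surfactant_thickness=delta, carrier_viscosity=eta)


class TestEqualVolumeMapping:
    @pytest.mark.parametrize("radius_nm, edge_nm", [(8.0, 12.90), (10.0, 16.12)])
    def test_printed_sizes(self, radius_nm, edge_nm):
        assert equal_volume_cube_edge(radius_nm * 1e-9) * 1e9 == pytest.approx(
            edge_nm, abs=0.005)

    def test_volume_preserved(self):
        for r in (5e-9, 8e-9, 10e-9, 25e-9):
            edge = equal_volume_cube_edge(r)
            assert edge**3 == pytest.approx(4 / 3 * math.pi * r**3, rel=1e-12)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            equal_volume_cube_edge(0.0)


class TestRelaxationTimes:
    def test_brown_time_reference_value(self):
        # independent hand evaluation: 3 eta V_H / (kB T) with
        # V_H = (4/3) pi (12 nm)^3 at eta = 1e-3 Pa s, T = 310 K
        p = make_sphere()
        v_h = 4 / 3 * math.pi * (12e-9) ** 3
        expected = 3 * 1e-3 * v_h / (BOLTZMANN * 310.0)
        assert brown_time(p, 310.0) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(5.07e-6, rel=0.01)

    def test_brown_time_linear_in_viscosity(self):
        p = make_sphere()
        p2 = dataclasses.replace(p, carrier_viscosity=2e-3)
        assert brown_time(p2, 310.0) == pytest.approx(2 * brown_time(p, 310.0))

    def test_zero_surfactant_gives_core_volume(self):
        p = make_sphere(delta=0.0)
        assert p.hydrodynamic_volume == pytest.approx(p.core_volume, rel=1e-14)

    def test_neel_time_reference_value(self):
        # hand evaluation of tau_0 (sqrt(pi)/2) e^Gamma / sqrt(Gamma),
        # Gamma = K V / kB T ~ 8.81 for R = 10 nm, K = 9e3, T = 310 K
        p = make_sphere()
        gamma = 9e3 * p.core_volume / (BOLTZMANN * 310.0)
        expected = 1e-9 * (math.sqrt(math.pi) / 2) * math.exp(gamma) / math.sqrt(gamma)
        assert neel_time(p, 310.0) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(2.0e-6, rel=0.01)

    def test_neel_time_increasing_in_anisotropy(self):
        taus = [neel_time(make_sphere(k_aniso=k), 310.0)
                for k in np.linspace(5e3, 5e4, 20)]
        assert np.all(np.diff(taus) > 0)

    def test_huge_barrier_returns_infinity(self):
        p = make_sphere(radius=50e-9, k_aniso=1e5)
        assert math.isinf(neel_time(p, 310.0))
        # and the harmonic combination falls back to the Brownian channel
        rb = relaxation_breakdown(p, 310.0)
        assert rb.tau_effective == rb.tau_brown

    @pytest.mark.parametrize("tn, tb, expected", [
        (2e-6, 2e-6, 1e-6),
        (2e-6, 5e-6, 10e-6 / 7),
        (math.inf, 5e-6, 5e-6),
    ])
    def test_effective_time_combination(self, tn, tb, expected):
        assert effective_relaxation_time(tn, tb) == pytest.approx(expected, rel=1e-12)


class TestSusceptibilityAndLossPower:
    def test_lorentzian_maximum(self):
        # at 2 pi f tau = 1 exactly, chi'' = mu0 Ms^2 V / (6 kB T)
        p = make_sphere()
        tau = relaxation_breakdown(p, 310.0).tau_effective
        f_star = 1.0 / (2 * math.pi * tau)
        chi = out_of_phase_susceptibility(p, FieldSpec(1.0, f_star), 310.0)
        bound = MU0 * p.saturation_magnetization**2 * p.core_volume / (
            6 * BOLTZMANN * 310.0)
        assert chi == pytest.approx(bound, rel=1e-12)

    def test_low_frequency_limit(self):
        # chi'' ~ x -> 0 linearly as f -> 0
        p = make_sphere()
        chi_1 = out_of_phase_susceptibility(p, FieldSpec(1.0, 1.0), 310.0)
        chi_01 = out_of_phase_susceptibility(p, FieldSpec(1.0, 0.1), 310.0)
        assert chi_01 == pytest.approx(chi_1 / 10, rel=1e-9)
        assert chi_1 < 1e-3  # far below the resonant response

    def test_peak_located_by_grid_scan(self):
        p = make_sphere()
        tau = relaxation_breakdown(p, 310.0).tau_effective
        freqs = np.logspace(3, 8, 4001)
        chis = [out_of_phase_susceptibility(p, FieldSpec(1.0, f), 310.0)
                for f in freqs]
        f_peak = freqs[int(np.argmax(chis))]
        assert f_peak == pytest.approx(1 / (2 * math.pi * tau), rel=0.01)

    def test_zero_amplitude_no_heating(self):
        p = make_sphere()
        assert loss_power_density(p, FieldSpec(0.0, 2e5), 310.0) == 0.0

    def test_quadratic_amplitude_scaling(self):
        p = make_sphere()
        p1 = loss_power_density(p, FieldSpec(2.5e3, 2e5), 310.0)
        p2 = loss_power_density(p, FieldSpec(5.0e3, 2e5), 310.0)
        assert p2 == pytest.approx(4 * p1, rel=1e-12)

    def test_loss_power_against_direct_expression(self):
        # single-expression oracle evaluated independently of the module code
        p = make_sphere()
        f, h, t = 2e5, 5e3, 310.0
        v = 4 / 3 * math.pi * (10e-9) ** 3
        tau_b = 3 * 1e-3 * (4 / 3 * math.pi * (12e-9) ** 3) / (BOLTZMANN * t)
        gamma = 9e3 * v / (BOLTZMANN * t)
        tau_n = 1e-9 * math.sqrt(math.pi) / 2 * math.exp(gamma) / math.sqrt(gamma)
        tau = tau_n * tau_b / (tau_n + tau_b)
        x = 2 * math.pi * f * tau
        chi = MU0 * 4.46e5**2 * v / (3 * BOLTZMANN * t) * x / (1 + x * x)
        expected = MU0 * math.pi * f * chi * h * h
        assert loss_power_density(p, FieldSpec(h, f), t) == pytest.approx(
            expected, rel=1e-12)
        assert 1e8 < expected < 1e9  # ~8e8 W/m^3 order for these defaults


class TestShapeComparison:
    def test_single_point_map_reduces_to_loss_power(self, default_sphere):
        p = default_sphere.particle
        m = slp_map(p, [2e5], [5e3], 310.15)
        assert m.values.shape == (1, 1)
        assert m.values[0, 0] == pytest.approx(
            loss_power_density(p, FieldSpec(5e3, 2e5), 310.15), rel=1e-12)

    def test_map_nonnegative_and_monotone_in_amplitude(self, default_cube):
        m = slp_map(default_cube.particle, np.linspace(100e3, 650e3, 12),
                    np.linspace(0.0, 15e3, 16), 310.15)
        assert np.all(m.values >= 0)
        assert np.all(np.diff(m.values, axis=1) >= 0)

    def test_cube_dominates_sphere_over_studied_band(self, default_sphere,
                                                     default_cube):
        # shipped defaults: cube's effective anisotropy sits near the
        # linear-response optimum, so its map dominates entrywise
        freqs = np.linspace(100e3, 650e3, 45)
        amps = np.linspace(1e3, 15e3, 8)
        m_s = slp_map(default_sphere.particle, freqs, amps, 310.15)
        m_c = slp_map(default_cube.particle, freqs, amps, 310.15)
        assert np.all(m_c.values >= m_s.values)

    def test_cube_variant_preserves_volume_and_magnetics(self, default_sphere):
        c = cube_variant(default_sphere.particle)
        assert c.shape == "cube"
        assert c.core_volume == pytest.approx(
            default_sphere.particle.core_volume, rel=1e-12)
        assert c.saturation_magnetization == \
            default_sphere.particle.saturation_magnetization

    def test_long_format_export(self, default_sphere, tmp_path):
        m = slp_map(default_sphere.particle, [1e5, 2e5], [0.0, 5e3], 310.15)
        frame = m.to_frame()
        assert list(frame.columns) == ["f_Hz", "H_A_per_m", "P_W_per_m3", "shape"]
        assert len(frame) == 4
        assert (frame.loc[frame.H_A_per_m == 0.0, "P_W_per_m3"] == 0).all()


class TestRandomDrawProperties:
    """Invariants over random physical parameter draws (seeded)."""

    def _draw(self, rng):
        return make_sphere(
            radius=rng.uniform(4e-9, 20e-9),
            k_aniso=rng.uniform(2e3, 4e4),
            m_s=rng.uniform(1e5, 6e5),
            delta=rng.uniform(0.0, 5e-9),
            eta=rng.uniform(3e-4, 5e-3),
        )

    def test_thousand_draws(self, rng):
        for _ in range(1000):
            p = self._draw(rng)
            t = rng.uniform(290.0, 330.0)
            f = rng.uniform(5e4, 1e6)
            h = rng.uniform(1e2, 2e4)
            rb = relaxation_breakdown(p, t)
            assert 0 < rb.tau_effective <= min(rb.tau_neel, rb.tau_brown) * (1 + 1e-12)
            chi = out_of_phase_susceptibility(p, FieldSpec(h, f), t)
            bound = MU0 * p.saturation_magnetization**2 * p.core_volume / (
                6 * BOLTZMANN * t)
            assert 0 <= chi <= bound * (1 + 1e-12)
            p1 = loss_power_density(p, FieldSpec(h, f), t)
            p4 = loss_power_density(p, FieldSpec(2 * h, f), t)
            assert p4 == pytest.approx(4 * p1, rel=1e-9)
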