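import dataclasses

import numpy as np
import pytest

from ferrotherm.flow import (
    lymphatic_sink,
    needle_inlet_velocity,
    permeability,
    solve_flow,
    starling_source,
)
from ferrotherm.grid import RadialGrid
from ferrotherm.scenario import Scenario, preset_scenario


class TestGrid:
    def test_interface_lands_on_face(self, small_grid):
        assert np.any(np.isclose(small_grid.edges, small_grid.interface_radius))
        assert small_grid.edges[0] == small_grid.inner_radius
        assert small_grid.edges[-1] == small_grid.outer_radius
        assert np.all(np.diff(small_grid.edges) > 0)

    def test_volumes_sum_to_shell(self, small_grid):
        total = 4 / 3 * np.pi * (small_grid.outer_radius**3
                                 - small_grid.inner_radius**3)
        assert small_grid.cell_volumes.sum() == pytest.approx(total, rel=1e-12)


class TestPointwiseOperations:
    @pytest.mark.parametrize("eps, expected", [
        (0.4, 9.876543e-12),  # 0.064e-8 / (180 * 0.36)
        (0.2, 6.944444e-13),
    ])
    def test_permeability_values(self, eps, expected):
        assert permeability(eps, 1e-4) == pytest.approx(expected, rel=1e-6)

    def test_permeability_increasing_in_porosity(self):
        eps = np.linspace(0.05, 0.95, 30)
        k = [permeability(e, 1e-4) for e in eps]
        assert np.all(np.diff(k) > 0)

    def test_starling_balance_point(self, default_sphere):
        vas = default_sphere.tumor.vascular
        p_star = vas.blood_pressure - vas.reflection_coefficient * (
            vas.plasma_oncotic_pressure - vas.interstitial_oncotic_pressure)
        assert starling_source(vas, p_star) == pytest.approx(0.0, abs=1e-18)

    def test_starling_decreasing_in_pressure(self, default_sphere):
        vas = default_sphere.tumor.vascular
        p = np.linspace(-2e3, 2e3, 50)
        assert np.all(np.diff(starling_source(vas, p)) < 0)

    def test_starling_tumor_default_value(self, default_sphere):
        # hand evaluation in SI: L_p S/V = 2.8e-9/133.322 * 2e4 Pa^-1 s^-1,
        # driving pressure 15.6 - 0.82*(20-15) = 11.5 mmHg
        vas = default_sphere.tumor.vascular
        expected = (2.8e-9 / 133.322 * 2e4) * (11.5 * 133.322)
        assert starling_source(vas, 0.0) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(6.44e-4, rel=1e-3)

    def test_lymphatics_absent_in_tumor(self, default_sphere):
        vas = default_sphere.tumor.vascular
        assert np.all(lymphatic_sink(vas, np.array([-1e4, 0.0, 1e4])) == 0.0)

    def test_lymphatic_zero_at_equilibrium_and_clamped(self, default_sphere):
        vas = default_sphere.healthy.vascular
        assert lymphatic_sink(vas, vas.lymphatic_pressure) == pytest.approx(0.0)
        assert lymphatic_sink(vas, vas.lymphatic_pressure - 500.0) == 0.0

    def test_lymphatic_derived_value(self, default_sphere):
        # 5e-5 mmHg^-1 s^-1 * 10 mmHg = 5e-4 s^-1, units cancel exactly
        vas = default_sphere.healthy.vascular
        value = lymphatic_sink(vas, vas.lymphatic_pressure + 1333.22)
        assert value == pytest.approx(5e-4, rel=1e-9)

    def test_needle_inlet_velocity(self, default_sphere):
        u = needle_inlet_velocity(default_sphere.infusion)
        assert u == pytest.approx(6.63e-4, rel=1e-3)
        doubled = dataclasses.replace(default_sphere.infusion,
                                      infusion_rate=2 * default_sphere.infusion.infusion_rate)
        assert needle_inlet_velocity(doubled) == pytest.approx(2 * u, rel=1e-12)
        zero = dataclasses.replace(default_sphere.infusion, infusion_rate=0.0)
        assert needle_inlet_velocity(zero) == 0.0


class TestFlowSolver:
    def test_no_sources_gives_uniform_pressure(self, default_sphere, small_grid):
        s = Scenario.from_dict(default_sphere.to_dict())
        for region in (s.tumor, s.healthy):
            region.vascular.hydraulic_conductivity = 0.0
            region.vascular.lymphatic_coefficient = 0.0
        f = solve_flow(s, small_grid, infusing=False)
        assert np.ptp(f.pressure) < 1e-10
        assert np.all(np.abs(f.darcy_flux) < 1e-18)

    def test_discrete_conservation(self, default_sphere, small_grid):
        for infusing in (True, False):
            f = solve_flow(default_sphere, small_grid, infusing=infusing)
            assert f.mass_balance_residual() < 1e-8

    def test_tumor_interstitial_pressure_elevated(self, default_sphere, small_grid):
        f = solve_flow(default_sphere, small_grid, infusing=False)
        tumor_p = f.pressure[small_grid.tumor_mask]
        healthy_p = f.pressure[~small_grid.tumor_mask]
        assert tumor_p.mean() > healthy_p.mean()
        assert tumor_p.max() > healthy_p[-1]

    def test_against_closed_form_two_region_solution(self, default_sphere):
        """Exact two-region oracle for the no-inlet pressure field.

        With constant coefficients per region the pressure equation
        m (1/r^2)(r^2 P')' = b (P - P_eq) has the exact solution
        P = P_eq + [A sinh(r/L) + B cosh(r/L)]/r with L = sqrt(m/b);
        the four constants follow from zero flux at both boundaries and
        pressure/flux continuity at the interface.  Entirely independent of
        the finite-volume path.
        """
        from ferrotherm.flow import permeability as perm

        s = default_sphere
        grid = RadialGrid.make(s.infusion.needle_radius, s.tumor_radius,
                               s.domain_radius, 400)
        f = solve_flow(s, grid, infusing=False)

        mu = s.particle.carrier_viscosity
        rn, r1, r2 = grid.inner_radius, s.tumor_radius, s.domain_radius
        params = []
        for vas, lymph_on in ((s.tumor.vascular, False), (s.healthy.vascular, True)):
            m = perm(vas.porosity, vas.grain_diameter) / mu
            b_star = vas.hydraulic_conductivity * vas.vessel_area_density
            a_star = b_star * (vas.blood_pressure - vas.reflection_coefficient
                               * (vas.plasma_oncotic_pressure
                                  - vas.interstitial_oncotic_pressure))
            lym = vas.lymphatic_coefficient if lymph_on else 0.0
            b = b_star + lym
            a = a_star + lym * vas.lymphatic_pressure
            params.append((m, a / b, np.sqrt(m / b)))
        (m1, peq1, l1), (m2, peq2, l2) = params

        def basis(r, length):
            sh, ch = np.sinh(r / length), np.cosh(r / length)
            val_s, val_c = sh / r, ch / r
            dva_s = ch / (length * r) - sh / r**2
            dva_c = sh / (length * r) - ch / r**2
            return val_s, val_c, dva_s, dva_c

        # unknowns [A1, B1, A2, B2]
        rows, rhs = [], []
        vs, vc, ds, dc = basis(rn, l1)
        rows.append([ds, dc, 0, 0]); rhs.append(0.0)           # P1'(rn) = 0
        vs2, vc2, ds2, dc2 = basis(r2, l2)
        rows.append([0, 0, ds2, dc2]); rhs.append(0.0)         # P2'(R2) = 0
        vs1i, vc1i, ds1i, dc1i = basis(r1, l1)
        vs2i, vc2i, ds2i, dc2i = basis(r1, l2)
        rows.append([vs1i, vc1i, -vs2i, -vc2i]); rhs.append(peq2 - peq1)
        rows.append([m1 * ds1i, m1 * dc1i, -m2 * ds2i, -m2 * dc2i]); rhs.append(0.0)
        coeff = np.linalg.solve(np.array(rows), np.array(rhs))

        r = grid.centers
        tum = grid.tumor_mask
        def profile(r, peq, length, a_c, b_c):
            vs, vc, _, _ = basis(r, length)
            return peq + a_c * vs + b_c * vc
        oracle = np.where(tum, profile(r, peq1, l1, coeff[0], coeff[1]),
                          profile(r, peq2, l2, coeff[2], coeff[3]))
        # the linear (unclamped) solution must be valid: P > P_L in healthy
        assert np.all(oracle[~tum] > s.healthy.vascular.lymphatic_pressure)
        scale = np.abs(oracle).max()
        assert np.max(np.abs(f.pressure - oracle)) / scale < 0.01

    def test_interface_flux_single_valued(self, default_sphere, small_grid):
        f = solve_flow(default_sphere, small_grid, infusing=True)
        # superficial (Darcy) flux is the conserved face quantity, so the
        # interstitial velocity jumps by the porosity ratio at the interface
        idx = int(np.argmin(np.abs(small_grid.edges
                                   - small_grid.interface_radius)))
        eps_t = default_sphere.tumor.vascular.porosity
        eps_h = default_sphere.healthy.vascular.porosity
        q = f.darcy_flux[idx]
        assert q / eps_t != pytest.approx(q / eps_h)  # velocity jumps
        # conservation already pins q itself; sanity: flux decreases ~1/r^2
        assert abs(f.darcy_flux[1]) < abs(f.darcy_flux[0])

    def test_inlet_flux_honoured(self, default_sphere, small_grid):
        f = solve_flow(default_sphere, small_grid, infusing=True)
        assert f.darcy_flux[0] == pytest.approx(
            needle_inlet_velocity(default_sphere.infusion), rel=1e-12)
        f_off = solve_flow(default_sphere, small_grid, infusing=False)
        assert f_off.darcy_flux[0] == 0.0
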