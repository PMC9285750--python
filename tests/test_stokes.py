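"""Forward Stokes solver: mass conservation, multipliers, Poiseuille oracle."""

import numpy as np
import pytest

import vasocal as vc
from vasocal.stokes import StokesOperators, section_pressure


class TestPlugProfile:
    def test_flux_equals_minus_q(self, tube2d):
        ops = StokesOperators(tube2d)
        g = ops.plug_vector(1.0)
        assert ops.phi_in @ g == pytest.approx(-1.0, abs=1e-10)

    def test_zero_flow_gives_zero_field(self, tube2d):
        g = vc.plug_inlet_profile(tube2d, 0.0)
        assert np.all(g == 0.0)

    def test_nominal_speed_is_q_over_area(self):
        mesh = vc.make_tube_mesh(1.0, 2.0, 0.25, dim=2)  # |Gamma_in| = 2
        ops = StokesOperators(mesh)
        g = ops.plug_vector(119.1 / 2.5)
        # interior inlet dofs carry ~Q/A along -n (x direction)
        speeds = g[ops.inlet_vdofs]
        nominal = (119.1 / 2.5) / 2.0
        interior = speeds[np.abs(speeds) > 0.5 * nominal]
        assert np.abs(interior).max() == pytest.approx(nominal, rel=0.1)


class TestTubeFlow:
    def test_outlet_flow_and_multiplier(self, tube2d):
        sol = vc.solve_stokes(tube2d, 0.04, vc.ResistanceSet([1000.0]), 10.0)
        assert sol.outlet_flows[0] == pytest.approx(10.0, rel=0.005)
        assert sol.lam[0] == pytest.approx(1.0e4, rel=0.005)
        assert sol.inlet_flow == pytest.approx(10.0, rel=1e-9)

    def test_free_outflow_matches_poiseuille_drop(self, tube2d):
        """With R ~ 0 the outlet pressure vanishes and the inlet mean
        pressure approaches the plane-Poiseuille drop 3 nu L Q / (2 r^3)."""
        nu, L, Q, r = 0.04, 5.0, 10.0, 0.5
        sol = vc.solve_stokes(tube2d, nu, vc.ResistanceSet([1e-12]), Q)
        p_out = section_pressure(sol, tube2d, vc.outlet_tag(1))
        p_in = section_pressure(sol, tube2d, vc.INLET)
        assert abs(p_out) < 0.02 * p_in
        drop = 3.0 * nu * L * Q / (2.0 * r ** 3)
        assert p_in - p_out == pytest.approx(drop, rel=0.10)

    def test_inlet_pressure_exceeds_multiplier(self, tube2d):
        sol = vc.solve_stokes(tube2d, 0.04, vc.ResistanceSet([1000.0]), 10.0)
        p_in = section_pressure(sol, tube2d, vc.INLET)
        assert p_in >= sol.lam[0]
        visc = 3.0 * 0.04 * 5.0 * 10.0 / (2.0 * 0.5 ** 3)
        assert p_in - sol.lam[0] == pytest.approx(visc, rel=0.15)

    def test_3d_tube_identities(self, tube3d):
        sol = vc.solve_stokes(tube3d, 0.04, vc.ResistanceSet([1000.0]), 10.0)
        assert sol.outlet_flows[0] == pytest.approx(10.0, rel=0.005)
        assert sol.lam[0] == pytest.approx(1.0e4, rel=0.005)


class TestMultiOutlet:
    def test_symmetric_geometry_equal_flows(self):
        mesh = vc.make_branching_mesh([0.4, 0.4], 0.6, 0.08)
        sol = vc.solve_stokes(mesh, 0.04, vc.ResistanceSet([5e3, 5e3]), 50.0)
        assert sol.outlet_flows[0] == pytest.approx(sol.outlet_flows[1],
                                                    rel=0.02)

    def test_mass_conservation(self, arch):
        sol = vc.solve_stokes(arch, 0.04,
                              vc.ResistanceSet([7e3, 21e3, 16e3, 1.7e3]),
                              119.1)
        assert sol.outlet_flows.sum() == pytest.approx(119.1, rel=1e-2)
        # multiplier identity holds to algebraic precision
        rel = np.abs(sol.lam - np.array([7e3, 21e3, 16e3, 1.7e3])
                     * sol.outlet_flows)
        assert np.max(rel / np.abs(sol.lam)) < 1e-6

    def test_conductance_split(self, arch):
        """With peripheral resistance >> internal viscous drop the flow
        fractions follow the 0D conductance split."""
        R = np.array([7e3, 21e3, 16e3, 1.7e3])
        sol = vc.solve_stokes(arch, 0.04, vc.ResistanceSet(R), 119.1)
        g = 1.0 / R
        expect = 119.1 * g / g.sum()
        np.testing.assert_allclose(sol.outlet_flows, expect, rtol=0.02)

    def test_outlet_flow_accessor(self, arch):
        sol = vc.solve_stokes(arch, 0.04,
                              vc.ResistanceSet([7e3, 21e3, 16e3, 1.7e3]),
                              119.1)
        assert vc.outlet_flow(sol, 0) == sol.outlet_flows[0]
        with pytest.raises(IndexError):
            vc.outlet_flow(sol, 4)


class TestSectionPressure:
    def test_constant_field(self, tube2d):
        sol = vc.solve_stokes(tube2d, 0.04, vc.ResistanceSet([10.0]), 1.0)
        sol.pressure[:] = 7.25
        assert section_pressure(sol, tube2d, vc.INLET) == pytest.approx(7.25)

    def test_linear_field_on_plane(self, tube2d):
        sol = vc.solve_stokes(tube2d, 0.04, vc.ResistanceSet([10.0]), 1.0)
        sol.pressure[:] = 2.0 * tube2d.vertices[:, 0] + 1.0
        # outlet plane sits at x = 5
        assert section_pressure(sol, tube2d, vc.outlet_tag(1)) == \
            pytest.approx(11.0, rel=1e-12)

    def test_unknown_tag_rejected(self, tube2d):
        sol = vc.solve_stokes(tube2d, 0.04, vc.ResistanceSet([10.0]), 1.0)
        with pytest.raises(KeyError):
            section_pressure(sol, tube2d, 99)


class TestValidation:
    def test_viscosity_must_be_positive(self, tube2d):
        with pytest.raises(ValueError):
            vc.solve_stokes(tube2d, 0.0, vc.ResistanceSet([1.0]), 1.0)

    def test_resistance_count_must_match(self, arch):
        with pytest.raises(ValueError):
            vc.solve_stokes(arch, 0.04, vc.ResistanceSet([1.0]), 1.0)

    def test_negative_resistance_rejected(self):
        with pytest.raises(ValueError):
            vc.ResistanceSet([-5.0])
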