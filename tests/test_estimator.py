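"""Optimal-control estimator: functional, recovery, adjoint consistency."""

import numpy as np
import pytest

import vasocal as vc
from vasocal.estimator import ResistanceEstimator, cost_functional
from vasocal.stokes import StokesOperators

from conftest import R_TRUE, Q_IN


class TestCostFunctional:
    def _exact_state(self, mesh, ops, meas):
        sol = ops.solve(vc.ResistanceSet(meas.p_d / meas.Q_out), meas.Q_in)
        sol.pressure[:] = meas.p_d
        sol.outlet_flows = meas.Q_out.copy()
        return sol

    def test_perfect_fit_is_zero(self, tube2d, tube_meas):
        ops = StokesOperators(tube2d)
        sol = self._exact_state(tube2d, ops, tube_meas)
        assert cost_functional(sol, tube_meas, tube2d, _ops=ops) == \
            pytest.approx(0.0, abs=1e-14)

    def test_ten_percent_pressure_offset(self, tube2d, tube_meas):
        ops = StokesOperators(tube2d)
        sol = self._exact_state(tube2d, ops, tube_meas)
        sol.pressure[:] = 1.1 * tube_meas.p_d
        assert cost_functional(sol, tube_meas, tube2d, _ops=ops) == \
            pytest.approx(0.005, rel=1e-10)

    def test_doubled_flow_without_pressure_term(self, tube2d, tube_meas):
        import dataclasses
        meas = dataclasses.replace(tube_meas, alpha_p=0.0,
                                   Q_out=tube_meas.Q_out.copy())
        ops = StokesOperators(tube2d)
        sol = self._exact_state(tube2d, ops, meas)
        sol.outlet_flows = 2.0 * meas.Q_out
        assert cost_functional(sol, meas, tube2d, _ops=ops) == \
            pytest.approx(0.5, rel=1e-12)

    def test_zero_measured_flow_rejected(self):
        with pytest.raises(ValueError):
            vc.MeasurementSet(p_d=1e5, Q_in=10.0, Q_out=[0.0])


class TestRecovery:
    def test_single_outlet_tube(self, tube_fit):
        assert tube_fit.params[0] == pytest.approx(1000.0, rel=0.005)
        assert tube_fit.converged

    def test_four_outlet_arch(self, arch_fit):
        np.testing.assert_allclose(arch_fit.params, R_TRUE, rtol=0.01)

    def test_recovery_insensitive_to_mesh_size(self):
        """Recovered resistances stay within 1% of truth across mesh
        resolutions (mass-consistent data)."""
        for h in (0.14, 0.1):
            mesh = vc.make_branching_mesh([0.4, 0.25, 0.3, 0.8], 1.0, h)
            meas = vc.make_synthetic_case(mesh, vc.ResistanceSet(R_TRUE), Q_IN)
            fit = vc.solve_ocp(mesh, meas)
            np.testing.assert_allclose(fit.params, R_TRUE, rtol=0.01)

    def test_assimilated_flows_match_consistent_data(self, arch_fit, arch_meas):
        np.testing.assert_allclose(arch_fit.predicted_flows, arch_meas.Q_out,
                                   rtol=0.005)

    def test_aux_flows_equal_state_fluxes(self, arch_fit):
        np.testing.assert_allclose(arch_fit.aux_flows,
                                   arch_fit.state.outlet_flows, rtol=1e-8)

    def test_optimum_at_most_cost_of_truth(self, arch, arch_meas, arch_fit):
        ops = arch_fit.model.ops
        J_truth = cost_functional(ops.solve(vc.ResistanceSet(R_TRUE), Q_IN),
                                  arch_meas, arch, _ops=ops)
        assert arch_fit.J <= J_truth * (1.0 + 1e-6)

    def test_objective_dominates_ohm_forward(self, arch, arch_meas_13,
                                             arch_fit_13):
        """J at the OCP optimum is no worse than J of the forward solve
        with Ohm's-law resistances."""
        ops = arch_fit_13.model.ops
        R_ohm = vc.ResistanceSet(arch_meas_13.p_d / arch_meas_13.Q_out)
        J_ohm = cost_functional(ops.solve(R_ohm, Q_IN), arch_meas_13, arch,
                                _ops=ops)
        assert arch_fit_13.J <= J_ohm


class TestOptimalityResiduals:
    def test_converged_residuals_small(self, arch_fit):
        for name, val in arch_fit.residuals.items():
            if name == 'control_gradient':
                continue
            if name == 'control':
                assert val < 1e-6
            else:
                assert val < 1e-8, name

    def test_perturbed_controls_have_nonzero_gradient(self, tube2d,
                                                      tube_meas):
        est = ResistanceEstimator(tube2d, tube_meas)
        g = est.gradient(np.array([1100.0]))
        assert abs(g[0]) > 0.0

    def test_adjoint_gradient_matches_finite_differences(self, tube2d,
                                                         tube_meas):
        est = ResistanceEstimator(tube2d, tube_meas)
        R = np.array([1300.0])
        g_adj = est.gradient(R)[0]
        h = 1.0
        g_fd = (est.cost(R + h) - est.cost(R - h)) / (2.0 * h)
        assert g_adj == pytest.approx(g_fd, rel=0.01)


class TestInletControl:
    def test_consistent_data_keeps_inlet(self, arch, arch_meas):
        fit = vc.solve_ocp(arch, arch_meas, control_inlet=True)
        assert fit.u_in == pytest.approx(1.0, abs=1e-4)
        np.testing.assert_allclose(fit.params, R_TRUE, rtol=0.01)

    def test_summary_mentions_inlet(self, arch_fit_13_inlet):
        text = arch_fit_13_inlet.summary()
        assert "u_in" in text and "inlet control: True" in text


class TestValidation:
    def test_measurement_outlet_count_mismatch(self, arch):
        meas = vc.MeasurementSet(p_d=1e5, Q_in=100.0, Q_out=[50.0, 50.0])
        with pytest.raises(ValueError):
            ResistanceEstimator(arch, meas)
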