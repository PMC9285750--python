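"""0D calibrators: MAP, Murray, Ohm, simplex optimisation, RCR splitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import vasocal as vc
from vasocal.lumped import ohm_cost
from vasocal.units import MMHG_TO_DYN_CM2

# case 1 of the aortic-arch study: printed measurements and resistances
CASE1_PD_MMHG = 98.7
CASE1_Q0 = 119.1
CASE1_QOUT = np.array([15.9, 5.98, 8.48, 73.1])          # BCA LCC LSUB DAo
CASE1_MURRAY = np.array([6837.0, 21242.0, 17591.0, 1527.0])
CASE1_OHM = np.array([8288.0, 21979.0, 15518.0, 1800.0])
CASE1_OHM_OPT = np.array([8190.0, 21981.0, 15511.0, 1679.0])

area_vectors = st.lists(st.floats(0.05, 20.0), min_size=2, max_size=6)


class TestMeanArterialPressure:
    @pytest.mark.parametrize("sys,dia,expect", [
        (120.0, 80.0, 280.0 / 3.0),
        (97.0, 97.0, 97.0),
        (150.0, 0.0, 50.0),
    ])
    def test_values(self, sys, dia, expect):
        assert vc.mean_arterial_pressure(sys, dia) == pytest.approx(expect)

    def test_inverted_pressures_rejected(self):
        with pytest.raises(ValueError):
            vc.mean_arterial_pressure(80.0, 120.0)


class TestMurray:
    def test_two_equal_areas(self):
        R = vc.murray_resistances([2.0, 2.0], p_d=100.0, Q0=1.0)
        np.testing.assert_allclose(R.R, [200.0, 200.0])

    def test_area_ratio_three_to_one(self):
        R = vc.murray_resistances([3.0, 1.0], p_d=100.0, Q0=1.0)
        np.testing.assert_allclose(R.R, [400.0 / 3.0, 400.0], rtol=1e-13)

    @settings(deadline=None, max_examples=50)
    @given(areas=area_vectors, n=st.floats(1.5, 3.5))
    def test_parallel_combination_is_total(self, areas, n):
        R = vc.murray_resistances(areas, p_d=1.3e5, Q0=119.1, exponent_n=n)
        parallel = 1.0 / np.sum(1.0 / R.R)
        assert parallel == pytest.approx(1.3e5 / 119.1, rel=1e-12)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            vc.murray_resistances([1.0, 0.0], 100.0, 1.0)


class TestOhm:
    def test_case1_printed_row(self):
        """LSUB and DAo entries recompute exactly from printed p_d and Q_i
        (the BCA/LCC entries differ in the last digits, consistent with
        unrounded inputs having been used upstream)."""
        R = vc.ohm_resistances(CASE1_PD_MMHG * MMHG_TO_DYN_CM2, CASE1_QOUT)
        assert round(R.R[2]) == 15518
        assert round(R.R[3]) == 1800

    def test_equal_flows(self):
        R = vc.ohm_resistances(100.0, [50.0, 50.0])
        np.testing.assert_allclose(R.R, [2.0, 2.0])

    def test_zero_flow_rejected(self):
        with pytest.raises(ValueError):
            vc.ohm_resistances(100.0, [50.0, 0.0])


class TestOhmOptimisation:
    def test_consistent_data_returns_ohm(self):
        Q = np.array([30.0, 70.0])
        p_d = 1.0e5
        R = vc.ohm_opt_resistances(p_d, Q.sum(), Q)
        np.testing.assert_allclose(R.R, p_d / Q, rtol=1e-6)
        assert ohm_cost(R.R, p_d, Q.sum(), Q) < 1e-10

    def test_pressure_weight_zero_decouples(self):
        Q = np.array([20.0, 80.0])
        R = vc.ohm_opt_resistances(1.0e5, 110.0, Q, alpha_p=0.0)
        np.testing.assert_allclose(R.R, 1.0e5 / Q, rtol=1e-12)

    def test_case1_objective_dominates_printed_row(self):
        p_d = CASE1_PD_MMHG * MMHG_TO_DYN_CM2
        R = vc.ohm_opt_resistances(p_d, CASE1_Q0, CASE1_QOUT)
        J_ours = ohm_cost(R.R, p_d, CASE1_Q0, CASE1_QOUT)
        J_printed = ohm_cost(CASE1_OHM_OPT, p_d, CASE1_Q0, CASE1_QOUT)
        assert J_ours <= J_printed + 1e-14

    @settings(deadline=None, max_examples=20)
    @given(flows=st.lists(st.floats(1.0, 90.0), min_size=2, max_size=5),
           violation=st.floats(0.0, 0.14))
    def test_descent_from_ohm_start(self, flows, violation):
        Q = np.asarray(flows)
        Q0 = Q.sum() / (1.0 - violation)
        p_d = 1.3e5
        R = vc.ohm_opt_resistances(p_d, Q0, Q)
        assert ohm_cost(R.R, p_d, Q0, Q) <= \
            ohm_cost(p_d / Q, p_d, Q0, Q) + 1e-14


class TestNetworkForward:
    def test_single_branch(self):
        flows, p = vc.network_forward(vc.ResistanceSet([1234.0]), 10.0)
        assert flows[0] == pytest.approx(10.0)
        assert p == pytest.approx(12340.0)

    def test_case1_murray_split(self):
        flows, _ = vc.network_forward(vc.ResistanceSet(CASE1_MURRAY), CASE1_Q0)
        assert float(f"{flows[0]:.3g}") == 19.2     # BCA
        assert float(f"{flows[2]:.3g}") == 7.48     # LSUB

    def test_case1_ohm_opt_pressure(self):
        _, p = vc.network_forward(vc.ResistanceSet(CASE1_OHM_OPT), CASE1_Q0)
        assert round(p / MMHG_TO_DYN_CM2) == 108

    @settings(deadline=None, max_examples=50)
    @given(areas=area_vectors, scale=st.floats(0.01, 100.0),
           q0=st.floats(1.0, 200.0))
    def test_mass_conservation_and_scaling(self, areas, scale, q0):
        R = vc.ResistanceSet(np.asarray(areas) * 1e3)
        flows, p = vc.network_forward(R, q0)
        assert flows.sum() == pytest.approx(q0, rel=1e-14)
        flows2, p2 = vc.network_forward(vc.ResistanceSet(R.R * scale), q0)
        np.testing.assert_allclose(flows2, flows, rtol=1e-12)
        assert p2 == pytest.approx(p * scale, rel=1e-12)

    def test_ohm_resistances_overpredict_uniformly(self):
        """With inconsistent data, the network with plain Ohm resistances
        over-predicts every outlet by the same factor Q0/sum(Q_i)."""
        p_d = CASE1_PD_MMHG * MMHG_TO_DYN_CM2
        R = vc.ohm_resistances(p_d, CASE1_QOUT)
        flows, _ = vc.network_forward(R, CASE1_Q0)
        factor = CASE1_Q0 / CASE1_QOUT.sum()
        np.testing.assert_allclose(flows / CASE1_QOUT, factor, rtol=1e-12)


class TestSplitRCR:
    def test_nine_percent_split(self):
        br = vc.split_rcr(vc.ResistanceSet([1000.0]), 1e-3, [1.0])
        assert br[0].R_proximal == pytest.approx(90.0)
        assert br[0].R_distal == pytest.approx(910.0)
        assert br[0].R_total == pytest.approx(1000.0, rel=1e-12)
        assert br[0].P_distal == 0.0

    def test_equal_area_compliance_split(self):
        br = vc.split_rcr(vc.ResistanceSet([1e3] * 4), 1e-3, [2.0] * 4)
        for b in br:
            assert b.C == pytest.approx(2.5e-4, rel=1e-15)

    @settings(deadline=None, max_examples=50)
    @given(areas=area_vectors)
    def test_compliances_sum_to_total(self, areas):
        R = vc.ResistanceSet(np.full(len(areas), 1e3))
        br = vc.split_rcr(R, 1e-3, areas)
        assert sum(b.C for b in br) == pytest.approx(1e-3, rel=1e-12)

    @pytest.mark.parametrize("frac", [0.0, 1.0, -0.2, 1.5])
    def test_fraction_outside_unit_interval_rejected(self, frac):
        with pytest.raises(ValueError):
            vc.split_rcr(vc.ResistanceSet([1e3]), 1e-3, [1.0],
                         proximal_fraction=frac)


class TestNetFlowReport:
    def test_consistent_measurements(self):
        meas = vc.MeasurementSet(p_d=1e5, Q_in=100.0, Q_out=[40.0, 60.0])
        net, pct = vc.net_flow_report(meas)
        assert net == 0.0 and pct == 0.0
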