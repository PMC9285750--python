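"""Wall shear stress postprocessing: traction, TAWSS, OSI, difference maps."""

import numpy as np
import pytest

import vasocal as vc
from vasocal.fem import TaylorHoodSpace


def brute_force_tawss(times, vecs):
    """Independent trapezoidal quadrature of |tau| done location by location."""
    T = times[-1] - times[0]
    out = np.empty(vecs.shape[1])
    for loc in range(vecs.shape[1]):
        mag = [np.sqrt(np.sum(vecs[n, loc] ** 2)) for n in range(len(times))]
        acc = 0.0
        for n in range(len(times) - 1):
            acc += 0.5 * (mag[n] + mag[n + 1]) * (times[n + 1] - times[n])
        out[loc] = acc / T
    return out


def brute_force_osi(times, vecs):
    out = np.empty(vecs.shape[1])
    for loc in range(vecs.shape[1]):
        mean_vec = np.zeros(vecs.shape[2])
        mag_int = 0.0
        for n in range(len(times) - 1):
            dt = times[n + 1] - times[n]
            mean_vec += 0.5 * (vecs[n, loc] + vecs[n + 1, loc]) * dt
            mag_int += 0.5 * (np.linalg.norm(vecs[n, loc])
                              + np.linalg.norm(vecs[n + 1, loc])) * dt
        out[loc] = 0.5 * (1.0 - np.linalg.norm(mean_vec) / mag_int)
    return out


class TestWSSFromVelocity:
    def test_poiseuille_wall_shear(self, tube2d):
        """Developed channel flow: |WSS| = 3 nu Q / (2 r^2) at the wall."""
        nu, Q, r = 0.04, 10.0, 0.5
        sol = vc.solve_stokes(tube2d, nu, vc.ResistanceSet([100.0]), Q)
        tau, cent = vc.wss_from_velocity(sol, tube2d, nu)
        mid = (cent[:, 0] > 2.0) & (cent[:, 0] < 4.0)
        analytic = 3.0 * nu * Q / (2.0 * r ** 2)
        np.testing.assert_allclose(np.linalg.norm(tau[mid], axis=1),
                                   analytic, rtol=0.10)

    def test_zero_velocity_zero_traction(self, tube2d):
        sol = vc.solve_stokes(tube2d, 0.04, vc.ResistanceSet([100.0]), 1.0)
        sol.velocity[:] = 0.0
        tau, _ = vc.wss_from_velocity(sol, tube2d, 0.04)
        assert np.abs(tau).max() == 0.0

    def test_rigid_rotation_has_no_shear(self, tube2d):
        sol = vc.solve_stokes(tube2d, 0.04, vc.ResistanceSet([100.0]), 1.0)
        space = TaylorHoodSpace(tube2d)
        x = space.node_coords
        sol.velocity = np.column_stack([-x[:, 1], x[:, 0]])
        tau, _ = vc.wss_from_velocity(sol, tube2d, 0.04)
        assert np.abs(tau).max() < 1e-11


class TestTAWSS:
    def test_constant_vector(self):
        t = np.linspace(0.0, 1.0, 11)
        vecs = np.tile([3.0, 4.0], (11, 5, 1))
        series = vc.WallFieldSeries(t, vecs)
        np.testing.assert_allclose(vc.tawss(series), 5.0, rtol=1e-14)

    def test_sign_flip_is_invisible_to_magnitude(self):
        t = np.array([0.0, 0.5, 1.0])
        tau0 = np.array([2.0, 0.0])
        vecs = np.array([[tau0], [tau0], [-tau0]])
        series = vc.WallFieldSeries(t, vecs)
        assert vc.tawss(series)[0] == pytest.approx(2.0)

    def test_random_series_matches_quadrature_oracle(self):
        rng = np.random.default_rng(7)
        t = np.sort(rng.uniform(0, 1, 30))
        t[0], t[-1] = 0.0, 1.0
        vecs = rng.standard_normal((30, 8, 3))
        series = vc.WallFieldSeries(t, vecs)
        np.testing.assert_allclose(vc.tawss(series),
                                   brute_force_tawss(t, vecs), rtol=1e-12)

    def test_single_sample_rejected(self):
        series = vc.WallFieldSeries(np.array([0.0]), np.zeros((1, 2, 2)))
        with pytest.raises(ValueError):
            vc.tawss(series)


class TestOSI:
    def test_unidirectional_is_zero(self):
        t = np.linspace(0.0, 1.0, 21)
        a = 1.0 + np.sin(2 * np.pi * t) ** 2
        vecs = np.einsum('n,d->nd', a, [1.0, 0.0])[:, None, :]
        series = vc.WallFieldSeries(t, vecs)
        assert vc.osi(series)[0] == pytest.approx(0.0, abs=1e-14)

    def test_perfect_reversal_is_half(self):
        t = np.array([0.0, 0.5, 1.0])
        tau0 = np.array([1.5, 0.0])
        vecs = np.array([[tau0], [0.0 * tau0], [-tau0]])
        series = vc.WallFieldSeries(t, vecs)
        assert vc.osi(series)[0] == pytest.approx(0.5)

    def test_random_series_matches_quadrature_oracle(self):
        rng = np.random.default_rng(11)
        t = np.linspace(0.0, 0.8, 40)
        vecs = rng.standard_normal((40, 6, 2))
        series = vc.WallFieldSeries(t, vecs)
        got = vc.osi(series)
        np.testing.assert_allclose(np.asarray(got),
                                   brute_force_osi(t, vecs), atol=1e-12)

    def test_bounds_and_time_rescaling_invariance(self):
        rng = np.random.default_rng(3)
        t = np.linspace(0.0, 1.0, 25)
        a = np.abs(rng.standard_normal(25)) + 0.1
        vecs = np.einsum('n,d->nd', a, [0.6, 0.8])[:, None, :]
        series = vc.WallFieldSeries(t, vecs)
        assert vc.osi(series)[0] == pytest.approx(0.0, abs=1e-14)
        stretched = vc.WallFieldSeries(2.5 * t, vecs)
        assert vc.osi(stretched)[0] == pytest.approx(0.0, abs=1e-14)
        random_series = vc.WallFieldSeries(
            t, rng.standard_normal((25, 9, 3)))
        vals = np.asarray(vc.osi(random_series))
        assert np.all(vals >= 0.0) and np.all(vals <= 0.5)

    def test_all_zero_series_masked_with_warning(self):
        series = vc.WallFieldSeries(np.linspace(0, 1, 5),
                                    np.zeros((5, 3, 2)))
        with pytest.warns(RuntimeWarning):
            out = vc.osi(series)
        assert np.all(out.mask)


class TestRelativeDifferenceMap:
    def test_identical_fields(self):
        f = np.array([1.0, 2.0, 3.0])
        np.testing.assert_array_equal(vc.relative_difference_map(f, f),
                                      np.zeros(3))

    def test_scaled_field_at_argmax(self):
        ref = np.array([0.5, 2.0, 1.0])
        field = 1.248 * ref
        eps = vc.relative_difference_map(field, ref)
        assert eps[1] == pytest.approx(0.248, rel=1e-12)

    def test_homogeneity(self):
        rng = np.random.default_rng(5)
        ref = np.abs(rng.standard_normal(20)) + 0.1
        field = np.abs(rng.standard_normal(20))
        e1 = vc.relative_difference_map(field, ref)
        e2 = vc.relative_difference_map(3.7 * field, 3.7 * ref)
        np.testing.assert_allclose(e1, e2, rtol=1e-12)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            vc.relative_difference_map(np.ones(3), np.zeros(3))
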