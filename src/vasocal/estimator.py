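"""One-shot adjoint estimation of resistive outlet boundary conditions.

The estimator treats the outlet resistances R_i (and optionally a scalar
inlet factor u_in) as control variables of an optimal control problem
constrained by the steady Stokes state system with multiplier-imposed
resistive outlets.  The assimilation functional is

    J = alpha_p/2 * int_Gp (p - p_d)^2 dG / int_Gp p_d^2 dG
      + sum_i alpha_i/2 * (Qhat_i - Q_i)^2 / Q_i^2
      [ + alpha_in/2 * (Qhat_in - Q_in)^2 / Q_in^2 ],

where Qhat_i are the computed outlet fluxes, Q_i / Q_in / p_d the
measurements and Gp a tagged pressure section (the inlet by default).
Stationarity of the Lagrangian yields a coupled optimality system: the
state equations, the adjoint equations for (z, b, t), the control
equations, and auxiliary flux identities k_i = int_Gi v.n that remove the
product-of-integrals terms.  The system is solved monolithically
("one-shot"): the two bilinear products (R_i with the outlet flux, and
t_i with the flux in the control equation) are resolved by Picard
iteration, lagging the flux; at the optimum t_i = 0 exactly, so the
lagging is consistent.  The initial resistances come from Ohm's law on the
measurements.

Model/Results layout: build a :class:`ResistanceEstimator` from a mesh and
a :class:`~vasocal.measurements.MeasurementSet`, call :meth:`fit`, and
read the estimates off the returned :class:`ResistanceEstimationResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .fem import apply_dirichlet_rows
from .measurements import MeasurementSet
from .meshing import VesselMesh
from .stokes import DEFAULT_VISCOSITY, ResistanceSet, StokesOperators, \
    StokesSolution
from .units import cgs_to_mmhg


# ---------------------------------------------------------------------------
# cost functional
# ---------------------------------------------------------------------------

def cost_functional(state: StokesSolution, meas: MeasurementSet,
                    mesh: VesselMesh, control_inlet: bool = False,
                    _ops: StokesOperators | None = None) -> float:
    """Evaluate the (dimensionless) assimilation functional J."""
    ops = _ops if _ops is not None else StokesOperators(mesh)
    space = ops.space
    ids = mesh.facet_indices(meas.pressure_section)
    M = space.facet_mass_p1(ids)
    m = space.facet_int_p1(ids)
    area = mesh.facet_measures()[ids].sum()
    p = state.pressure
    press_sq = float(p @ (M @ p)) - 2.0 * meas.p_d * float(m @ p) \
        + meas.p_d ** 2 * area
    J = 0.5 * meas.alpha_p * press_sq / (meas.p_d ** 2 * area)
    J += 0.5 * np.sum(meas.alpha_out
                      * (state.outlet_flows - meas.Q_out) ** 2 / meas.Q_out ** 2)
    if control_inlet:
        J += 0.5 * meas.alpha_in * (state.inlet_flow - meas.Q_in) ** 2 \
            / meas.Q_in ** 2
    return float(J)


# ---------------------------------------------------------------------------
# results object
# ---------------------------------------------------------------------------

@dataclass
class ResistanceEstimationResults:
    """Estimates and diagnostics of a fitted :class:`ResistanceEstimator`.

    ``params`` holds the estimated resistances (dyn.s/cm^5, ascending
    outlet tag); ``u_in`` is the inlet scale factor (1 when inlet control
    is disabled).  The attached state is the assimilated Stokes solution;
    z, b, t are the adjoint velocity/pressure/outlet multipliers and k the
    auxiliary outlet fluxes.
    """

    model: "ResistanceEstimator"
    params: np.ndarray
    u_in: float
    J: float
    n_iter: int
    converged: bool
    state: StokesSolution
    adjoint_velocity: np.ndarray
    adjoint_pressure: np.ndarray
    adjoint_multipliers: np.ndarray
    aux_flows: np.ndarray
    k_in: float | None
    residuals: dict = field(default_factory=dict)

    @property
    def resistances(self) -> ResistanceSet:
        return ResistanceSet(self.params)

    @property
    def predicted_flows(self) -> np.ndarray:
        return self.state.outlet_flows

    @property
    def predicted_pressure(self) -> float:
        """Mean pressure on the pressure section, dyn/cm^2."""
        from .stokes import section_pressure
        return section_pressure(self.state, self.model.mesh,
                                self.model.meas.pressure_section)

    @property
    def flow_errors_pct(self) -> np.ndarray:
        meas = self.model.meas
        return 100.0 * (self.predicted_flows - meas.Q_out) / meas.Q_out

    @property
    def pressure_error_pct(self) -> float:
        meas = self.model.meas
        return 100.0 * (self.predicted_pressure - meas.p_d) / meas.p_d

    def summary(self) -> str:
        meas = self.model.meas
        lines = [
            "Resistance estimation (adjoint optimal control, steady Stokes)",
            "=" * 64,
            f"outlets: {len(self.params)}   inlet control: "
            f"{self.model.control_inlet}   Picard iterations: {self.n_iter}"
            f"   converged: {self.converged}",
            f"J = {self.J:.6e}",
            f"pressure: target {cgs_to_mmhg(meas.p_d):8.2f} mmHg   "
            f"assimilated {cgs_to_mmhg(self.predicted_pressure):8.2f} mmHg "
            f"({self.pressure_error_pct:+.1f}%)",
        ]
        if self.model.control_inlet:
            lines.append(
                f"inlet flow: measured {meas.Q_in:8.2f} cm3/s   recovered "
                f"{self.state.inlet_flow:8.2f} cm3/s (u_in = {self.u_in:.4f})")
        lines.append("-" * 64)
        lines.append(f"{'outlet':>6} {'R (dyn.s/cm5)':>16} "
                     f"{'Q meas':>10} {'Q fit':>10} {'err %':>8}")
        for i, tag in enumerate(self.model.mesh.outlet_tags):
            lines.append(
                f"{tag:>6} {self.params[i]:>16.1f} {meas.Q_out[i]:>10.3f} "
                f"{self.predicted_flows[i]:>10.3f} "
                f"{self.flow_errors_pct[i]:>8.2f}")
        return "\n".join(lines)


#: Spec-facing alias: the OCP solution bundle.
OCPSolution = ResistanceEstimationResults


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class ResistanceEstimator:
    """Optimal-control estimator of resistive outlet boundary conditions.

    Parameters
    ----------
    mesh : VesselMesh
        Tagged vessel mesh (one inlet, >= 1 outlets).
    meas : MeasurementSet
        Pressure/flow targets and weights.
    viscosity : float
        Fluid viscosity, poise (CGS, unit density), default 0.04.
    control_inlet : bool
        If True, also estimate a scalar inlet factor u_in; the inlet
        Dirichlet condition is then imposed weakly through a Lagrange
        multiplier field on the inlet trace space.
    traction_correction : bool
        Include the outlet terms that remove the tangential natural
        traction (default True).
    """

    def __init__(self, mesh: VesselMesh, meas: MeasurementSet,
                 viscosity: float = DEFAULT_VISCOSITY,
                 control_inlet: bool = False,
                 traction_correction: bool = True):
        if len(meas.Q_out) != mesh.n_outlets:
            raise ValueError("measurement/outlet count mismatch")
        self.mesh = mesh
        self.meas = meas
        self.control_inlet = bool(control_inlet)
        self.ops = StokesOperators(mesh, viscosity, traction_correction)
        space = self.ops.space
        ids = mesh.facet_indices(meas.pressure_section)
        self._Mp = space.facet_mass_p1(ids)
        self._mp = space.facet_int_p1(ids)
        self._area_p = float(mesh.facet_measures()[ids].sum())
        if self.control_inlet:
            Mfull = sp.kron(space.facet_mass_p2(mesh.facet_indices(1)),
                            sp.identity(space.dim), format='csr')
            self._trace_dofs = self.ops.inlet_vdofs
            self._C = Mfull[self._trace_dofs, :].tocsr()

    # -- pieces ----------------------------------------------------------
    @property
    def _alpha(self) -> np.ndarray:
        return self.meas.alpha_out

    def _forward(self, R: np.ndarray, u_in: float = 1.0) -> StokesSolution:
        return self.ops.solve(ResistanceSet(R), u_in * self.meas.Q_in)

    def cost(self, R: np.ndarray, u_in: float = 1.0) -> float:
        """J at the forward Stokes solution for the given controls."""
        state = self._forward(R, u_in)
        return cost_functional(state, self.meas, self.mesh,
                               self.control_inlet, _ops=self.ops)

    # -- adjoint solve at fixed controls ---------------------------------
    def solve_adjoint(self, state: StokesSolution, R: np.ndarray):
        """Adjoint variables (z, b, t) at a forward state (fixed controls)."""
        ops, meas = self.ops, self.meas
        nvd, npd = ops.space.n_vdof, ops.space.n_pdof
        no = self.mesh.n_outlets
        Phi = ops.Phi
        a_q2 = self._alpha / meas.Q_out ** 2
        wp = meas.alpha_p / (meas.p_d ** 2 * self._area_p)
        K = sp.bmat([
            [ops.A + ops.G.T, ops.B.T, -Phi @ sp.diags(R)],
            [-ops.B, None, None],
            [Phi.T, None, sp.identity(no)]], format='csr')
        rhs = np.concatenate([
            -Phi @ (a_q2 * (state.outlet_flows - meas.Q_out)),
            wp * (meas.p_d * self._mp - self._Mp @ state.pressure),
            np.zeros(no)])
        if self.control_inlet:
            rhs[:nvd] += ops.phi_in * (meas.alpha_in / meas.Q_in ** 2) \
                * (state.inlet_flow - meas.Q_in)
        fixed = np.concatenate([ops.wall_vdofs, ops.inlet_vdofs])
        K = apply_dirichlet_rows(K, rhs, fixed, np.zeros(fixed.size))
        x = spla.spsolve(K.tocsc(), rhs)
        z = x[:nvd]
        b = x[nvd:nvd + npd]
        t = x[nvd + npd:]
        return z, b, t

    def gradient(self, R: np.ndarray) -> np.ndarray:
        """Adjoint gradient dJ/dR at fixed-inlet controls."""
        state = self._forward(R)
        _, _, t = self.solve_adjoint(state, R)
        return -t * state.outlet_flows

    # -- one-shot system --------------------------------------------------
    def _assemble(self, Qhat: np.ndarray, Rm: np.ndarray):
        """Linearised one-shot optimality system at lagged fluxes Qhat."""
        ops, meas, mesh = self.ops, self.meas, self.mesh
        space = ops.space
        nvd, npd, no = space.n_vdof, space.n_pdof, mesh.n_outlets
        Phi, phi_in = ops.Phi, ops.phi_in
        A, G, B = ops.A, ops.G, ops.B
        a_q2 = sp.diags(self._alpha / meas.Q_out ** 2)
        wp = meas.alpha_p / (meas.p_d ** 2 * self._area_p)
        Z = None

        if not self.control_inlet:
            # cols: v, p, lam, z, b, t, k, R
            K = sp.bmat([
                [A + G, -B.T, Phi, Z, Z, Z, Z, Z],
                [B, Z, Z, Z, Z, Z, Z, Z],
                [Z, Z, sp.identity(no), Z, Z, Z, Z, -sp.diags(Qhat)],
                [Z, Z, Z, A + G.T, B.T, -Phi @ sp.diags(Rm), Phi @ a_q2, Z],
                [Z, wp * self._Mp, Z, -B, Z, Z, Z, Z],
                [Z, Z, Z, Phi.T, Z, sp.identity(no), Z, Z],
                [Z, Z, Z, Z, Z, sp.diags(Qhat), Z, Z],
                [-Phi.T, Z, Z, Z, Z, Z, sp.identity(no), Z],
            ], format='csr')
            rhs = np.zeros(K.shape[0])
            off_adj = nvd + npd + no
            rhs[off_adj:off_adj + nvd] = Phi @ (self._alpha / meas.Q_out)
            rhs[off_adj + nvd:off_adj + nvd + npd] = wp * meas.p_d * self._mp
            offsets = dict(v=0, p=nvd, lam=nvd + npd, z=off_adj,
                           b=off_adj + nvd, t=off_adj + nvd + npd,
                           k=off_adj + nvd + npd + no,
                           R=off_adj + nvd + npd + 2 * no,
                           row_v=0, row_z=off_adj)
            return K, rhs, offsets

        # inlet-control layout
        C = self._C
        ntr = C.shape[0]
        g_in = ops.plug_vector(meas.Q_in)
        Cg = sp.csr_matrix((C @ g_in).reshape(-1, 1))
        a_in = meas.alpha_in / meas.Q_in ** 2
        col_kin = sp.csr_matrix((-a_in * phi_in).reshape(-1, 1))
        phi_in_col = sp.csr_matrix(phi_in.reshape(-1, 1))
        one = sp.identity(1, format='csr')
        # cols: v, p, lam, mu, uin, z, b, t, k, zeta, kin, R
        K = sp.bmat([
            [A + G, -B.T, Phi, C.T, Z, Z, Z, Z, Z, Z, Z, Z],
            [B, Z, Z, Z, Z, Z, Z, Z, Z, Z, Z, Z],
            [Z, Z, sp.identity(no), Z, Z, Z, Z, Z, Z, Z, Z, -sp.diags(Qhat)],
            [C, Z, Z, Z, -Cg, Z, Z, Z, Z, Z, Z, Z],
            [Z, Z, Z, Z, Z, A + G.T, B.T, -Phi @ sp.diags(Rm), Phi @ a_q2,
             C.T, col_kin, Z],
            [Z, wp * self._Mp, Z, Z, Z, -B, Z, Z, Z, Z, Z, Z],
            [Z, Z, Z, Z, Z, Phi.T, Z, sp.identity(no), Z, Z, Z, Z],
            [Z, Z, Z, Z, Z, C, Z, Z, Z, Z, Z, Z],
            [Z, Z, Z, Z, Z, Z, Z, Z, Z, Cg.T, Z, Z],
            [Z, Z, Z, Z, Z, Z, Z, sp.diags(Qhat), Z, Z, Z, Z],
            [-Phi.T, Z, Z, Z, Z, Z, Z, Z, sp.identity(no), Z, Z, Z],
            [phi_in_col.T, Z, Z, Z, Z, Z, Z, Z, Z, Z, one, Z],
        ], format='csr')
        rhs = np.zeros(K.shape[0])
        off_adj = nvd + npd + no + ntr
        rhs[off_adj:off_adj + nvd] = Phi @ (self._alpha / meas.Q_out) \
            - (meas.alpha_in / meas.Q_in) * phi_in
        rhs[off_adj + nvd:off_adj + nvd + npd] = wp * meas.p_d * self._mp
        offsets = dict(v=0, p=nvd, lam=nvd + npd, mu=nvd + npd + no,
                       uin=nvd + npd + no + ntr, row_v=0, row_z=off_adj)
        offsets['z'] = offsets['uin'] + 1
        offsets['b'] = offsets['z'] + nvd
        offsets['t'] = offsets['b'] + npd
        offsets['k'] = offsets['t'] + no
        offsets['zeta'] = offsets['k'] + no
        offsets['kin'] = offsets['zeta'] + ntr
        offsets['R'] = offsets['kin'] + 1
        return K, rhs, offsets

    def _column_scales(self, off: dict) -> np.ndarray:
        """Physical block scaling of the monolithic unknown vector.

        Raw CGS units leave the one-shot matrix badly conditioned (the
        constant-pressure mode has curvature alpha_p/p_d^2 ~ 1e-11 against
        O(1) constraint entries); measuring pressures in units of p_d and
        flows in units of Q_in restores a solvable spread.
        """
        meas = self.meas
        space = self.ops.space
        nvd, npd, no = space.n_vdof, space.n_pdof, self.mesh.n_outlets
        P0, Q0 = meas.p_d, meas.Q_in
        V0 = Q0 / self.mesh.inlet_area
        amax = max(float(np.max(meas.alpha_out)), meas.alpha_p,
                   meas.alpha_in, 1e-6)
        Vz = amax / (self.ops.nu * Q0)
        Pz = amax / Q0
        sizes = dict(v=nvd, p=npd, lam=no, z=nvd, b=npd, t=no, k=no, R=no)
        scales = dict(v=V0, p=P0, lam=P0, z=Vz, b=Pz, t=Pz, k=Q0, R=P0 / Q0)
        if self.control_inlet:
            ntr = self._C.shape[0]
            sizes.update(mu=ntr, uin=1, zeta=ntr, kin=1)
            scales.update(mu=P0, uin=1.0, zeta=Pz, kin=Q0)
        n = sum(sizes.values())
        dc = np.ones(n)
        for name, size in sizes.items():
            dc[off[name]:off[name] + size] = scales[name]
        return dc

    def _scaled_solve(self, K: sp.csr_matrix, rhs: np.ndarray,
                      off: dict) -> np.ndarray:
        dc = self._column_scales(off)
        Kc = (K @ sp.diags(dc)).tocsr()
        rmax = np.asarray(abs(Kc).max(axis=1).todense()).ravel()
        rmax[rmax == 0] = 1.0
        dr = 1.0 / rmax
        y = spla.spsolve((sp.diags(dr) @ Kc).tocsc(), dr * rhs)
        return dc * y

    # -- fit ---------------------------------------------------------------
    def fit(self, max_iter: int = 50, rtol: float = 1e-8,
            R0: np.ndarray | None = None) -> ResistanceEstimationResults:
        """Solve the coupled optimality system by Picard-lagged one-shot
        solves and return the results object."""
        ops, meas, mesh = self.ops, self.meas, self.mesh
        space = ops.space
        nvd, npd, no = space.n_vdof, space.n_pdof, mesh.n_outlets
        if R0 is None:
            R0 = meas.p_d / meas.Q_out          # Ohm's-law start
        R = np.asarray(R0, dtype=float)
        state = self._forward(R)
        Qhat = state.outlet_flows.copy()

        converged = False
        n_iter = 0
        x = None
        for n_iter in range(1, max_iter + 1):
            if np.any(np.abs(Qhat) < 1e-12 * meas.Q_in):
                raise RuntimeError("an outlet flux vanished during the "
                                   "one-shot iteration; system is singular")
            K, rhs, off = self._assemble(Qhat, R)
            K, rhs = self._dirichlet(K, rhs, off)
            x = self._scaled_solve(K, rhs, off)
            R_new = x[off['R']:off['R'] + no]
            V = x[off['v']:off['v'] + nvd]
            Qhat = np.asarray(ops.Phi.T @ V).ravel()
            dR = np.max(np.abs(R_new - R) / np.maximum(np.abs(R), 1e-30))
            R = R_new
            if dR < rtol:
                converged = True
                break
        if not converged:
            warnings.warn(
                f"one-shot Picard iteration did not reach rtol={rtol} in "
                f"{max_iter} iterations (last dR={dR:.2e})", RuntimeWarning)
        if np.any(R <= 0):
            warnings.warn("estimated resistance is non-positive; value "
                          "reported as-is", RuntimeWarning)

        state = ops.extract_state(x[off['v']:off['v'] + nvd],
                                  x[off['p']:off['p'] + npd],
                                  x[off['lam']:off['lam'] + no])
        z = x[off['z']:off['z'] + nvd]
        b = x[off['b']:off['b'] + npd]
        t = x[off['t']:off['t'] + no]
        k = x[off['k']:off['k'] + no]
        u_in = float(x[off['uin']]) if self.control_inlet else 1.0
        k_in = float(x[off['kin']]) if self.control_inlet else None
        J = cost_functional(state, meas, mesh, self.control_inlet,
                            _ops=ops)
        res = ResistanceEstimationResults(
            model=self, params=R, u_in=u_in, J=J, n_iter=n_iter,
            converged=converged, state=state,
            adjoint_velocity=z.reshape(space.n_nodes, space.dim),
            adjoint_pressure=b, adjoint_multipliers=t, aux_flows=k,
            k_in=k_in)
        res._x = x
        res.residuals = self.optimality_residual(res)
        return res

    # -- residuals ---------------------------------------------------------
    def _dirichlet(self, K, rhs, off):
        ops = self.ops
        if self.control_inlet:
            fixed_v = ops.wall_vdofs
        else:
            fixed_v = np.concatenate([ops.wall_vdofs, ops.inlet_vdofs])
        g = ops.plug_vector(self.meas.Q_in)
        K = apply_dirichlet_rows(K, rhs, off['row_v'] + fixed_v,
                                 g[fixed_v], cols=off['v'] + fixed_v)
        K = apply_dirichlet_rows(K, rhs, off['row_z'] + fixed_v,
                                 np.zeros(fixed_v.size),
                                 cols=off['z'] + fixed_v)
        return K, rhs

    def _row_spans(self):
        space = self.ops.space
        nvd, npd, no = space.n_vdof, space.n_pdof, self.mesh.n_outlets
        if not self.control_inlet:
            names = [('state_momentum', nvd), ('state_continuity', npd),
                     ('state_multiplier', no), ('adjoint_momentum', nvd),
                     ('adjoint_continuity', npd), ('adjoint_multiplier', no),
                     ('control', no), ('aux_flux', no)]
        else:
            ntr = self._C.shape[0]
            names = [('state_momentum', nvd), ('state_continuity', npd),
                     ('state_multiplier', no), ('inlet_trace', ntr),
                     ('adjoint_momentum', nvd), ('adjoint_continuity', npd),
                     ('adjoint_multiplier', no), ('adjoint_inlet_trace', ntr),
                     ('control_inlet', 1), ('control', no),
                     ('aux_flux', no), ('aux_inlet_flux', 1)]
        spans, start = [], 0
        for name, size in names:
            spans.append((name, start, size))
            start += size
        return spans

    def optimality_residual(self, sol: ResistanceEstimationResults) -> dict:
        """Relative residual norm of every optimality equation at ``sol``.

        The monolithic system is re-assembled with the *true* bilinear
        products (the solution's own outlet fluxes, not the lagged ones)
        and each equation block's residual is scaled backward-error style
        by |K| |x| and the block right-hand side.  The ``control`` entry is
        the dimensionless gradient dJ/d(log R_i) = -R_i t_i Qhat_i, which
        vanishes exactly at a stationary point; ``control_gradient`` is the
        raw dJ/dR vector.
        """
        if getattr(sol, '_x', None) is None:
            raise ValueError("solution does not carry its state vector")
        x = sol._x
        Qhat = sol.state.outlet_flows
        R = sol.params
        K, rhs, off = self._assemble(Qhat, R)
        K, rhs = self._dirichlet(K, rhs, off)
        r = K @ x - rhs
        scale = np.abs(K) @ np.abs(x)
        # blocks whose magnitude is negligible against the whole system are
        # measured against the problem scale instead of their own (near-zero)
        # terms, so perfect fits do not produce spurious 0/0 ratios
        floor = 1e-8 * (np.linalg.norm(scale) + np.linalg.norm(rhs))
        out = {}
        for name, start, size in self._row_spans():
            denom = max(np.linalg.norm(scale[start:start + size]),
                        np.linalg.norm(rhs[start:start + size]), floor, 1e-30)
            out[name] = float(np.linalg.norm(r[start:start + size]) / denom)
        t = sol.adjoint_multipliers
        grad = -t * Qhat
        out['control'] = float(np.linalg.norm(R * grad))
        out['control_gradient'] = grad
        return out


# ---------------------------------------------------------------------------
# operation-level API
# ---------------------------------------------------------------------------

def solve_ocp(mesh: VesselMesh, meas: MeasurementSet,
              viscosity: float = DEFAULT_VISCOSITY,
              control_inlet: bool = False,
              **fit_kwargs) -> ResistanceEstimationResults:
    """Assemble and solve the full optimality system; return the solution."""
    model = ResistanceEstimator(mesh, meas, viscosity, control_inlet)
    return model.fit(**fit_kwargs)


def optimality_residual(sol: ResistanceEstimationResults,
                        mesh: VesselMesh | None = None,
                        meas: MeasurementSet | None = None) -> dict:
    """Per-equation residual norms of the optimality system at ``sol``."""
    return sol.model.optimality_residual(sol)
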