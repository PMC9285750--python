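"""Steady Stokes flow with multiplier-imposed resistive outlets.

The state problem: find velocity v, pressure p and one scalar multiplier
lambda_i per outlet such that

    -nu Lap(v) + grad(p) = 0,   div(v) = 0        in Omega,
    v = plug inlet profile                         on Gamma_in,
    v = 0                                          on Gamma_w,
    lambda_i = R_i * int_{Gamma_i} v.n dGamma      (definition),
    natural outlet traction = -lambda_i n          on Gamma_i,

with the tangential component of the viscous natural traction removed on
the outlets (the resistive coupled-multidomain condition).  Discretised
with Taylor-Hood P2/P1 elements and solved by sparse direct factorisation
of the monolithic saddle-point system.

Density is 1 g/cm^3 (CGS) so the viscosity ``nu`` (default 0.04) acts as
the momentum-equation coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import meshing
from .fem import TaylorHoodSpace, apply_dirichlet_rows
from .meshing import VesselMesh

DEFAULT_VISCOSITY = 0.04  # dyn.s/cm^2 with unit density


@dataclass
class ResistanceSet:
    """Per-outlet resistances, dyn.s/cm^5, ordered by ascending outlet tag."""

    R: np.ndarray

    def __post_init__(self):
        self.R = np.atleast_1d(np.asarray(self.R, dtype=float))
        if np.any(self.R < 0):
            raise ValueError("resistances must be nonnegative")

    def __len__(self) -> int:
        return len(self.R)

    def __iter__(self):
        return iter(self.R)

    def match(self, mesh: VesselMesh) -> None:
        if len(self) != mesh.n_outlets:
            raise ValueError(
                f"{len(self)} resistances given for a mesh with "
                f"{mesh.n_outlets} outlets")


@dataclass
class StokesSolution:
    """Discrete Stokes state.

    velocity : (n_nodes, dim) nodal values, cm/s (P2 nodes)
    pressure : (n_vertices,) nodal values, dyn/cm^2 (P1 nodes)
    lam : (n_outlets,) outlet multipliers lambda_i, dyn/cm^2
    outlet_flows : (n_outlets,) int_{Gamma_i} v.n, cm^3/s (outflow positive)
    inlet_flow : inlet flow, cm^3/s (inflow positive)
    """

    velocity: np.ndarray
    pressure: np.ndarray
    lam: np.ndarray
    outlet_flows: np.ndarray
    inlet_flow: float


class StokesOperators:
    """Assembled operators for one (mesh, viscosity) pair, reused by the
    forward solver and by the optimal-control estimator."""

    def __init__(self, mesh: VesselMesh, viscosity: float = DEFAULT_VISCOSITY,
                 traction_correction: bool = True):
        if viscosity <= 0:
            raise ValueError("viscosity must be positive")
        mesh.validate()
        self.mesh = mesh
        self.nu = float(viscosity)
        self.traction_correction = bool(traction_correction)
        self.space = TaylorHoodSpace(mesh)

    # -- operator blocks ------------------------------------------------
    @cached_property
    def A(self) -> sp.csr_matrix:
        return self.space.vector_stiffness(self.nu)

    @cached_property
    def G(self) -> sp.csr_matrix:
        """Traction-correction terms summed over all outlets."""
        if not self.traction_correction:
            return sp.csr_matrix((self.space.n_vdof, self.space.n_vdof))
        blocks = None
        for tag in self.mesh.outlet_tags:
            ids = self.mesh.facet_indices(tag)
            Gi = self.space.boundary_traction(ids, self.nu)
            blocks = Gi if blocks is None else blocks + Gi
        return blocks.tocsr()

    @cached_property
    def B(self) -> sp.csr_matrix:
        return self.space.divergence

    @cached_property
    def Phi(self) -> sp.csr_matrix:
        """Outlet flux functionals, one column per outlet."""
        cols = [self.space.flux_vector(self.mesh.facet_indices(t))
                for t in self.mesh.outlet_tags]
        return sp.csr_matrix(np.column_stack(cols))

    @cached_property
    def phi_in(self) -> np.ndarray:
        return self.space.flux_vector(self.mesh.facet_indices(meshing.INLET))

    # -- boundary dof sets ----------------------------------------------
    @cached_property
    def wall_vdofs(self) -> np.ndarray:
        return self.space.vdofs_of_nodes(self.space.boundary_nodes(meshing.WALL))

    @cached_property
    def inlet_vdofs(self) -> np.ndarray:
        """Inlet velocity dofs excluding the wall rim (wall wins there)."""
        dofs = self.space.vdofs_of_nodes(self.space.boundary_nodes(meshing.INLET))
        return np.setdiff1d(dofs, self.wall_vdofs)

    @cached_property
    def inlet_normal(self) -> np.ndarray:
        ids = self.mesh.facet_indices(meshing.INLET)
        _, n, _, _, _, _ = self.space.facet_geometry(ids)
        return n.mean(axis=0)

    def plug_vector(self, Q_in: float) -> np.ndarray:
        """Full-length velocity dof vector for the plug inlet profile.

        The nominal datum is the uniform inward velocity -(Q/|Gamma_in|) n.
        After zeroing the wall rim (no-slip precedence) the interpolant
        loses O(h) of its flux, so the free inlet dofs are rescaled to make
        the discrete inlet flux exactly -Q_in.
        """
        if Q_in < 0:
            raise ValueError("Q_in must be nonnegative")
        area = self.mesh.inlet_area
        if area <= 0:
            raise ValueError("inlet has zero area")
        g = np.zeros(self.space.n_vdof)
        if Q_in == 0.0:
            return g
        speed = Q_in / area
        n = self.inlet_normal
        d = self.space.dim
        nodes = self.inlet_vdofs // d
        comps = self.inlet_vdofs % d
        g[self.inlet_vdofs] = -speed * n[comps]
        flux = float(self.phi_in @ g)          # ~ -Q_in * (1 - rim deficit)
        if flux >= 0:
            raise ValueError("inlet plug produced non-inward flux")
        g[self.inlet_vdofs] *= Q_in / (-flux)
        return g

    # -- forward solve ---------------------------------------------------
    def solve(self, R: ResistanceSet, Q_in: float) -> StokesSolution:
        R.match(self.mesh)
        no = self.mesh.n_outlets
        nvd, npd = self.space.n_vdof, self.space.n_pdof
        Phi = self.Phi
        K = sp.bmat([
            [self.A + self.G, -self.B.T, Phi],
            [self.B, None, None],
            [-sp.diags(R.R) @ Phi.T, None, sp.identity(no)]], format='csr')
        rhs = np.zeros(nvd + npd + no)
        g = self.plug_vector(Q_in)
        fixed = np.concatenate([self.wall_vdofs, self.inlet_vdofs])
        K = apply_dirichlet_rows(K, rhs, fixed, g[fixed])
        x = spla.spsolve(K.tocsc(), rhs)
        res = np.linalg.norm(K @ x - rhs) / max(np.linalg.norm(rhs), 1e-30)
        if res > 1e-9:
            raise RuntimeError(
                f"Stokes linear solve residual {res:.2e} exceeds 1e-9; "
                "check that inlet, wall and outlet groups are all present")
        return self.extract_state(x[:nvd], x[nvd:nvd + npd], x[nvd + npd:])

    def extract_state(self, V: np.ndarray, P: np.ndarray,
                      lam: np.ndarray) -> StokesSolution:
        d = self.space.dim
        vel = V.reshape(self.space.n_nodes, d)
        flows = np.asarray(self.Phi.T @ V).ravel()
        inlet = -float(self.phi_in @ V)
        return StokesSolution(vel, P, np.asarray(lam).ravel(), flows, inlet)


# ---------------------------------------------------------------------------
# operation-level API
# ---------------------------------------------------------------------------

def plug_inlet_profile(mesh: VesselMesh, Q_in: float,
                       viscosity: float = DEFAULT_VISCOSITY) -> np.ndarray:
    """Velocity dof vector of the plug inlet datum with exact flux -Q_in."""
    return StokesOperators(mesh, viscosity).plug_vector(Q_in)


def solve_stokes(mesh: VesselMesh, viscosity: float, R: ResistanceSet,
                 Q_in: float, traction_correction: bool = True) -> StokesSolution:
    """Solve the steady Stokes problem with resistive outlets."""
    ops = StokesOperators(mesh, viscosity, traction_correction)
    return ops.solve(R, Q_in)


def section_pressure(sol: StokesSolution, mesh: VesselMesh, section: int) -> float:
    """Area-averaged pressure over the tagged surface ``section``."""
    space = TaylorHoodSpace(mesh)
    ids = mesh.facet_indices(section)
    m = space.facet_int_p1(ids)
    area = mesh.facet_measures()[ids].sum()
    return float(m @ sol.pressure) / float(area)


def outlet_flow(sol: StokesSolution, outlet_index: int) -> float:
    """Flux through outlet ``outlet_index`` (0-based), outflow positive."""
    flows = sol.outlet_flows
    if not 0 <= outlet_index < len(flows):
        raise IndexError(f"outlet index {outlet_index} out of range")
    return float(flows[outlet_index])
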