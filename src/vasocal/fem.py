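"""Minimal Taylor-Hood finite element core on simplicial meshes.

Velocity lives in vector P2 (continuous piecewise quadratics, nodes at
vertices and edge midpoints), pressure in P1 (vertices) -- the inf-sup
stable pair used throughout the package.  Only the operators the vascular
solvers need are provided: the viscous stiffness, the velocity divergence,
boundary flux functionals, facet mass matrices, and the outlet traction
correction terms of the resistive boundary condition.

Velocity dof layout is node-major: dof = node * dim + component.
"""

from __future__ import annotations

import math
from functools import cached_property

import numpy as np
import scipy.sparse as sp

from .meshing import VesselMesh

# ---------------------------------------------------------------------------
# quadrature rules on the reference simplex, barycentric points, weights
# summing to one (scale by the cell measure when integrating)
# ---------------------------------------------------------------------------

# 3-point Gauss on an interval, exact to degree 5
_G3 = np.array([0.5 - math.sqrt(0.15), 0.5, 0.5 + math.sqrt(0.15)])
EDGE_RULE = (np.column_stack([1.0 - _G3, _G3]),
             np.array([5.0, 8.0, 5.0]) / 18.0)

# edge-midpoint rule on a triangle, exact to degree 2
TRI_RULE_2 = (np.array([[0.5, 0.5, 0.0], [0.5, 0.0, 0.5], [0.0, 0.5, 0.5]]),
              np.full(3, 1.0 / 3.0))

# Dunavant 6-point rule on a triangle, exact to degree 4
_a1, _b1 = 0.108103018168070, 0.445948490915965
_a2, _b2 = 0.816847572980459, 0.091576213509771
TRI_RULE_4 = (
    np.array([
        [_a1, _b1, _b1], [_b1, _a1, _b1], [_b1, _b1, _a1],
        [_a2, _b2, _b2], [_b2, _a2, _b2], [_b2, _b2, _a2],
    ]),
    np.array([0.223381589678011] * 3 + [0.109951743655322] * 3),
)

# 4-point rule on a tetrahedron, exact to degree 2
_at, _bt = 0.585410196624969, 0.138196601125011
TET_RULE_2 = (
    np.array([
        [_at, _bt, _bt, _bt], [_bt, _at, _bt, _bt],
        [_bt, _bt, _at, _bt], [_bt, _bt, _bt, _at],
    ]),
    np.full(4, 0.25),
)


def cell_rule(dim: int):
    """Volume rule (degree 2: enough for P2-gradient x P2-gradient)."""
    return TRI_RULE_2 if dim == 2 else TET_RULE_2


def facet_rule(dim: int):
    """Facet rule (degree >= 4: enough for P2-trace mass)."""
    return EDGE_RULE if dim == 2 else TRI_RULE_4


# ---------------------------------------------------------------------------
# P2 / P1 basis evaluation in barycentric coordinates
# ---------------------------------------------------------------------------

def local_edges(dim: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(dim + 1) for j in range(i + 1, dim + 1)]


def p2_basis(lam: np.ndarray) -> np.ndarray:
    """P2 basis values; lam is (nq, nlam) -> (nq, nloc)."""
    nlam = lam.shape[1]
    cols = [lam[:, i] * (2.0 * lam[:, i] - 1.0) for i in range(nlam)]
    cols += [4.0 * lam[:, i] * lam[:, j] for i, j in local_edges(nlam - 1)]
    return np.column_stack(cols)


def p2_grad(lam: np.ndarray, gradlam: np.ndarray) -> np.ndarray:
    """P2 basis gradients.

    lam: (nq, nlam); gradlam: (nc, nlam, d) constant barycentric gradients.
    Returns (nc, nq, nloc, d).
    """
    nq, nlam = lam.shape
    nc, _, d = gradlam.shape
    edges = local_edges(nlam - 1)
    out = np.empty((nc, nq, nlam + len(edges), d))
    for a in range(nlam):
        out[:, :, a, :] = (4.0 * lam[None, :, a, None] - 1.0) * gradlam[:, None, a, :]
    for e, (i, j) in enumerate(edges):
        out[:, :, nlam + e, :] = 4.0 * (
            lam[None, :, i, None] * gradlam[:, None, j, :]
            + lam[None, :, j, None] * gradlam[:, None, i, :])
    return out


# ---------------------------------------------------------------------------
# Taylor-Hood space
# ---------------------------------------------------------------------------

class TaylorHoodSpace:
    """P2 velocity / P1 pressure dof management and assembly on a VesselMesh."""

    def __init__(self, mesh: VesselMesh):
        self.mesh = mesh
        d = mesh.dim
        cells = mesh.cells
        pairs = np.vstack([np.sort(cells[:, [i, j]], axis=1)
                           for i, j in local_edges(d)])
        edges, inverse = np.unique(pairs, axis=0, return_inverse=True)
        self.edges = edges
        self.n_vert = mesh.n_vertices
        self.n_edge = edges.shape[0]
        self.n_nodes = self.n_vert + self.n_edge
        ne_loc = len(local_edges(d))
        cell_edges = inverse.reshape(ne_loc, mesh.n_cells).T
        self.cell_nodes = np.hstack([cells, self.n_vert + cell_edges])
        self._edge_lookup = {(int(a), int(b)): k
                             for k, (a, b) in enumerate(edges)}

        # geometry
        X = mesh.vertices[cells]
        M = X[:, 1:, :] - X[:, :1, :]
        self.cell_meas = np.abs(np.linalg.det(M)) / math.factorial(d)
        Minv = np.linalg.inv(M)
        gradlam = np.empty((mesh.n_cells, d + 1, d))
        gradlam[:, 1:, :] = np.transpose(Minv, (0, 2, 1))
        gradlam[:, 0, :] = -gradlam[:, 1:, :].sum(axis=1)
        self.gradlam = gradlam
        self.cell_x0 = X[:, 0, :]

    # -- dof maps -------------------------------------------------------
    @property
    def dim(self) -> int:
        return self.mesh.dim

    @property
    def n_vdof(self) -> int:
        return self.n_nodes * self.dim

    @property
    def n_pdof(self) -> int:
        return self.n_vert

    @cached_property
    def node_coords(self) -> np.ndarray:
        mids = 0.5 * (self.mesh.vertices[self.edges[:, 0]]
                      + self.mesh.vertices[self.edges[:, 1]])
        return np.vstack([self.mesh.vertices, mids])

    def edge_node(self, a: int, b: int) -> int:
        key = (a, b) if a < b else (b, a)
        return self.n_vert + self._edge_lookup[key]

    def vdofs_of_nodes(self, nodes: np.ndarray) -> np.ndarray:
        nodes = np.asarray(nodes, dtype=np.int64)
        return (nodes[:, None] * self.dim
                + np.arange(self.dim)[None, :]).ravel()

    def barycentric(self, cell_ids: np.ndarray, x: np.ndarray) -> np.ndarray:
        """Barycentric coordinates of points x (n, d) in the given cells."""
        rel = x - self.cell_x0[cell_ids]
        lam = np.einsum('nkd,nd->nk', self.gradlam[cell_ids], rel)
        lam[:, 0] += 1.0
        return lam

    # -- volume operators ----------------------------------------------
    @cached_property
    def stiffness_p2(self) -> sp.csr_matrix:
        """Scalar P2 stiffness: int grad(phi_a) . grad(phi_b)."""
        lam, w = cell_rule(self.dim)
        G = p2_grad(lam, self.gradlam)
        K = np.einsum('q,c,cqad,cqbd->cab', w, self.cell_meas, G, G,
                      optimize=True)
        nloc = self.cell_nodes.shape[1]
        rows = np.repeat(self.cell_nodes, nloc, axis=1).ravel()
        cols = np.tile(self.cell_nodes, (1, nloc)).ravel()
        A = sp.coo_matrix((K.ravel(), (rows, cols)),
                          shape=(self.n_nodes, self.n_nodes))
        return A.tocsr()

    def vector_stiffness(self, nu: float) -> sp.csr_matrix:
        """nu * int grad(v) : grad(w) on vector P2 (node-major dofs)."""
        return sp.kron(self.stiffness_p2, sp.identity(self.dim),
                       format='csr') * nu

    @cached_property
    def divergence(self) -> sp.csr_matrix:
        """B[q, vdof] = int psi_q * d(phi_a)/dx_j  (pressure rows)."""
        lam, w = cell_rule(self.dim)
        G = p2_grad(lam, self.gradlam)          # (nc,nq,nloc,d)
        P = lam                                  # P1 basis = barycentric
        Bloc = np.einsum('q,c,qp,cqaj->cpaj', w, self.cell_meas, P, G,
                         optimize=True)
        nc, nlam, nloc, d = Bloc.shape
        prow = np.broadcast_to(self.mesh.cells[:, :, None, None],
                               Bloc.shape)
        vcol = (self.cell_nodes[:, None, :, None] * d
                + np.arange(d)[None, None, None, :])
        vcol = np.broadcast_to(vcol, Bloc.shape)
        B = sp.coo_matrix((Bloc.ravel(), (prow.ravel(), vcol.ravel())),
                          shape=(self.n_pdof, self.n_vdof))
        return B.tocsr()

    # -- facet data -----------------------------------------------------
    def facet_geometry(self, facet_ids: np.ndarray):
        """Measures, outward normals, trace-node ids and quad data."""
        mesh = self.mesh
        facets = mesh.facets[facet_ids]
        X = mesh.vertices[facets]                     # (nf, d, d)
        if self.dim == 2:
            t = X[:, 1] - X[:, 0]
            meas = np.linalg.norm(t, axis=1)
            n = np.column_stack([t[:, 1], -t[:, 0]]) / meas[:, None]
        else:
            a = X[:, 1] - X[:, 0]
            b = X[:, 2] - X[:, 0]
            cr = np.cross(a, b)
            nrm = np.linalg.norm(cr, axis=1)
            meas = 0.5 * nrm
            n = cr / nrm[:, None]
        # orient outward: away from the adjacent cell centroid
        cells = mesh.facet_cells[facet_ids]
        ccent = mesh.vertices[mesh.cells[cells]].mean(axis=1)
        fcent = X.mean(axis=1)
        flip = np.einsum('fd,fd->f', n, fcent - ccent) < 0
        n[flip] *= -1.0

        # trace P2 nodes: facet vertices then facet-edge midside nodes
        nodes = [facets]
        for i, j in local_edges(self.dim - 1):
            nodes.append(np.array([self.edge_node(a, b)
                                   for a, b in zip(facets[:, i], facets[:, j])]))
        tnodes = np.column_stack(nodes) if self.dim == 3 else np.column_stack(
            [facets, nodes[1]])
        lam, w = facet_rule(self.dim)
        phys = np.einsum('qk,fkd->fqd', lam, X)
        return meas, n, tnodes, (lam, w), phys, cells

    def flux_vector(self, facet_ids: np.ndarray) -> np.ndarray:
        """phi with phi . V = int_facets v . n  (outward normal)."""
        meas, n, tnodes, (lam, w), _, _ = self.facet_geometry(facet_ids)
        Phi = p2_basis(lam)                           # (nq, nfl)
        contrib = np.einsum('q,f,qa,fd->fad', w, meas, Phi, n)
        out = np.zeros(self.n_vdof)
        dofs = tnodes[:, :, None] * self.dim + np.arange(self.dim)[None, None, :]
        np.add.at(out, dofs.ravel(), contrib.ravel())
        return out

    def facet_mass_p2(self, facet_ids: np.ndarray) -> sp.csr_matrix:
        """Scalar facet mass on the P2 trace, (n_nodes x n_nodes)."""
        meas, _, tnodes, (lam, w), _, _ = self.facet_geometry(facet_ids)
        Phi = p2_basis(lam)
        Mloc = np.einsum('q,f,qa,qb->fab', w, meas, Phi, Phi)
        nfl = tnodes.shape[1]
        rows = np.repeat(tnodes, nfl, axis=1).ravel()
        cols = np.tile(tnodes, (1, nfl)).ravel()
        return sp.coo_matrix((Mloc.ravel(), (rows, cols)),
                             shape=(self.n_nodes, self.n_nodes)).tocsr()

    def facet_mass_p1(self, facet_ids: np.ndarray) -> sp.csr_matrix:
        """Scalar facet mass on the P1 trace, (n_vert x n_vert)."""
        meas, _, _, (lam, w), _, _ = self.facet_geometry(facet_ids)
        facets = self.mesh.facets[facet_ids]
        L = lam[:, :self.dim]                        # facet P1 basis
        Mloc = np.einsum('q,f,qa,qb->fab', w, meas, L, L)
        nfl = facets.shape[1]
        rows = np.repeat(facets, nfl, axis=1).ravel()
        cols = np.tile(facets, (1, nfl)).ravel()
        return sp.coo_matrix((Mloc.ravel(), (rows, cols)),
                             shape=(self.n_vert, self.n_vert)).tocsr()

    def facet_int_p1(self, facet_ids: np.ndarray) -> np.ndarray:
        """Vector m with m . P = int_facets p dGamma (P1 pressure)."""
        meas, _, _, (lam, w), _, _ = self.facet_geometry(facet_ids)
        facets = self.mesh.facets[facet_ids]
        L = lam[:, :self.dim]
        contrib = np.einsum('q,f,qa->fa', w, meas, L)
        out = np.zeros(self.n_vert)
        np.add.at(out, facets.ravel(), contrib.ravel())
        return out

    def boundary_traction(self, facet_ids: np.ndarray, nu: float,
                          sign_normal: float = 1.0) -> sp.csr_matrix:
        """Outlet traction-correction operator N - T on vector P2 dofs.

        (N V) . W = nu * int (w.n)(n . (grad v) n),
        (T V) . W = nu * int  w . ((grad v) n),
        so N - T subtracts the tangential component of the viscous natural
        traction on the given facets.
        """
        meas, n, tnodes, (lam, w), phys, cells = self.facet_geometry(facet_ids)
        d = self.dim
        rows, cols, vals = [], [], []
        for f in range(facet_ids.size):
            c = cells[f]
            lam_c = self.barycentric(np.full(phys.shape[1], c), phys[f])
            Gc = p2_grad(lam_c, self.gradlam[c:c + 1])[0]   # (nq, nloc, d)
            dn = Gc @ n[f]                                   # (nq, nloc)
            Phi = p2_basis(lam)                              # (nq, nfl)
            Ns = nu * meas[f] * np.einsum('q,qa,qb->ab', w, Phi, dn)
            cn = self.cell_nodes[c]
            # T: component-diagonal
            for alpha in range(d):
                rows.append(np.repeat(tnodes[f] * d + alpha, cn.size))
                cols.append(np.tile(cn * d + alpha, tnodes.shape[1]))
                vals.append(-Ns.ravel())
            # N: n_alpha n_beta outer structure
            for alpha in range(d):
                for beta in range(d):
                    rows.append(np.repeat(tnodes[f] * d + alpha, cn.size))
                    cols.append(np.tile(cn * d + beta, tnodes.shape[1]))
                    vals.append(n[f, alpha] * n[f, beta] * Ns.ravel())
        if not rows:
            return sp.csr_matrix((self.n_vdof, self.n_vdof))
        return sp.coo_matrix(
            (np.concatenate(vals),
             (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.n_vdof, self.n_vdof)).tocsr()

    # -- boundary node sets --------------------------------------------
    def boundary_nodes(self, tag: int) -> np.ndarray:
        """All P2 nodes (vertex + midside) on facets with the given tag."""
        fid = self.mesh.facet_indices(tag)
        facets = self.mesh.facets[fid]
        nodes = set(facets.ravel().tolist())
        for i, j in local_edges(self.dim - 1):
            for a, b in zip(facets[:, i], facets[:, j]):
                nodes.add(self.edge_node(a, b))
        return np.array(sorted(nodes), dtype=np.int64)

    def velocity_gradient(self, cell_ids: np.ndarray, x: np.ndarray,
                          vel: np.ndarray) -> np.ndarray:
        """grad v (n, d, d) at points x inside the given cells.

        ``vel`` is the nodal velocity (n_nodes, dim); entry [n, i, j] is
        d(v_i)/d(x_j).
        """
        lam = self.barycentric(cell_ids, x)
        out = np.empty((x.shape[0], self.dim, self.dim))
        for k, (c, l) in enumerate(zip(cell_ids, lam)):
            G = p2_grad(l[None, :], self.gradlam[c:c + 1])[0, 0]  # (nloc, d)
            vloc = vel[self.cell_nodes[c]]                        # (nloc, d)
            out[k] = vloc.T @ G
        return out


def apply_dirichlet_rows(K: sp.csr_matrix, rhs: np.ndarray,
                         dofs: np.ndarray, values: np.ndarray,
                         cols: np.ndarray | None = None) -> sp.csr_matrix:
    """Replace the given rows with ``x[col] = value`` rows.

    ``cols`` defaults to ``dofs`` (square single-field systems); in block
    systems the constrained unknown's column index may differ from the
    equation's row index.
    """
    if cols is None:
        cols = dofs
    n = K.shape[0]
    keep = np.ones(n)
    keep[dofs] = 0.0
    out = (sp.diags(keep) @ K).tocsr()
    out += sp.coo_matrix((np.ones(len(dofs)), (dofs, cols)), shape=K.shape)
    rhs[dofs] = values
    return out.tocsr()
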