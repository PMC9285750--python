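"""Parametric vessel meshes with tagged boundaries.

A :class:`VesselMesh` is a simplicial mesh (triangles in 2D, tetrahedra in
3D) of a vessel segment whose boundary facets are partitioned into one
inlet, a wall, and one or more outlet groups.  Facet tags follow the fixed
convention ``INLET = 1``, ``WALL = 2`` and ``OUTLET_i = 10 + i`` for the
i-th outlet (i starting at 1, ordered by ascending tag everywhere in the
package).

Two generators are provided:

``make_tube_mesh``
    A straight cylindrical vessel: a channel of half-width ``radius`` in
    2D, or a disk-sectioned cylinder in 3D (structured, no external mesher
    required).

``make_branching_mesh``
    A planar single-inlet, multi-outlet manifold emulating an arch-like
    vessel whose distal boundary carries 2-6 outlets of prescribed radii,
    separated by wall segments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

INLET = 1
WALL = 2
OUTLET_BASE = 10  # outlet i carries tag OUTLET_BASE + i


def outlet_tag(i: int) -> int:
    """Tag of the i-th outlet (1-based)."""
    return OUTLET_BASE + i


@dataclass
class VesselMesh:
    """Tagged simplicial mesh of a vessel segment (CGS units, cm).

    Attributes
    ----------
    vertices : (n_vertices, dim) float array
    cells : (n_cells, dim+1) int array
        Simplex connectivity.
    facets : (n_facets, dim) int array
        Boundary facet connectivity (edges in 2D, triangles in 3D).
    facet_tags : (n_facets,) int array
        One tag per boundary facet (INLET, WALL or an outlet tag).
    facet_cells : (n_facets,) int array
        Index of the cell adjacent to each boundary facet.
    """

    vertices: np.ndarray
    cells: np.ndarray
    facets: np.ndarray
    facet_tags: np.ndarray
    facet_cells: np.ndarray
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    # -- basic geometry -------------------------------------------------
    @property
    def dim(self) -> int:
        return self.vertices.shape[1]

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_cells(self) -> int:
        return self.cells.shape[0]

    def cell_measures(self) -> np.ndarray:
        """Area (2D) or volume (3D) of every cell, strictly positive."""
        X = self.vertices[self.cells]
        M = X[:, 1:, :] - X[:, :1, :]
        det = np.linalg.det(M)
        return np.abs(det) / math.factorial(self.dim)

    def facet_measures(self) -> np.ndarray:
        """Length (2D) or area (3D) of every boundary facet."""
        X = self.vertices[self.facets]
        if self.dim == 2:
            return np.linalg.norm(X[:, 1] - X[:, 0], axis=1)
        a = X[:, 1] - X[:, 0]
        b = X[:, 2] - X[:, 0]
        return 0.5 * np.linalg.norm(np.cross(a, b), axis=1)

    # -- tags -----------------------------------------------------------
    @property
    def outlet_tags(self) -> list[int]:
        tags = sorted(set(self.facet_tags.tolist()))
        return [t for t in tags if t > OUTLET_BASE]

    @property
    def n_outlets(self) -> int:
        return len(self.outlet_tags)

    def facet_indices(self, tag: int) -> np.ndarray:
        idx = np.nonzero(self.facet_tags == tag)[0]
        if idx.size == 0:
            raise KeyError(f"no boundary facet carries tag {tag}")
        return idx

    def boundary_measure(self, tag: int) -> float:
        return float(self.facet_measures()[self.facet_indices(tag)].sum())

    @property
    def inlet_area(self) -> float:
        return self.boundary_measure(INLET)

    @property
    def outlet_areas(self) -> np.ndarray:
        m = self.facet_measures()
        return np.array([m[self.facet_indices(t)].sum() for t in self.outlet_tags])

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        """Check the structural invariants; raise ValueError on failure."""
        if np.any(self.cell_measures() <= 0):
            raise ValueError("mesh contains degenerate cells")
        if self.facets.shape[0] != self.facet_tags.shape[0]:
            raise ValueError("facet/tag count mismatch")
        for need, name in ((INLET, "inlet"), (WALL, "wall")):
            if not np.any(self.facet_tags == need):
                raise ValueError(f"mesh has no {name} facets")
        if self.n_outlets == 0:
            raise ValueError("mesh has no outlet facets")
        # boundary facets extracted from cells must coincide with tagged set
        bfacets, _ = _boundary_facets(self.cells, self.dim)
        if bfacets.shape[0] != self.facets.shape[0]:
            raise ValueError("tags do not partition the boundary")


# ---------------------------------------------------------------------------
# boundary extraction
# ---------------------------------------------------------------------------

def _boundary_facets(cells: np.ndarray, dim: int) -> tuple[np.ndarray, np.ndarray]:
    """Facets of the mesh boundary and their adjacent cell index."""
    nloc = dim + 1
    # each cell face = all vertices except one
    faces = []
    owners = []
    for drop in range(nloc):
        keep = [k for k in range(nloc) if k != drop]
        faces.append(cells[:, keep])
        owners.append(np.arange(cells.shape[0]))
    faces = np.vstack(faces)
    owners = np.concatenate(owners)
    key = np.sort(faces, axis=1)
    _, inverse, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    on_boundary = counts[inverse] == 1
    return faces[on_boundary], owners[on_boundary]


def _facet_centroids(vertices: np.ndarray, facets: np.ndarray) -> np.ndarray:
    return vertices[facets].mean(axis=1)


# ---------------------------------------------------------------------------
# straight tube
# ---------------------------------------------------------------------------

def make_tube_mesh(radius: float, length: float, target_edge_length: float,
                   dim: int = 2) -> VesselMesh:
    """Structured mesh of a straight vessel of given radius and length.

    In 2D the domain is the channel [0, L] x [-r, r]; in 3D a cylinder of
    radius r aligned with z.  The inlet is at the proximal end, the single
    outlet at the distal end.
    """
    if radius <= 0 or length <= 0 or target_edge_length <= 0:
        raise ValueError("radius, length and target_edge_length must be positive")
    if dim == 2:
        return _tube_2d(radius, length, target_edge_length)
    if dim == 3:
        return _tube_3d(radius, length, target_edge_length)
    raise ValueError(f"dim must be 2 or 3, got {dim}")


def _structured_rectangle(x: np.ndarray, y_rows: np.ndarray):
    """Triangulate a transfinite grid: x (nx+1,), y_rows (ny+1, nx+1)."""
    nxp, = x.shape
    nyp = y_rows.shape[0]
    X, _ = np.meshgrid(x, np.arange(nyp))
    verts = np.column_stack([X.ravel(), y_rows.ravel()])

    def vid(i, j):  # column i, row j
        return j * nxp + i

    tris = []
    for j in range(nyp - 1):
        for i in range(nxp - 1):
            a, b = vid(i, j), vid(i + 1, j)
            c, d = vid(i + 1, j + 1), vid(i, j + 1)
            if (i + j) % 2 == 0:
                tris.append((a, b, c)); tris.append((a, c, d))
            else:
                tris.append((a, b, d)); tris.append((b, c, d))
    return verts, np.asarray(tris, dtype=np.int64)


def _tube_2d(r: float, L: float, h: float) -> VesselMesh:
    nx = max(2, round(L / h))
    ny = max(2, round(2 * r / h))
    x = np.linspace(0.0, L, nx + 1)
    yy = np.linspace(-r, r, ny + 1)
    y_rows = np.repeat(yy[:, None], nx + 1, axis=1)
    verts, cells = _structured_rectangle(x, y_rows)
    facets, owners = _boundary_facets(cells, 2)
    cent = _facet_centroids(verts, facets)
    tol = 1e-9 * max(L, r)
    tags = np.full(facets.shape[0], WALL, dtype=np.int64)
    tags[np.abs(cent[:, 0]) < tol] = INLET
    tags[np.abs(cent[:, 0] - L) < tol] = outlet_tag(1)
    return VesselMesh(verts, cells, facets, tags, owners)


def _disk_grid(r: float, n_side: int):
    """Map a square grid to the unit disk (boundary nodes exactly on circle)."""
    u = np.linspace(-1.0, 1.0, n_side + 1)
    U, V = np.meshgrid(u, u)
    X = U * np.sqrt(1.0 - 0.5 * V * V)
    Y = V * np.sqrt(1.0 - 0.5 * U * U)
    pts = np.column_stack([X.ravel(), Y.ravel()]) * r
    nxp = n_side + 1

    def vid(i, j):
        return j * nxp + i

    tris = []
    for j in range(n_side):
        for i in range(n_side):
            a, b = vid(i, j), vid(i + 1, j)
            c, d = vid(i + 1, j + 1), vid(i, j + 1)
            if (i + j) % 2 == 0:
                tris.append((a, b, c)); tris.append((a, c, d))
            else:
                tris.append((a, b, d)); tris.append((b, c, d))
    return pts, np.asarray(tris, dtype=np.int64)


_PRISM_ROTATIONS = [
    (0, 1, 2, 3, 4, 5), (1, 2, 0, 4, 5, 3), (2, 0, 1, 5, 3, 4),
    (3, 5, 4, 0, 2, 1), (4, 3, 5, 1, 0, 2), (5, 4, 3, 2, 1, 0),
]


def _split_prism(p: np.ndarray) -> list[tuple[int, int, int, int]]:
    """Split a prism into 3 tets with globally consistent quad diagonals.

    Classic smallest-vertex rule: rotate the prism so its smallest global
    vertex index sits at local position 0; the two possible diagonal
    patterns are then decided by comparing opposite quad corners.
    """
    k = int(np.argmin(p))
    for rot in _PRISM_ROTATIONS:
        if rot[0] == k:
            q = [p[i] for i in rot]
            break
    if min(q[1], q[5]) < min(q[2], q[4]):
        tets = [(q[0], q[1], q[2], q[5]), (q[0], q[1], q[5], q[4]),
                (q[0], q[4], q[5], q[3])]
    else:
        tets = [(q[0], q[1], q[2], q[4]), (q[0], q[4], q[2], q[5]),
                (q[0], q[4], q[5], q[3])]
    return tets


def _tube_3d(r: float, L: float, h: float) -> VesselMesh:
    n_side = max(2, round(2 * r / h))
    nz = max(2, round(L / h))
    disk, tris = _disk_grid(r, n_side)
    n2 = disk.shape[0]
    z = np.linspace(0.0, L, nz + 1)
    verts = np.empty(((nz + 1) * n2, 3))
    for k, zk in enumerate(z):
        verts[k * n2:(k + 1) * n2, :2] = disk
        verts[k * n2:(k + 1) * n2, 2] = zk
    tets = []
    for k in range(nz):
        lo, hi = k * n2, (k + 1) * n2
        for t in tris:
            prism = np.array([lo + t[0], lo + t[1], lo + t[2],
                              hi + t[0], hi + t[1], hi + t[2]])
            tets.extend(_split_prism(prism))
    cells = np.asarray(tets, dtype=np.int64)
    facets, owners = _boundary_facets(cells, 3)
    cent = _facet_centroids(verts, facets)
    tol = 1e-9 * max(L, r)
    tags = np.full(facets.shape[0], WALL, dtype=np.int64)
    tags[np.abs(cent[:, 2]) < tol] = INLET
    tags[np.abs(cent[:, 2] - L) < tol] = outlet_tag(1)
    return VesselMesh(verts, cells, facets, tags, owners)


# ---------------------------------------------------------------------------
# branching manifold (2D)
# ---------------------------------------------------------------------------

def make_branching_mesh(outlet_radii, trunk_radius: float,
                        target_edge_length: float, length: float | None = None,
                        gap_fraction: float = 0.6) -> VesselMesh:
    """Planar single-inlet manifold whose distal edge carries several outlets.

    The domain is a transfinite quadrilateral: the proximal (inlet) edge has
    width ``2*trunk_radius``; the distal edge is partitioned into outlet
    segments of width ``2*r_i`` separated by wall gaps.  Emulates, at desk
    scale, an arch-like vessel feeding 2-6 branches.

    Parameters
    ----------
    outlet_radii : sequence of float, length 2-6
        Radii of the outlet branches, cm; outlet i (tag ``10+i``) has
        cross-section measure ``2*r_i``.
    trunk_radius : float
        Half-width of the inlet, cm.
    target_edge_length : float
        Requested mesh edge length, cm.
    length : float, optional
        Proximal-to-distal extent; default ``4*trunk_radius``.
    gap_fraction : float
        Wall gap between adjacent outlets, as a fraction of the smallest
        outlet radius.
    """
    radii = np.asarray(outlet_radii, dtype=float)
    if radii.ndim != 1 or not (2 <= radii.size <= 6):
        raise ValueError("2 to 6 outlet radii are required")
    if np.any(radii <= 0) or trunk_radius <= 0 or target_edge_length <= 0:
        raise ValueError("radii and mesh size must be positive")
    h = target_edge_length
    L = 4.0 * trunk_radius if length is None else float(length)
    if L <= 0:
        raise ValueError("length must be positive")
    gap = gap_fraction * radii.min()
    widths = 2.0 * radii
    H = widths.sum() + gap * (radii.size - 1)
    if H / (2.0 * trunk_radius) > 25 or L < h:
        raise ValueError("degenerate manifold geometry rejected")

    # distal-edge partition: alternating outlet / gap segments
    segments = []  # (y_start, y_end, tag)
    y = 0.0
    for i, w in enumerate(widths, start=1):
        segments.append((y, y + w, outlet_tag(i)))
        y += w
        if i < radii.size:
            segments.append((y, y + gap, WALL))
            y += gap

    # fractional rows: include every segment endpoint exactly
    fs = [0.0]
    for y0, y1, _ in segments:
        n = max(1, round((y1 - y0) / h))
        fs.extend(np.linspace(y0, y1, n + 1)[1:] / H)
    fs = np.array(fs)
    fs[-1] = 1.0

    nx = max(2, round(L / h))
    s = np.linspace(0.0, 1.0, nx + 1)
    c = 0.5 * H
    y_left = (c - trunk_radius) + fs * (2.0 * trunk_radius)
    y_right = fs * H
    # transfinite blend between inlet edge and distal edge
    y_rows = (1.0 - s)[None, :] * y_left[:, None] + s[None, :] * y_right[:, None]
    verts, cells = _structured_rectangle(s * L, y_rows)

    facets, owners = _boundary_facets(cells, 2)
    cent = _facet_centroids(verts, facets)
    tol = 1e-9 * max(L, H)
    tags = np.full(facets.shape[0], WALL, dtype=np.int64)
    tags[np.abs(cent[:, 0]) < tol] = INLET
    distal = np.abs(cent[:, 0] - L) < tol
    for fidx in np.nonzero(distal)[0]:
        ym = cent[fidx, 1]
        for y0, y1, tag in segments:
            if y0 - tol <= ym <= y1 + tol:
                tags[fidx] = tag
                break
    mesh = VesselMesh(verts, cells, facets, tags, owners)
    mesh.validate()
    return mesh
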