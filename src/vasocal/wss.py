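"""Wall shear stress postprocessing: WSS vectors, TAWSS, OSI, difference maps.

The wall shear stress is the tangential component of the viscous traction
nu (grad v + grad v^T) n evaluated on the wall; given a time series of WSS
vectors over one cardiac cycle the standard haemodynamic indicators are

    TAWSS = (1/T) int_0^T |tau(t)| dt,
    OSI   = 1/2 (1 - |int_0^T tau dt| / int_0^T |tau| dt)  in [0, 0.5],

and calibration methods are compared through pointwise relative-difference
maps normalised by the global maximum of a reference field.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import meshing
from .fem import TaylorHoodSpace
from .meshing import VesselMesh
from .stokes import StokesSolution


@dataclass
class WallFieldSeries:
    """WSS vectors sampled at wall locations over one cardiac cycle.

    times : (nt,) s, strictly increasing, spanning one period
    wss_vectors : (nt, n_locations, dim) dyn/cm^2
    locations : (n_locations, dim) wall facet centroids, cm (optional aid)
    """

    times: np.ndarray
    wss_vectors: np.ndarray
    locations: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.wss_vectors = np.asarray(self.wss_vectors, dtype=float)
        if self.times.ndim != 1 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.wss_vectors.shape[0] != self.times.size:
            raise ValueError("one vector field per time sample is required")
        if self.wss_vectors.ndim != 3:
            raise ValueError("wss_vectors must be (nt, nloc, dim)")

    @property
    def period(self) -> float:
        return float(self.times[-1] - self.times[0])


def wss_from_velocity(sol: StokesSolution, mesh: VesselMesh,
                      viscosity: float) -> tuple[np.ndarray, np.ndarray]:
    """Tangential viscous traction at wall facet centroids.

    Returns ``(tau, centroids)`` with tau of shape (n_wall_facets, dim):
    tau = sigma_v n - (n . sigma_v n) n, sigma_v = nu (grad v + grad v^T).
    """
    space = TaylorHoodSpace(mesh)
    ids = mesh.facet_indices(meshing.WALL)
    _, n, _, _, _, cells = space.facet_geometry(ids)
    centroids = mesh.vertices[mesh.facets[ids]].mean(axis=1)
    gradv = space.velocity_gradient(cells, centroids, sol.velocity)
    sym = viscosity * (gradv + np.transpose(gradv, (0, 2, 1)))
    traction = np.einsum('fij,fj->fi', sym, n)
    normal_part = np.einsum('fi,fi->f', traction, n)
    tau = traction - normal_part[:, None] * n
    return tau, centroids


def tawss(series: WallFieldSeries) -> np.ndarray:
    """Time-averaged WSS magnitude per wall location, dyn/cm^2."""
    if series.times.size < 2:
        raise ValueError("TAWSS needs at least two time samples")
    mag = np.linalg.norm(series.wss_vectors, axis=2)
    return np.trapezoid(mag, series.times, axis=0) / series.period


def osi(series: WallFieldSeries) -> np.ma.MaskedArray:
    """Oscillatory shear index per wall location, masked where undefined.

    OSI = 0.5 (1 - |int tau dt| / int |tau| dt), clipped to [0, 0.5];
    locations where the time-integrated magnitude vanishes are masked.
    """
    if series.times.size < 2:
        raise ValueError("OSI needs at least two time samples")
    mean_vec = np.trapezoid(series.wss_vectors, series.times, axis=0)
    mag_int = np.trapezoid(np.linalg.norm(series.wss_vectors, axis=2),
                           series.times, axis=0)
    undefined = mag_int <= 0.0
    if undefined.all():
        warnings.warn("all-zero WSS series: OSI undefined everywhere",
                      RuntimeWarning)
    safe = np.where(undefined, 1.0, mag_int)
    vals = 0.5 * (1.0 - np.linalg.norm(mean_vec, axis=1) / safe)
    return np.ma.MaskedArray(np.clip(vals, 0.0, 0.5), mask=undefined)


def relative_difference_map(field: np.ndarray,
                            reference: np.ndarray) -> np.ndarray:
    """Pointwise |field - reference| / max(reference).

    The denominator is the global maximum of the reference field (the map
    used to compare calibration methods against the optimal-control one).
    """
    field = np.asarray(field, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if field.shape != reference.shape:
        raise ValueError("fields must share the wall index set")
    ref_max = reference.max()
    if not ref_max > 0:
        raise ValueError("reference field has non-positive maximum")
    return np.abs(field - reference) / ref_max
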