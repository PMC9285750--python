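"""Synthetic measurement generation with controlled mass-conservation violation.

Ground-truth data are produced by a steady Stokes forward solve with known
outlet resistances: the section pressure becomes the pressure target p_d
and the outlet fluxes become the measured flows.  A prescribed fraction of
the inlet flow can then be removed uniformly from the outlet measurements,
emulating the net-flow inconsistency of 4D-Flow MRI data (the inlet flow
is kept exact): after rescaling, Q_in - sum(Q_i) = violation * Q_in.
"""

from __future__ import annotations

import numpy as np

from .measurements import MeasurementSet
from .meshing import VesselMesh
from .stokes import DEFAULT_VISCOSITY, ResistanceSet, StokesOperators, \
    section_pressure
from . import meshing

MAX_VIOLATION = 0.15  # above ~15% net flow 4D-Flow data are deemed unusable


def make_synthetic_case(mesh: VesselMesh, R_true: ResistanceSet, Q_in: float,
                        violation_fraction: float = 0.0, seed: int = 0,
                        viscosity: float = DEFAULT_VISCOSITY,
                        pressure_section: int = meshing.INLET,
                        jitter: float = 0.0) -> MeasurementSet:
    """Forward-solve with known resistances and package the measurements.

    Parameters
    ----------
    violation_fraction : float in [0, 0.15]
        Fraction of the inlet flow missing from the outlet measurements.
    seed : int
        Seed for the optional multiplicative per-outlet jitter (only used
        when ``jitter`` > 0; the default is exact, noise-free data).
    jitter : float
        Relative standard deviation of the per-outlet noise, default 0.
    """
    if not 0.0 <= violation_fraction <= MAX_VIOLATION:
        raise ValueError(
            f"violation_fraction must lie in [0, {MAX_VIOLATION}]")
    ops = StokesOperators(mesh, viscosity)
    sol = ops.solve(R_true, Q_in)
    p_d = section_pressure(sol, mesh, pressure_section)
    Q_out = sol.outlet_flows.copy()
    if jitter > 0.0:
        rng = np.random.default_rng(seed)
        Q_out = Q_out * (1.0 + jitter * rng.standard_normal(len(Q_out)))
    # uniform rescaling: sum(Q_out) = (1 - violation) * Q_in exactly
    Q_out *= (1.0 - violation_fraction) * Q_in / Q_out.sum()
    return MeasurementSet(p_d=p_d, Q_in=Q_in, Q_out=Q_out,
                          pressure_section=pressure_section)
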