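"""0D (lumped-parameter) calibrators and the resistive network forward model.

These are the two standard outlet-resistance calibrators the optimal-control
estimator is compared against, plus the supporting pieces:

* ``mean_arterial_pressure`` -- MAP = (P_sys + 2 P_diast) / 3;
* ``murray_resistances`` -- split the total resistance p_d/Q0 by outlet
  area (Murray's law with exponent n, conventionally 2 for the arch);
* ``ohm_resistances`` -- R_i = p_d / Q_i per outlet;
* ``ohm_opt_resistances`` -- minimise the 0D analogue of the assimilation
  functional with a derivative-free simplex search;
* ``network_forward`` -- flows/pressure of the pure-resistor junction;
* ``split_rcr`` -- proximal/distal resistance and compliance splitting for
  three-element Windkessel outlets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .measurements import MeasurementSet
from .stokes import ResistanceSet


@dataclass
class RCRBranch:
    """One three-element Windkessel outlet (CGS units)."""

    R_proximal: float   # dyn.s/cm^5
    C: float            # cm^5/dyn
    R_distal: float     # dyn.s/cm^5
    P_distal: float = 0.0  # dyn/cm^2

    def __post_init__(self):
        if self.R_proximal <= 0 or self.R_distal <= 0:
            raise ValueError("resistances must be positive")
        if self.C <= 0:
            raise ValueError("compliance must be positive")
        if self.P_distal < 0:
            raise ValueError("distal pressure must be nonnegative")

    @property
    def R_total(self) -> float:
        return self.R_proximal + self.R_distal


def mean_arterial_pressure(P_sys: float, P_diast: float) -> float:
    """MAP = (P_sys + 2*P_diast)/3, same unit as the inputs."""
    if P_sys < P_diast:
        raise ValueError("systolic pressure below diastolic")
    if P_sys <= 0 or P_diast < 0:
        raise ValueError("pressures must be positive")
    return (P_sys + 2.0 * P_diast) / 3.0


def murray_resistances(outlet_areas, p_d: float, Q0: float,
                       exponent_n: float = 2.0) -> ResistanceSet:
    """Split R_tot = p_d/Q0 over the outlets by Murray's law.

    With the conventional exponent n = 2 the flow through each outlet is
    proportional to its cross-sectional area Gamma_i, so
    R_i = (sum_j s_j / s_i) * R_tot with s_i = Gamma_i; for general n,
    s_i = Gamma_i^(n/2) (i.e. r_i^n for circular outlets).  The parallel
    combination of the returned resistances equals R_tot identically.
    """
    areas = np.atleast_1d(np.asarray(outlet_areas, dtype=float))
    if np.any(areas <= 0):
        raise ValueError("outlet areas must be positive")
    if p_d <= 0 or Q0 <= 0:
        raise ValueError("p_d and Q0 must be positive")
    R_tot = p_d / Q0
    s = areas ** (exponent_n / 2.0)
    return ResistanceSet(R_tot * s.sum() / s)


def ohm_resistances(p_d: float, Q_out) -> ResistanceSet:
    """Ohm's law per outlet: R_i = p_d / Q_i."""
    Q = np.atleast_1d(np.asarray(Q_out, dtype=float))
    if np.any(Q <= 0):
        raise ValueError("outlet flows must be positive")
    if p_d <= 0:
        raise ValueError("p_d must be positive")
    return ResistanceSet(p_d / Q)


def ohm_cost(R, p_d: float, Q0: float, Q_out, alpha_p: float = 1.0,
             alpha_out=1.0) -> float:
    """0D analogue of the assimilation functional.

    J_ohm = alpha_p (R_tot Q0 - p_d)^2 / p_d^2
          + sum_i alpha_i (p_d/R_i - Q_i)^2 / Q_i^2,
    with R_tot the parallel combination of the R_i.
    """
    R = np.asarray(R, dtype=float)
    Q = np.atleast_1d(np.asarray(Q_out, dtype=float))
    a = np.broadcast_to(np.asarray(alpha_out, dtype=float), Q.shape)
    R_tot = 1.0 / np.sum(1.0 / R)
    jp = alpha_p * (R_tot * Q0 - p_d) ** 2 / p_d ** 2
    jq = np.sum(a * (p_d / R - Q) ** 2 / Q ** 2)
    return float(jp + jq)


def ohm_opt_resistances(p_d: float, Q0: float, Q_out, alpha_p: float = 1.0,
                        alpha_out=1.0) -> ResistanceSet:
    """Minimise ``ohm_cost`` with Nelder-Mead from the Ohm's-law start.

    The simplex search never returns a point worse than its start, so the
    result is guaranteed to dominate plain Ohm's law in the 0D objective.
    """
    start = ohm_resistances(p_d, Q_out).R
    if alpha_p == 0.0:
        return ResistanceSet(start)  # flow terms alone: exact zero at Ohm
    res = minimize(
        ohm_cost, start, args=(p_d, Q0, Q_out, alpha_p, alpha_out),
        method="Nelder-Mead",
        options={"xatol": 1e-10 * start.max(), "fatol": 1e-14,
                 "maxfev": 10000, "adaptive": True})
    if np.any(res.x <= 0):
        raise RuntimeError(
            f"simplex search left the feasible region (final simplex size "
            f"{res.get('final_simplex', (None,))[0]})")
    return ResistanceSet(res.x)


def network_forward(R: ResistanceSet, Q0: float):
    """Flows and junction pressure of the pure-resistor junction.

    Conductance-weighted split: Q_i = Q0 (1/R_i)/sum_j(1/R_j) and
    p = Q0 / sum_j (1/R_j); mass is conserved exactly.

    Returns
    -------
    flows : (n,) ndarray, cm^3/s
    pressure : float, dyn/cm^2
    """
    if Q0 <= 0:
        raise ValueError("Q0 must be positive")
    if np.any(R.R <= 0):
        raise ValueError("network resistances must be strictly positive")
    g = 1.0 / R.R
    flows = Q0 * g / g.sum()
    pressure = Q0 / g.sum()
    return flows, float(pressure)


def split_rcr(R_total: ResistanceSet, C_total: float, outlet_areas,
              proximal_fraction: float = 0.09,
              P_distal: float = 0.0) -> list[RCRBranch]:
    """Split total resistances and compliance into Windkessel branches.

    R_p,i = f R_i and R_d,i = (1-f) R_i with f = 0.09 by default; the total
    compliance is split proportionally to outlet area; the distal pressure
    defaults to zero.
    """
    if not 0.0 < proximal_fraction < 1.0:
        raise ValueError("proximal_fraction must lie in (0, 1)")
    if C_total <= 0:
        raise ValueError("C_total must be positive")
    areas = np.atleast_1d(np.asarray(outlet_areas, dtype=float))
    if np.any(areas <= 0):
        raise ValueError("outlet areas must be positive")
    if len(areas) != len(R_total):
        raise ValueError("one area per resistance is required")
    C = C_total * areas / areas.sum()
    return [RCRBranch(proximal_fraction * R, Ci, (1.0 - proximal_fraction) * R,
                      P_distal)
            for R, Ci in zip(R_total.R, C)]


def net_flow_report(meas: MeasurementSet):
    """Net flow Q_in - sum(Q_i) and its percentage of the inlet flow."""
    net = meas.net_flow
    return net, 100.0 * net / meas.Q_in
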