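"""Unsteady 0D surrogate: three-element Windkessel branches at a junction.

A prescribed periodic inlet flow waveform Q_in(t) feeds a common junction
at pressure P(t); each branch i is a three-element Windkessel (proximal
resistance R_p, compliance C, distal resistance R_d, distal pressure
P_dist).  With capacitor pressure pi_i the governing system is

    Q_i = (P - pi_i) / R_p,i                 (branch flow)
    C_i dpi_i/dt = Q_i - (pi_i - P_dist,i)/R_d,i
    sum_i Q_i = Q_in(t)                      (junction mass balance)

i.e. a linear DAE: the junction condition determines P(t) given the
capacitor states; the states are advanced with implicit (backward) Euler.
The 3D domain between inlet and outlets is approximated as a
zero-resistance junction (its viscous drop is much smaller than the
peripheral resistances in the arterial cases of interest).

Averaging the capacitor ODE over one period kills the dpi/dt term, so the
last-cycle mean flows of a periodically converged simulation match the
pure-resistor network split with totals R_p + R_d -- the property used to
validate estimated resistances in a pulsatile setting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import lu_factor, lu_solve

from .lumped import RCRBranch


@dataclass
class FlowWaveform:
    """Periodic inlet flow waveform over one cardiac cycle.

    times : (n,) strictly increasing, s, spanning [0, T]
    values : (n,) cm^3/s, with values[0] == values[-1] (periodic closure)
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.size < 3:
            raise ValueError("waveform needs at least 3 samples")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.times[0] != 0.0:
            raise ValueError("waveform must start at t = 0")
        scale = max(abs(self.values).max(), 1e-30)
        if abs(self.values[0] - self.values[-1]) > 1e-9 * scale:
            raise ValueError("waveform is not periodic "
                             "(first and last values differ)")

    @property
    def period(self) -> float:
        return float(self.times[-1])

    @property
    def mean(self) -> float:
        """Cycle-mean flow (trapezoidal rule), cm^3/s."""
        return float(np.trapezoid(self.values, self.times) / self.period)

    def __call__(self, t) -> np.ndarray:
        """Periodic linear interpolation."""
        tau = np.mod(t, self.period)
        return np.interp(tau, self.times, self.values)


def physiological_waveform(mean_flow: float, period: float = 0.8,
                           systole_fraction: float = 0.35,
                           n_samples: int = 201) -> FlowWaveform:
    """Synthetic aortic-like inlet waveform with the requested cycle mean.

    A half-sine systolic ejection over ``systole_fraction`` of the cycle
    and a small constant diastolic offset; stands in for patient inlet
    waveforms, which are not distributed.
    """
    if mean_flow <= 0 or period <= 0:
        raise ValueError("mean_flow and period must be positive")
    t = np.linspace(0.0, period, n_samples)
    ts = systole_fraction * period
    base = 0.1 * mean_flow
    wave = np.where(t < ts, np.sin(np.pi * t / ts) ** 2, 0.0)
    raw = base + wave
    m = np.trapezoid(raw, t) / period
    # scale the pulsatile part so the trapezoidal mean is exact
    scale = (mean_flow - base) / (m - base)
    values = base + scale * wave
    values[-1] = values[0]
    return FlowWaveform(t, values)


@dataclass
class RCRNetworkSeries:
    """Time series of a junction-coupled Windkessel simulation."""

    times: np.ndarray               # (nt,)
    junction_pressure: np.ndarray   # (nt,) dyn/cm^2
    branch_flows: np.ndarray        # (nt, nb) cm^3/s
    branch_pressures: np.ndarray    # (nt, nb) capacitor pressures, dyn/cm^2
    period: float


def _periodic_capacitor_state(waveform: FlowWaveform, Rp, Rd, C, Pd,
                              dt: float) -> np.ndarray:
    """Capacitor pressures at t=0 of the periodic regime.

    The junction-coupled RCR network is linear and time-invariant, so its
    periodic response to the periodic inflow follows harmonic by harmonic:
    each branch sees the inflow through the junction impedance split, with
    the capacitor||R_d impedance Z_d = 1/(i w C + 1/R_d).
    """
    T = waveform.period
    n = max(int(round(T / dt)), 16)
    t = np.arange(n) * (T / n)
    qhat = np.fft.rfft(waveform(t)) / n
    w = 2.0 * np.pi * np.arange(qhat.size) / T
    # DC: junction balance sum_i (P - Pd_i)/(Rp_i+Rd_i) = mean inflow
    g = 1.0 / (Rp + Rd)
    P0 = (qhat[0].real + np.sum(g * Pd)) / np.sum(g)
    q0 = (P0 - Pd) * g
    pi0 = Pd + Rd * q0
    # harmonics
    pi_t0 = pi0.astype(complex)
    for k in range(1, qhat.size):
        Zd = 1.0 / (1j * w[k] * C + 1.0 / Rd)
        Yb = 1.0 / (Rp + Zd)
        Pk = qhat[k] / np.sum(Yb)
        Qk = Pk * Yb
        pik = Qk * Zd
        # rfft one-sided: double all but DC (and Nyquist when n even)
        factor = 1.0 if (n % 2 == 0 and k == qhat.size - 1) else 2.0
        pi_t0 += factor * pik            # e^{i w 0} = 1
    return pi_t0.real


def simulate_rcr_network(waveform: FlowWaveform, branches: list[RCRBranch],
                         n_cycles: int = 5, dt: float | None = None,
                         initial_capacitor_pressure=None) -> RCRNetworkSeries:
    """Integrate the junction-coupled Windkessel DAE over n cardiac cycles.

    Backward Euler on the capacitor states with the junction pressure
    solved simultaneously (one small linear system per step, constant
    matrix, factorised once).  dt defaults to T/1000 and must satisfy
    dt <= T/200.  By default the capacitor states start on the exact
    periodic orbit of the linear network; pass
    ``initial_capacitor_pressure`` (one value per branch, dyn/cm^2) to
    start elsewhere and observe the transient.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    T = waveform.period
    if dt is None:
        dt = T / 1000.0
    if dt > T / 200.0:
        raise ValueError("dt too coarse: need dt <= T/200")
    nb = len(branches)
    if nb == 0:
        raise ValueError("at least one branch is required")
    Rp = np.array([b.R_proximal for b in branches])
    Rd = np.array([b.R_distal for b in branches])
    C = np.array([b.C for b in branches])
    Pd = np.array([b.P_distal for b in branches])

    nt = int(round(n_cycles * T / dt)) + 1
    times = np.arange(nt) * dt
    Qin = waveform(times)

    # unknowns per step: [pi_1..pi_nb, P]
    A = np.zeros((nb + 1, nb + 1))
    for i in range(nb):
        A[i, i] = C[i] / dt + 1.0 / Rd[i] + 1.0 / Rp[i]
        A[i, nb] = -1.0 / Rp[i]
        A[nb, i] = -1.0 / Rp[i]
    A[nb, nb] = np.sum(1.0 / Rp)
    lu = lu_factor(A)

    if initial_capacitor_pressure is not None:
        pi = np.asarray(initial_capacitor_pressure, dtype=float).copy()
        if pi.shape != (nb,):
            raise ValueError("one initial capacitor pressure per branch")
    else:
        # start from the exact periodic orbit of the (linear) network,
        # computed harmonic-by-harmonic, so the slow capacitor transients
        # (tau = R_d C, up to seconds) are gone within the simulated cycles
        pi = _periodic_capacitor_state(waveform, Rp, Rd, C, Pd, dt)

    P_series = np.empty(nt)
    pi_series = np.empty((nt, nb))
    Q_series = np.empty((nt, nb))
    P0 = float((Qin[0] + np.sum(pi / Rp)) / np.sum(1.0 / Rp))
    P_series[0] = P0
    pi_series[0] = pi
    Q_series[0] = (P0 - pi) / Rp
    rhs = np.empty(nb + 1)
    for n in range(1, nt):
        rhs[:nb] = C / dt * pi + Pd / Rd
        rhs[nb] = Qin[n]
        x = lu_solve(lu, rhs)
        pi = x[:nb]
        P = x[nb]
        pi_series[n] = pi
        P_series[n] = P
        Q_series[n] = (P - pi) / Rp
    return RCRNetworkSeries(times, P_series, Q_series,
                            pi_series, T)


def cycle_stats(series: RCRNetworkSeries, period: float | None = None):
    """Trapezoidal means over exactly the final cardiac cycle.

    Returns (mean branch flows (nb,), mean junction pressure).
    """
    T = series.period if period is None else float(period)
    t_end = series.times[-1]
    mask = series.times >= t_end - T - 1e-12
    t = series.times[mask]
    if t[-1] - t[0] < T * (1.0 - 1e-9):
        raise ValueError("series shorter than one period")
    flows = np.trapezoid(series.branch_flows[mask], t, axis=0) / (t[-1] - t[0])
    pressure = np.trapezoid(series.junction_pressure[mask], t) / (t[-1] - t[0])
    return flows, float(pressure)
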