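"""NHS myofilament model: Ca transient -> active tension.

Five states: Ca bound to troponin C (uM), the tropomyosin/available
actin-site variable z, and three fading-memory crossbridge terms
Q1..Q3 driven by the stretch rate.  Tension is algebraic in the state.
Under the isometric protocol (stretch 1, stretch rate 0) the Q terms
receive no input and stay identically zero.

Coupling to the myocyte model is one-way: the cytosolic Ca transient
drives troponin binding, but bound troponin is not fed back into the
myocyte Ca balance (the electrophysiology model carries its own troponin
buffer).  Within the myofilament model itself, tension feeds back on the
troponin unbinding rate as the model prescribes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from . import _kernels as K
from .parameters import NHSParameters

N_NHS_STATES = 5
NHS_STATE_NAMES = ["Ca_TRPN", "z_tm", "Q1", "Q2", "Q3"]


@dataclass(frozen=True)
class MechanicalInput:
    """Fiber stretch (dimensionless) and stretch rate (1/s)."""

    lam: float = 1.0
    dlam_dt: float = 0.0

    def __post_init__(self):
        if not np.isfinite(self.lam) or self.lam <= 0.0:
            raise ValueError("fiber stretch lam must be positive")


ISOMETRIC = MechanicalInput(1.0, 0.0)


def resting_state() -> np.ndarray:
    """Unbound, fully relaxed myofilament state (tension exactly 0 kPa)."""
    return np.zeros(N_NHS_STATES)


def nhs_derivatives(t: float, nhs_state: np.ndarray, ca_i: float,
                    mech: MechanicalInput = ISOMETRIC,
                    params: NHSParameters | None = None) -> np.ndarray:
    """d/dt (per ms) of the myofilament state for cytosolic Ca ``ca_i`` (uM)."""
    if ca_i < 0:
        raise ValueError("ca_i must be non-negative")
    p = params or NHSParameters()
    y = np.asarray(nhs_state, dtype=float)
    if y.shape != (N_NHS_STATES,):
        raise ValueError(f"expected {N_NHS_STATES} myofilament states")
    return K.nhs_derivs(y, p.to_array(), float(ca_i), mech.lam, mech.dlam_dt)


def active_tension(nhs_state: np.ndarray,
                   mech: MechanicalInput = ISOMETRIC,
                   params: NHSParameters | None = None) -> float:
    """Active tension T (kPa) generated by the myofilament state."""
    p = params or NHSParameters()
    y = np.asarray(nhs_state, dtype=float)
    if y.shape != (N_NHS_STATES,):
        raise ValueError(f"expected {N_NHS_STATES} myofilament states")
    return float(K.nhs_tension(y, p.to_array(), mech.lam, mech.dlam_dt))


def run_isometric(ca_times_ms: np.ndarray, ca_trace_uM: np.ndarray,
                  lam: float = 1.0,
                  params: NHSParameters | None = None,
                  y0: np.ndarray | None = None,
                  rtol: float = 1e-8, atol: float = 1e-10) -> np.ndarray:
    """Drive the myofilament model with a sampled Ca transient.

    ``ca_trace_uM`` is linearly interpolated between samples (the trace is
    assumed densely sampled relative to myofilament kinetics).  Returns the
    tension series (kPa) on the same time grid.
    """
    t = np.asarray(ca_times_ms, dtype=float)
    ca = np.asarray(ca_trace_uM, dtype=float)
    if t.size == 0:
        raise ValueError("empty Ca trace")
    if t.shape != ca.shape:
        raise ValueError("time and Ca arrays must have the same shape")
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("Ca trace time grid must be strictly increasing")
    if np.any(ca < 0):
        raise ValueError("Ca trace must be non-negative")
    mech = MechanicalInput(lam, 0.0)
    p = params or NHSParameters()
    p_arr = p.to_array()
    y0 = resting_state() if y0 is None else np.asarray(y0, dtype=float)

    def rhs(tt, yy):
        ca_now = np.interp(tt, t, ca)
        return K.nhs_derivs(yy, p_arr, ca_now, mech.lam, mech.dlam_dt)

    if t.size == 1:
        states = y0[None, :]
    else:
        sol = solve_ivp(rhs, (t[0], t[-1]), y0, method="LSODA",
                        t_eval=t, rtol=rtol, atol=atol)
        if not sol.success:  # pragma: no cover
            raise RuntimeError(f"myofilament integration failed: {sol.message}")
        states = sol.y.T
    return np.array([K.nhs_tension(s, p_arr, mech.lam, mech.dlam_dt)
                     for s in states])
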