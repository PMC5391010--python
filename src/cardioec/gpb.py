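"""Modified GPB human ventricular myocyte model: Python-facing API.

The model couples membrane electrophysiology (fast/late Na, L-type Ca,
delayed-rectifier / transient-outward / inward-rectifier K, Cl, pump and
exchanger currents) to four-compartment Ca handling (junctional cleft,
subsarcolemmal space, bulk cytosol, SR) with explicit buffering.  Heart
failure remodelling enters through the 11 impact factors of
:mod:`cardioec.disease`.
"""

from __future__ import annotations

import collections
import math

import numpy as np

from . import _kernels as K
from . import registry as R
from .disease import ImpactFactors
from .parameters import GPBParameters

CurrentSet = collections.namedtuple("CurrentSet", K.CURRENT_NAMES)

CURRENT_NAMES = K.CURRENT_NAMES


def nernst(z: int, conc_out: float, conc_in: float,
           params: GPBParameters | None = None) -> float:
    """Nernst reversal potential (mV): E = RT/(zF) ln([X]_o/[X]_i)."""
    p = params or GPBParameters()
    if conc_out <= 0 or conc_in <= 0:
        raise ValueError("Nernst concentrations must be strictly positive")
    return (p.R * p.Temp) / (z * p.Frdy) * math.log(conc_out / conc_in)


def late_na_current(Vm: float, mL: float, hL: float,
                    params: GPBParameters,
                    nernst_junc: float, nernst_sl: float,
                    f_NaL: float = 1.0):
    """Late Na current split into junctional/subsarcolemmal parts (uA/uF).

    I_NaL_junc = F_junc * g_NaL * mL^3 * hL * (Vm - E_junc), likewise for
    the subsarcolemmal part with F_sl and E_sl; the total is their sum and
    the impact factor ``f_NaL`` scales g_NaL.
    """
    if not np.isfinite(Vm):
        raise ValueError("Vm must be finite")
    if not (0.0 <= mL <= 1.0 and 0.0 <= hL <= 1.0):
        raise ValueError("gates mL, hL must lie in [0, 1]")
    g = params.GNaL * f_NaL * mL**3 * hL
    i_junc = params.Fjunc * g * (Vm - nernst_junc)
    i_sl = params.Fsl * g * (Vm - nernst_sl)
    return i_junc, i_sl, i_junc + i_sl


def late_na_gate_rates(Vm: float, params: GPBParameters,
                       f_hl: float = 1.0):
    """(alpha_mL [1/ms], beta_mL [1/ms], hL_inf, tau_hL_eff [ms]).

    alpha_mL = 0.32 (Vm+47.13) / (1 - e^{-0.1 (Vm+47.13)}) with the
    analytic limit 0.32/0.1 at the removable singularity Vm = -47.13 mV;
    hL_inf = 1/(1 + e^{(Vm+91)/6.1}); the effective inactivation time
    constant is f_hl * tau_hL.
    """
    if not np.isfinite(Vm):
        raise ValueError("Vm must be finite")
    return K.late_na_rates(Vm, params.tau_hL, f_hl)


def validate_state(y: np.ndarray, params: GPBParameters | None = None) -> None:
    """Check state invariants, naming the offending component on failure."""
    y = np.asarray(y, dtype=float)
    if y.shape != (R.N_STATES,):
        raise ValueError(
            f"state vector must have length {R.N_STATES}, got {y.shape}")
    if not np.all(np.isfinite(y)):
        bad = R.STATE_NAMES[int(np.where(~np.isfinite(y))[0][0])]
        raise ValueError(f"state component {bad} is not finite")
    lo, hi = R.state_bounds()
    below = y < lo
    if np.any(below):
        bad = R.STATE_NAMES[int(np.where(below)[0][0])]
        raise ValueError(f"state component {bad} below its lower bound")
    above = y > hi
    if np.any(above):
        bad = R.STATE_NAMES[int(np.where(above)[0][0])]
        raise ValueError(f"state component {bad} above its upper bound")
    for name in ("Naj", "Nasl", "Nai", "Ki", "Caj", "Casl", "Cai", "Ca_sr"):
        if y[R.STATE_INDEX[name]] <= 0.0:
            raise ValueError(
                f"ion concentration {name} must be strictly positive")


def compute_currents(state: np.ndarray, params: GPBParameters,
                     factors: ImpactFactors) -> CurrentSet:
    """Evaluate all ionic currents (uA/uF) and SR fluxes (mM/ms)."""
    validate_state(state, params)
    arr = K.compute_currents_arr(np.asarray(state, dtype=float),
                                 params.to_array(), factors.to_array())
    return CurrentSet(*arr)


def derivatives(t: float, state: np.ndarray, params: GPBParameters,
                factors: ImpactFactors, stim: float = 0.0) -> np.ndarray:
    """d(state)/dt of the electrophysiology block at time ``t``.

    ``stim`` is the applied stimulus current in uA/uF (positive
    depolarizing, i.e. an inward membrane current of equal magnitude).
    The NHS entries of the returned vector are zero; use
    :func:`cardioec.simulation.coupled_derivatives` for the full system.
    """
    validate_state(state, params)
    return K.gpb_derivs(np.asarray(state, dtype=float), params.to_array(),
                        factors.to_array(), stim)


def total_calcium(y: np.ndarray, params: GPBParameters) -> float:
    """Volume-weighted total Ca content (mol, scaled by 1e3) of the cell.

    Sums free Ca and all Ca-bound buffer states over the junctional,
    subsarcolemmal, cytosolic and SR compartments; conserved whenever
    the sarcolemmal Ca pathways (I_CaL Ca flux, I_Cabk, I_pCa, I_ncx)
    are zeroed.
    """
    p = params
    i = R.STATE_INDEX
    junc = y[i["Caj"]] + y[i["SLLj"]] + y[i["SLHj"]]
    sl = y[i["Casl"]] + y[i["SLLsl"]] + y[i["SLHsl"]]
    myo = (y[i["Cai"]] + y[i["TnCL"]] + y[i["TnCHc"]] + y[i["CaM"]]
           + y[i["Myoc"]] + y[i["SRB"]])
    sr = y[i["Ca_sr"]] + y[i["Csqn"]]
    return (p.Vjunc * junc + p.Vsl * sl + p.Vmyo * myo + p.Vsr * sr)


def zero_sarcolemmal_ca_fluxes(params: GPBParameters) -> GPBParameters:
    """Parameter set with every transmembrane Ca pathway switched off."""
    return params.replace(pCa=0.0, GCaB=0.0, IbarSLCaP=0.0, IbarNCX=0.0)
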