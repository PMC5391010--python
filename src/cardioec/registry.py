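"""Canonical state-variable registry for the coupled myocyte model.

Every consumer of the state vector (right-hand side, integrator, I/O,
tests) resolves indices through this registry; positional literals are
defined here once and nowhere else.

The electrophysiology block is the Grandi-Pasqualini-Bers (GPB) human
ventricular myocyte model extended with the two late-Na gates (mL, hL).
The GPB model proper has 38 dynamic equations (bulk K+ is clamped); the
late-Na extension adds two, and the NHS myofilament block five more.
"""

from __future__ import annotations

import numpy as np

# (name, unit, lower bound, upper bound). Bounds are physical validity
# bounds used for input validation, not solver constraints.  ``inf`` upper
# bounds on bound-buffer states are tightened dynamically against B_max by
# the validators in :mod:`cardioec.gpb`.
_INF = float("inf")

STATE_SPEC: list[tuple[str, str, float, float]] = [
    # fast Na gates
    ("m", "1", 0.0, 1.0),
    ("h", "1", 0.0, 1.0),
    ("j", "1", 0.0, 1.0),
    # L-type Ca gates
    ("d", "1", 0.0, 1.0),
    ("f", "1", 0.0, 1.0),
    ("fcaBj", "1", 0.0, 1.0),      # Ca-dependent inactivation fraction, junctional
    ("fcaBsl", "1", 0.0, 1.0),     # Ca-dependent inactivation fraction, subsarcolemmal
    # transient outward K gates (slow, fast)
    ("xtos", "1", 0.0, 1.0),
    ("ytos", "1", 0.0, 1.0),
    ("xtof", "1", 0.0, 1.0),
    ("ytof", "1", 0.0, 1.0),
    # delayed rectifiers
    ("xkr", "1", 0.0, 1.0),
    ("xks", "1", 0.0, 1.0),
    # RyR release channel states
    ("ryr_r", "1", 0.0, 1.0),
    ("ryr_o", "1", 0.0, 1.0),
    ("ryr_i", "1", 0.0, 1.0),
    # Na buffers (bound concentration, mM)
    ("NaBj", "mM", 0.0, _INF),
    ("NaBsl", "mM", 0.0, _INF),
    # cytosolic Ca buffers (bound concentration, mM)
    ("TnCL", "mM", 0.0, _INF),
    ("TnCHc", "mM", 0.0, _INF),
    ("TnCHm", "mM", 0.0, _INF),
    ("CaM", "mM", 0.0, _INF),
    ("Myoc", "mM", 0.0, _INF),
    ("Myom", "mM", 0.0, _INF),
    ("SRB", "mM", 0.0, _INF),
    # sarcolemmal Ca buffers (bound concentration, mM)
    ("SLLj", "mM", 0.0, _INF),
    ("SLLsl", "mM", 0.0, _INF),
    ("SLHj", "mM", 0.0, _INF),
    ("SLHsl", "mM", 0.0, _INF),
    # calsequestrin (bound concentration, mM)
    ("Csqn", "mM", 0.0, _INF),
    # ion concentrations
    ("Ca_sr", "mM", 0.0, _INF),
    ("Naj", "mM", 0.0, _INF),
    ("Nasl", "mM", 0.0, _INF),
    ("Nai", "mM", 0.0, _INF),
    ("Ki", "mM", 0.0, _INF),
    ("Caj", "mM", 0.0, _INF),
    ("Casl", "mM", 0.0, _INF),
    ("Cai", "mM", 0.0, _INF),
    # membrane potential
    ("Vm", "mV", -_INF, _INF),
    # late Na gates (model extension)
    ("mL", "1", 0.0, 1.0),
    ("hL", "1", 0.0, 1.0),
    # NHS myofilament states
    ("Ca_TRPN", "uM", 0.0, _INF),  # Ca bound to troponin C
    ("z_tm", "1", 0.0, 1.0),       # tropomyosin / available actin sites
    ("Q1", "1", -_INF, _INF),      # crossbridge fading-memory terms
    ("Q2", "1", -_INF, _INF),
    ("Q3", "1", -_INF, _INF),
]

STATE_NAMES: list[str] = [s[0] for s in STATE_SPEC]
STATE_UNITS: dict[str, str] = {s[0]: s[1] for s in STATE_SPEC}
STATE_INDEX: dict[str, int] = {n: i for i, n in enumerate(STATE_NAMES)}
N_STATES = len(STATE_NAMES)

# dynamic-equation bookkeeping: bulk K+ is clamped in the GPB model
N_GPB_ORIGINAL_ODES = 38          # published count for the original model
N_LATE_NA_ODES = 2
N_NHS_ODES = 5
CLAMPED_STATES = ("Ki",)

# integer index constants used by the compiled right-hand side
for _i, _n in enumerate(STATE_NAMES):
    globals()["S_" + _n.upper()] = _i

S_M: int; S_H: int; S_J: int; S_D: int; S_F: int
S_FCABJ: int; S_FCABSL: int
S_XTOS: int; S_YTOS: int; S_XTOF: int; S_YTOF: int
S_XKR: int; S_XKS: int
S_RYR_R: int; S_RYR_O: int; S_RYR_I: int
S_NABJ: int; S_NABSL: int
S_TNCL: int; S_TNCHC: int; S_TNCHM: int; S_CAM: int
S_MYOC: int; S_MYOM: int; S_SRB: int
S_SLLJ: int; S_SLLSL: int; S_SLHJ: int; S_SLHSL: int
S_CSQN: int; S_CA_SR: int
S_NAJ: int; S_NASL: int; S_NAI: int; S_KI: int
S_CAJ: int; S_CASL: int; S_CAI: int
S_VM: int; S_ML: int; S_HL: int
S_CA_TRPN: int; S_Z_TM: int; S_Q1: int; S_Q2: int; S_Q3: int


def state_bounds() -> tuple[np.ndarray, np.ndarray]:
    lo = np.array([s[2] for s in STATE_SPEC])
    hi = np.array([s[3] for s in STATE_SPEC])
    return lo, hi


# Default initial condition: the conventional 1-Hz resting state of the
# GPB model family (myofilament block starts fully relaxed except for a
# near-equilibrium troponin occupancy).  Production runs re-converge it by
# pre-pacing; see docs/methods.md for how the pre-pacing count was chosen.
_DEFAULT_INIT = {
    "m": 1.405627e-3,
    "h": 9.867005e-1,
    "j": 9.915620e-1,
    "d": 7.175662e-6,
    "f": 9.994000e-1,
    "fcaBj": 2.421991e-2,
    "fcaBsl": 1.452605e-2,
    "xtos": 4.051574e-3,
    "ytos": 9.945511e-1,
    "xtof": 4.051574e-3,
    "ytof": 9.945511e-1,
    "xkr": 8.641386e-3,
    "xks": 5.412034e-3,
    "ryr_r": 8.884332e-1,
    "ryr_o": 8.156628e-7,
    "ryr_i": 1.024274e-7,
    "NaBj": 3.539892e0,
    "NaBsl": 7.720854e-1,
    "TnCL": 8.773191e-3,
    "TnCHc": 1.078283e-1,
    "TnCHm": 1.524002e-2,
    "CaM": 2.911916e-4,
    "Myoc": 1.298754e-3,
    "Myom": 1.381982e-1,
    "SRB": 2.143165e-3,
    "SLLj": 9.566355e-3,
    "SLLsl": 1.110363e-1,
    "SLHj": 7.347888e-3,
    "SLHsl": 7.297378e-2,
    "Csqn": 1.242988e0,
    "Ca_sr": 0.554514e0,
    "Naj": 8.80329e0,
    "Nasl": 8.80733e0,
    "Nai": 8.80853e0,
    "Ki": 1.20e2,
    "Caj": 1.737475e-4,
    "Casl": 1.031812e-4,
    "Cai": 8.597401e-5,
    "Vm": -8.09763e1,
    "mL": 1.4e-3,
    "hL": 0.15,
    "Ca_TRPN": 3.0,
    "z_tm": 5.0e-3,
    "Q1": 0.0,
    "Q2": 0.0,
    "Q3": 0.0,
}


def default_initial_state() -> np.ndarray:
    """Return the default resting state vector (copy)."""
    y = np.empty(N_STATES)
    for name, idx in STATE_INDEX.items():
        y[idx] = _DEFAULT_INIT[name]
    return y
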