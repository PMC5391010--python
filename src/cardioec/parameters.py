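"""Model constants: GPB electrophysiology, NHS myofilament, Holzapfel-Ogden.

Internal unit conventions (conversions happen only at I/O boundaries):
time ms, voltage mV, membrane currents uA/uF, concentrations mM (GPB) or
uM (NHS), fluxes mM/ms, tension/stress kPa.

The GPB constants are the published human ventricular set; the two
junctional<->subsarcolemmal<->cytosol Ca diffusion constants carry the
modified values that raise the peak Ca transient to ~1 uM, and ``GNaL`` /
``tau_hL`` parameterize the late-Na extension (see docs/methods.md).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np

# cell geometry (um) -> compartment volumes (L)
_CELL_LENGTH = 100.0
_CELL_RADIUS = 10.25
VCELL = math.pi * _CELL_RADIUS**2 * _CELL_LENGTH * 1e-15  # [L]


@dataclass(frozen=True)
class GPBParameters:
    """All constants of the modified GPB myocyte model (flat, serializable)."""

    # physical constants
    R: float = 8314.0            # [J/kmol/K]
    Frdy: float = 96485.0        # [C/mol]
    Temp: float = 310.0          # [K]
    Cmem: float = 1.3810e-10     # [F] membrane capacitance

    # compartment volumes [L]
    Vcell: float = VCELL
    Vmyo: float = 0.65 * VCELL
    Vsr: float = 0.035 * VCELL
    Vsl: float = 0.02 * VCELL
    Vjunc: float = 0.0539 * 0.01 * VCELL

    # inter-compartment diffusion constants [L/ms]
    # Ca values are the modified ones (1.5x and 2.0x the original GPB
    # 8.2413e-13 and 3.7243e-12) that rescale the Ca transient peak to ~1 uM.
    J_ca_juncsl: float = 1.2362e-12
    J_ca_slmyo: float = 7.4485e-12
    J_na_juncsl: float = 1.0 / (1.6382e12 / 3 * 100)
    J_na_slmyo: float = 1.0 / (1.8308e10 / 3 * 100)

    # fraction of membrane current in the junctional cleft vs subsarcolemma
    Fjunc: float = 0.11
    Fsl: float = 0.89
    Fjunc_CaL: float = 0.9
    Fsl_CaL: float = 0.1

    # fixed external / internal ion concentrations [mM]
    Ko: float = 5.4
    Nao: float = 140.0
    Cao: float = 1.8
    Cli: float = 15.0
    Clo: float = 150.0
    Mgi: float = 1.0

    # fast Na current
    GNa: float = 23.0            # [mS/uF]
    GNaB: float = 0.597e-3       # [mS/uF] background Na

    # late Na current extension
    GNaL: float = 0.0065         # [mS/uF] maximal conductance
    tau_hL: float = 233.0        # [ms] baseline inactivation time constant

    # Na/K pump
    IbarNaK: float = 1.8         # [uA/uF]
    KmNaip: float = 11.0         # [mM]
    KmKo: float = 1.5            # [mM]

    # K currents
    pNaK: float = 0.01833        # Na permeability ratio of IKs reversal
    gkr: float = 0.035           # [mS/uF] (times sqrt(Ko/5.4))
    gks: float = 0.0035          # [mS/uF]
    gkp: float = 0.002           # [mS/uF]
    gki: float = 0.35            # [mS/uF] (times sqrt(Ko/5.4))
    GtoSlow: float = 0.13 * 0.12   # [mS/uF] epicardial split
    GtoFast: float = 0.13 * 0.88   # [mS/uF]

    # Cl currents
    GClCa: float = 0.5 * 0.109625  # [mS/uF]
    GClB: float = 9e-3             # [mS/uF]
    KdClCa: float = 100e-3         # [mM]

    # L-type Ca current (GHK permeabilities [cm/s])
    pNa: float = 0.50 * 1.5e-8
    pCa: float = 0.50 * 5.4e-4
    pK: float = 0.50 * 2.7e-7
    Q10CaL: float = 1.8
    ICaL_scale: float = 0.45

    # Na/Ca exchanger
    IbarNCX: float = 4.5         # [uA/uF]
    KmCai: float = 3.59e-3       # [mM]
    KmCao: float = 1.3           # [mM]
    KmNai: float = 12.29         # [mM]
    KmNao: float = 87.5          # [mM]
    ksat: float = 0.32
    nu: float = 0.27
    Kdact: float = 0.150e-3      # [mM]
    Q10NCX: float = 1.57

    # sarcolemmal Ca pump
    IbarSLCaP: float = 0.0673    # [uA/uF]
    KmPCa: float = 0.5e-3        # [mM]
    Q10SLCaP: float = 2.35

    # background Ca current
    GCaB: float = 5.513e-4       # [uA/uF]

    # SR fluxes: SERCA uptake, RyR release, leak
    Q10SRCaP: float = 2.6
    Vmax_SRCaP: float = 5.3114e-3  # [mM/ms]
    Kmf: float = 0.246e-3          # [mM]
    Kmr: float = 1.7               # [mM]
    hillSRCaP: float = 1.787
    ks: float = 25.0               # [1/ms] RyR release rate
    koCa: float = 10.0             # [1/mM^2/ms]
    kom: float = 0.06              # [1/ms]
    kiCa: float = 0.5              # [1/mM/ms]
    kim: float = 0.005             # [1/ms]
    ec50SR: float = 0.45           # [mM]
    MaxSR: float = 15.0
    MinSR: float = 1.0
    leak_rate: float = 5.348e-6    # [1/ms] SR leak coefficient

    # Na buffering
    Bmax_Naj: float = 7.561      # [mM]
    Bmax_Nasl: float = 1.65      # [mM]
    koff_na: float = 1e-3        # [1/ms]
    kon_na: float = 0.1e-3       # [1/mM/ms]

    # cytosolic Ca buffers
    Bmax_TnClow: float = 70e-3     # [mM]
    koff_tncl: float = 19.6e-3     # [1/ms]
    kon_tncl: float = 32.7         # [1/mM/ms]
    Bmax_TnChigh: float = 140e-3   # [mM]
    koff_tnchca: float = 0.032e-3  # [1/ms]
    kon_tnchca: float = 2.37       # [1/mM/ms]
    koff_tnchmg: float = 3.33e-3   # [1/ms]
    kon_tnchmg: float = 3e-3       # [1/mM/ms]
    Bmax_CaM: float = 24e-3        # [mM]
    koff_cam: float = 238e-3       # [1/ms]
    kon_cam: float = 34.0          # [1/mM/ms]
    Bmax_myosin: float = 140e-3    # [mM]
    koff_myoca: float = 0.46e-3    # [1/ms]
    kon_myoca: float = 13.8        # [1/mM/ms]
    koff_myomg: float = 0.057e-3   # [1/ms]
    kon_myomg: float = 0.0157      # [1/mM/ms]
    Bmax_SR: float = 19 * 0.9e-3   # [mM]
    koff_sr: float = 60e-3         # [1/ms]
    kon_sr: float = 100.0          # [1/mM/ms]

    # sarcolemmal Ca buffers (Bmax scaled by compartment volume ratios)
    Bmax_SLlowsl: float = 37.4e-3 * 0.65 / 0.02
    Bmax_SLlowj: float = 4.6e-3 * 0.65 / 0.00539 * 0.1
    koff_sll: float = 1300e-3      # [1/ms]
    kon_sll: float = 100.0         # [1/mM/ms]
    Bmax_SLhighsl: float = 13.4e-3 * 0.65 / 0.02
    Bmax_SLhighj: float = 1.65e-3 * 0.65 / 0.00539 * 0.1
    koff_slh: float = 30e-3        # [1/ms]
    kon_slh: float = 100.0         # [1/mM/ms]

    # calsequestrin
    Bmax_Csqn: float = 140e-3 * 0.65 / 0.035
    koff_csqn: float = 65.0        # [1/ms]
    kon_csqn: float = 100.0        # [1/mM/ms]

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ValueError(f"parameter {f.name} is not finite")
        nonneg = [f.name for f in dataclasses.fields(self)
                  if f.name not in ("Temp",)]
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValueError(f"parameter {name} must be non-negative")
        if abs(self.Fjunc + self.Fsl - 1.0) > 1e-12:
            raise ValueError("Fjunc + Fsl must equal 1")
        if abs(self.Fjunc_CaL + self.Fsl_CaL - 1.0) > 1e-12:
            raise ValueError("Fjunc_CaL + Fsl_CaL must equal 1")

    def replace(self, **kwargs) -> "GPBParameters":
        return dataclasses.replace(self, **kwargs)

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in GPB_PARAM_NAMES])

    def to_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in GPB_PARAM_NAMES}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "GPBParameters":
        unknown = set(d) - set(GPB_PARAM_NAMES)
        if unknown:
            raise KeyError(f"unknown GPB parameter(s): {sorted(unknown)}")
        return cls(**d)


GPB_PARAM_NAMES: list[str] = [f.name for f in dataclasses.fields(GPBParameters)]
GPB_PARAM_INDEX: dict[str, int] = {n: i for i, n in enumerate(GPB_PARAM_NAMES)}

# index constants for the compiled right-hand side (P_<NAME>)
for _i, _n in enumerate(GPB_PARAM_NAMES):
    globals()["P_" + _n.upper()] = _i


@dataclass(frozen=True)
class NHSParameters:
    """NHS myofilament model constants (native units: uM, s, kPa)."""

    k_on: float = 100.0        # [1/uM/s] Ca-troponin binding
    k_refoff: float = 200.0    # [1/s] reference unbinding rate
    gamma_trpn: float = 2.0    # tension dependence of unbinding
    Ca_TRPN_max: float = 70.0  # [uM] total troponin C
    Ca50_ref: float = 1.05     # [uM] half-activation Ca at lambda = 1
    T_ref: float = 56.2        # [kPa] reference isometric tension
    beta_0: float = 4.9        # length dependence of T0
    beta_1: float = -4.0       # length dependence of Ca50
    n_hill: float = 3.0        # tropomyosin activation Hill coefficient
    z_p: float = 0.85          # linearization point for z_max
    alpha_0: float = 8.0       # [1/s] tropomyosin activation rate
    alpha_r1: float = 2.0      # [1/s] linear relaxation rate
    alpha_r2: float = 1.75     # [1/s] nonlinear relaxation rate
    n_rel: float = 3.0
    K_z: float = 0.15
    a_xb: float = 0.35         # crossbridge tension curvature
    A1: float = -29.0
    A2: float = 138.0
    A3: float = 129.0
    alpha_1: float = 30.0      # [1/s]
    alpha_2: float = 130.0     # [1/s]
    alpha_3: float = 625.0     # [1/s]

    def replace(self, **kwargs) -> "NHSParameters":
        return dataclasses.replace(self, **kwargs)

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in NHS_PARAM_NAMES])

    def to_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in NHS_PARAM_NAMES}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "NHSParameters":
        unknown = set(d) - set(NHS_PARAM_NAMES)
        if unknown:
            raise KeyError(f"unknown NHS parameter(s): {sorted(unknown)}")
        return cls(**d)


NHS_PARAM_NAMES: list[str] = [f.name for f in dataclasses.fields(NHSParameters)]
for _i, _n in enumerate(NHS_PARAM_NAMES):
    globals()["NP_" + _n.upper()] = _i


@dataclass(frozen=True)
class HOParameters:
    """Holzapfel-Ogden passive law constants plus active-tension scaling.

    Defaults are the inversely-estimated healthy-LV values (a-type in kPa,
    b-type dimensionless).
    """

    a: float = 0.24
    b: float = 5.08
    a_f: float = 1.46
    b_f: float = 4.15
    a_s: float = 0.87
    b_s: float = 1.6
    a_fs: float = 0.3
    b_fs: float = 1.3
    T_scale: float = 3.0

    def __post_init__(self):
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"HO parameter {f.name} must be non-negative")

    def replace(self, **kwargs) -> "HOParameters":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name))
                for f in dataclasses.fields(self)}
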