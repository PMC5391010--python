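"""Holzapfel-Ogden passive myocardium, active stress, and a thick-walled
incompressible-sphere surrogate of left-ventricular pump function.

The passive law is the structure-based orthotropic strain-energy function

    W = a/(2b) [exp(b(I1-3)) - 1]
        + sum_{i=f,s} a_i/(2b_i) [exp(b_i (I4i' - 1)^2) - 1]
        + a_fs/(2 b_fs) [exp(b_fs I8fs^2) - 1],

with I4i' = max(I4i, 1) so fiber/sheet families bear load only in
extension.  (The isotropic term is normalized by its reference-state
constant so W(I) = 0; stress is unaffected.)  The first Piola-Kirchhoff
stress carries the reference-state correction

    P^p = dW/dF - a exp(b(I1-3)) F^{-T},

which guarantees P^p(I) = 0 exactly.

The sphere surrogate replaces the full 3D fluid-structure model: a
thick-walled sphere with exactly incompressible radial kinematics,
fibers and sheets lying in the two tangential directions, inflated
quasi-statically.  It reproduces directional pump-function trends
(end-diastolic volume vs filling pressure, end-systolic volume vs
afterload and contractility), not organ-level magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .parameters import HOParameters

MMHG_TO_KPA = 0.133322


@dataclass(frozen=True)
class DeformationState:
    """Deformation gradient with reference fiber/sheet directions."""

    F: np.ndarray
    f0: np.ndarray
    s0: np.ndarray

    def __post_init__(self):
        F = np.asarray(self.F, dtype=float)
        if F.shape != (3, 3):
            raise ValueError("F must be a 3x3 matrix")
        for name in ("f0", "s0"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,):
                raise ValueError(f"{name} must be a 3-vector")
            if abs(np.linalg.norm(v) - 1.0) > 1e-8:
                raise ValueError(f"{name} must be a unit vector")
        object.__setattr__(self, "F", F)
        object.__setattr__(self, "f0", np.asarray(self.f0, dtype=float))
        object.__setattr__(self, "s0", np.asarray(self.s0, dtype=float))
        if np.linalg.det(F) <= 0:
            raise ValueError("det(F) must be positive")

    @property
    def J(self) -> float:
        return float(np.linalg.det(self.F))

    @property
    def C(self) -> np.ndarray:
        return self.F.T @ self.F

    @property
    def I1(self) -> float:
        return float(np.trace(self.C))

    @property
    def I4f(self) -> float:
        return float(self.f0 @ self.C @ self.f0)

    @property
    def I4s(self) -> float:
        return float(self.s0 @ self.C @ self.s0)

    @property
    def I8fs(self) -> float:
        return float(self.f0 @ self.C @ self.s0)

    @property
    def fbar(self) -> np.ndarray:
        """Unit vector of the current (deformed) fiber direction."""
        f = self.F @ self.f0
        return f / np.linalg.norm(f)


def strain_energy(defo: DeformationState, params: HOParameters) -> float:
    """Strain energy density W (kPa), zero in the reference state."""
    p = params
    I1, I4f, I4s, I8fs = defo.I1, defo.I4f, defo.I4s, defo.I8fs
    W = p.a / (2.0 * p.b) * (np.exp(p.b * (I1 - 3.0)) - 1.0)
    for a_i, b_i, I4 in ((p.a_f, p.b_f, I4f), (p.a_s, p.b_s, I4s)):
        e = max(I4, 1.0) - 1.0  # fiber families only load in extension
        if a_i > 0:
            W += a_i / (2.0 * b_i) * (np.exp(b_i * e * e) - 1.0)
    if p.a_fs > 0:
        W += p.a_fs / (2.0 * p.b_fs) * (np.exp(p.b_fs * I8fs**2) - 1.0)
    return float(W)


def passive_pk1(defo: DeformationState, params: HOParameters) -> np.ndarray:
    """First Piola-Kirchhoff passive stress (kPa); exactly zero at F = I."""
    p = params
    F = defo.F
    f0, s0 = defo.f0, defo.s0
    I1, I4f, I4s, I8fs = defo.I1, defo.I4f, defo.I4s, defo.I8fs
    iso = p.a * np.exp(p.b * (I1 - 3.0))
    P = iso * F
    if I4f > 1.0:
        P = P + (2.0 * p.a_f * (I4f - 1.0)
                 * np.exp(p.b_f * (I4f - 1.0) ** 2)) * (F @ np.outer(f0, f0))
    if I4s > 1.0:
        P = P + (2.0 * p.a_s * (I4s - 1.0)
                 * np.exp(p.b_s * (I4s - 1.0) ** 2)) * (F @ np.outer(s0, s0))
    P = P + (p.a_fs * I8fs * np.exp(p.b_fs * I8fs**2)) \
        * (F @ (np.outer(f0, s0) + np.outer(s0, f0)))
    # reference-state correction: -a exp(b(I1-3)) F^{-T}
    P = P - iso * np.linalg.inv(F).T
    return P


def active_cauchy_stress(T: float, fbar: np.ndarray,
                         T_scale: float = 1.0) -> np.ndarray:
    """Active Cauchy stress T_scale * T * fbar (x) fbar (kPa)."""
    fbar = np.asarray(fbar, dtype=float)
    if fbar.shape != (3,) or abs(np.linalg.norm(fbar) - 1.0) > 1e-8:
        raise ValueError("fbar must be a unit 3-vector")
    return T_scale * T * np.outer(fbar, fbar)


@dataclass(frozen=True)
class SphereLVConfig:
    """Geometry and loading of the spherical LV surrogate.

    Radii in cm (reference, unloaded); pressures in mmHg.  Default
    geometry is a typical unloaded human LV-scale sphere (cavity ~45 mL,
    wall ~1 cm); default pressures are the end-diastolic and end-systolic
    loading values of the organ-level protocol (8 and 150 mmHg).
    """

    inner_radius_cm: float = 2.2
    outer_radius_cm: float = 3.2
    ed_pressure_mmHg: float = 8.0
    es_pressure_mmHg: float = 150.0

    def __post_init__(self):
        if not 0 < self.inner_radius_cm < self.outer_radius_cm:
            raise ValueError("need 0 < inner radius < outer radius")
        if self.ed_pressure_mmHg < 0 or self.es_pressure_mmHg < 0:
            raise ValueError("pressures must be non-negative")


_GAUSS_N = 96
_GAUSS_X, _GAUSS_W = np.polynomial.legendre.leggauss(_GAUSS_N)


def _tangential_stress_difference(lam: np.ndarray,
                                  params: HOParameters) -> np.ndarray:
    """s_tt + s_pp - 2 s_rr for F = diag(lam^-2, lam, lam), fibers along
    theta and sheets along phi (both tangential; I8fs = 0).

    Normal-stress differences are independent of the constraint pressure
    and of the reference-state correction (both isotropic in Cauchy form).
    Equivalent to evaluating :func:`passive_pk1` on the same deformation
    (cross-checked in the test suite).
    """
    lam = np.asarray(lam, dtype=float)
    I1 = 2.0 * lam**2 + lam**-4
    iso = params.a * np.exp(params.b * (I1 - 3.0))
    dev = iso * (2.0 * lam**2 - 2.0 * lam**-4)
    I4 = lam**2
    stretch = I4 > 1.0
    for a_i, b_i in ((params.a_f, params.b_f), (params.a_s, params.b_s)):
        term = np.where(
            stretch,
            2.0 * a_i * (I4 - 1.0) * np.exp(b_i * (I4 - 1.0) ** 2) * I4,
            0.0)
        dev = dev + term
    return dev


def _sphere_pressure(ri: float, config: SphereLVConfig, params: HOParameters,
                     active_tension_kPa: float) -> float:
    """Cavity pressure (kPa) in equilibrium with deformed inner radius ri.

    Incompressible radial map r(R)^3 = R^3 + ri^3 - Ri^3; at radius r the
    tangential stretch is lam = r/R.  Radial equilibrium integrates the
    tangential/radial normal-stress difference across the wall,
    P = int_ri^ro (s_tt + s_pp - 2 s_rr + T_active) dr / r, with the
    active fiber tension split equally between the two tangential
    directions (fixed-order Gauss-Legendre quadrature).
    """
    Ri = config.inner_radius_cm
    Ro = config.outer_radius_cm
    ro = (Ro**3 + ri**3 - Ri**3) ** (1.0 / 3.0)
    r = 0.5 * (ro - ri) * _GAUSS_X + 0.5 * (ro + ri)
    w = 0.5 * (ro - ri) * _GAUSS_W
    R = (r**3 - ri**3 + Ri**3) ** (1.0 / 3.0)
    lam = r / R
    dev = _tangential_stress_difference(lam, params)
    return float(np.sum(w * (dev + active_tension_kPa) / r))


def sphere_inflate(config: SphereLVConfig, params: HOParameters,
                   pressure_mmHg: float, active_tension_kPa: float = 0.0,
                   bracket=(0.3, 3.0), n_scan: int = 400) -> float:
    """Equilibrium cavity volume (mL) under pressure and active tension.

    The pressure balance is solved by bracketed root-finding on the
    deformed inner radius over ``bracket`` x reference inner radius.  An
    actively contracting sphere can have several equilibria; the
    most-contracted one (smallest radius) is selected deterministically,
    which makes the end-systolic volume monotone in tension and afterload.
    """
    target = pressure_mmHg * MMHG_TO_KPA

    def residual(ri):
        return _sphere_pressure(ri, config, params, active_tension_kPa) - target

    lo = bracket[0] * config.inner_radius_cm
    hi = bracket[1] * config.inner_radius_cm
    grid = np.linspace(lo, hi, n_scan)
    res = np.array([residual(g) for g in grid])
    sign_change = np.nonzero(np.diff(np.sign(res)) != 0)[0]
    if sign_change.size == 0:
        raise RuntimeError(
            "no equilibrium in bracket "
            f"[{lo:.3g}, {hi:.3g}] cm: residual range "
            f"[{res.min():.4g}, {res.max():.4g}] kPa around target "
            f"{target:.4g} kPa")
    k = int(sign_change[0])
    ri = brentq(residual, grid[k], grid[k + 1], xtol=1e-10, rtol=1e-12)
    return float(4.0 / 3.0 * np.pi * ri**3)


def sphere_pv(config: SphereLVConfig, params: HOParameters,
              peak_tension_kPa: float) -> dict[str, float]:
    """Quasi-static pump-function summary of the sphere surrogate.

    EDV: passive inflation at the end-diastolic pressure.  ESV: inflation
    at the end-systolic pressure with the myocyte model's peak active
    tension times T_scale held constant (the end-systolic loading
    protocol).  Returns EDV, ESV, SV = EDV - ESV and EF = SV/EDV; SV and
    EF are negative when the ventricle cannot eject against the afterload.
    """
    edv = sphere_inflate(config, params, config.ed_pressure_mmHg, 0.0)
    esv = sphere_inflate(config, params, config.es_pressure_mmHg,
                         params.T_scale * peak_tension_kPa)
    sv = edv - esv
    return {"EDV_mL": edv, "ESV_mL": esv, "SV_mL": sv,
            "EF_percent": 100.0 * sv / edv}
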