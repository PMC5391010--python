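"""The healthy -> failing continuum of ion-channel remodelling.

Heart-failure remodelling is encoded as 11 dimensionless multipliers
("impact factors") on Ca-handling-relevant quantities of the myocyte
model: the late-Na inactivation time constant (f_hl) and conductance
(f_NaL), inward-rectifier K (f_Ki), Na/K pump (f_NaK), background Na and
Ca currents (f_Nabk, f_Cabk), Na/Ca exchanger (f_ncx), transient-outward
K (f_to), SR leak (f_SRleak), SERCA uptake (f_SRca) and the SR-release
half-activation EC50 (f_EC50SR).

Four named cases span the continuum: A (healthy, all unity), D
(end-stage failure), and B/C obtained by moving one- and two-thirds of
the way from A to D componentwise.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np

FACTOR_NAMES: list[str] = [
    "f_hl", "f_NaL", "f_Ki", "f_NaK", "f_Nabk", "f_Cabk",
    "f_ncx", "f_to", "f_SRleak", "f_SRca", "f_EC50SR",
]


@dataclass(frozen=True)
class ImpactFactors:
    f_hl: float = 1.0
    f_NaL: float = 1.0
    f_Ki: float = 1.0
    f_NaK: float = 1.0
    f_Nabk: float = 1.0
    f_Cabk: float = 1.0
    f_ncx: float = 1.0
    f_to: float = 1.0
    f_SRleak: float = 1.0
    f_SRca: float = 1.0
    f_EC50SR: float = 1.0

    def __post_init__(self):
        for name in FACTOR_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"impact factor {name} is not finite")
            if v < 0:
                raise ValueError(f"impact factor {name} must be >= 0")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FACTOR_NAMES])

    def to_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in FACTOR_NAMES}

    @classmethod
    def from_array(cls, arr) -> "ImpactFactors":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (len(FACTOR_NAMES),):
            raise ValueError(
                f"expected {len(FACTOR_NAMES)} impact factors, got shape {arr.shape}")
        return cls(**dict(zip(FACTOR_NAMES, arr)))

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "ImpactFactors":
        unknown = set(d) - set(FACTOR_NAMES)
        if unknown:
            raise KeyError(f"unknown impact factor(s): {sorted(unknown)}")
        return cls(**d)

    def replace(self, **kwargs) -> "ImpactFactors":
        return dataclasses.replace(self, **kwargs)


# endpoint rows of the continuum (healthy A, end-stage failing D)
CASE_A = ImpactFactors()
CASE_D = ImpactFactors(
    f_hl=2.0, f_NaL=2.0, f_Ki=0.68, f_NaK=0.5, f_Nabk=0.0,
    f_Cabk=1.530, f_ncx=1.75, f_to=0.4, f_SRleak=5.0, f_SRca=0.5,
    f_EC50SR=0.89,
)

# severity fraction of each named case on the A -> D line
CASE_SEVERITY: dict[str, float] = {"A": 0.0, "B": 1.0 / 3.0, "C": 2.0 / 3.0, "D": 1.0}


def factors_for_severity(s: float) -> ImpactFactors:
    """Componentwise interpolation A + s*(D - A) at severity ``s``.

    ``s`` outside [0, 1] is allowed for extrapolation studies but flagged
    with a warning.  Full precision is kept; printed-table rounding is a
    display concern only.
    """
    s = float(s)
    if not np.isfinite(s):
        raise ValueError("severity must be finite")
    a = CASE_A.to_array()
    d = CASE_D.to_array()
    vals = a + s * (d - a)
    if s < 0.0 or s > 1.0:
        warnings.warn(
            f"severity {s} outside [0, 1]: extrapolating beyond the "
            "healthy-failing continuum (factors clipped at 0)", stacklevel=2)
        vals = np.maximum(vals, 0.0)
    return ImpactFactors.from_array(vals)


def factors_for_case(label) -> ImpactFactors:
    """Resolve a case letter, severity fraction, factor mapping or vector."""
    if isinstance(label, ImpactFactors):
        return label
    if isinstance(label, str):
        key = label.strip().upper()
        if key not in CASE_SEVERITY:
            raise KeyError(f"unknown case label {label!r}; expected one of A-D")
        return factors_for_severity(CASE_SEVERITY[key])
    if isinstance(label, dict):
        return ImpactFactors.from_dict(label)
    if isinstance(label, (int, float)):
        return factors_for_severity(label)
    if np.ndim(label) == 1:
        return ImpactFactors.from_array(label)
    raise TypeError(f"cannot interpret {label!r} as a disease case")


# printed table rows (3-4 significant figures) for regression against the
# published case definitions; computation always uses exact interpolation.
PRINTED_TABLE: dict[str, dict[str, float]] = {
    "A": {n: 1.0 for n in FACTOR_NAMES},
    "B": dict(zip(FACTOR_NAMES,
                  [1.333, 1.333, 0.893, 0.833, 0.667, 1.177,
                   1.25, 0.8, 2.333, 0.833, 0.963])),
    "C": dict(zip(FACTOR_NAMES,
                  [1.666, 1.666, 0.787, 0.667, 0.333, 1.353,
                   1.5, 0.6, 3.667, 0.667, 0.927])),
    "D": CASE_D.to_dict(),
}
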