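"""Scalar features of action-potential, Ca-transient and tension traces.

All features are defined on one recorded beat whose time origin is the
stimulus onset.  Sub-sample linear interpolation is used at every level
crossing; derivatives are centered finite differences on the recorded
grid (the simulator's dense output, not raw adaptive solver steps).
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

#: Repolarization fraction defining the effective refractory period:
#: ERP is measured from the AP upstroke to the crossing of this fraction
#: of repolarization.  The value is calibrated once so that the healthy
#: case reproduces the published ERP/APD90 relationship; it is a named
#: configuration constant, not a hidden fit (see docs/methods.md).
ERP_REPOLARIZATION_FRACTION = 0.80

#: Minimum upstroke velocity (mV/ms) below which a trace is considered
#: to contain no action potential.
AP_DETECTION_THRESHOLD = 5.0


class NoActionPotentialError(ValueError):
    """Raised when a voltage trace contains no detectable AP upstroke."""


class NoPeakError(ValueError):
    """Raised when a transient trace has no interior peak."""


@dataclass(frozen=True)
class BiomarkerReport:
    """The scalar features of one beat (units in field names)."""

    apd90_ms: float
    resting_potential_mV: float
    ap_amplitude_mV: float
    ap_upstroke_velocity_V_per_s: float
    erp_ms: float
    cat_peak_uM: float
    cat_time_to_peak_s: float
    cat_upstroke_velocity_uM_per_s: float
    cat_amplitude_uM: float
    tension_peak_kPa: float
    tension_dev_rate_kPa_per_s: float
    tension_rt50_s: float

    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}


def _check_trace(t, x, min_samples=3):
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    if t.ndim != 1 or t.shape != x.shape:
        raise ValueError("time and signal must be 1-D arrays of equal length")
    if t.size < min_samples:
        raise ValueError(f"need at least {min_samples} samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be strictly increasing")
    return t, x


def _derivative(t, x):
    """Centered finite differences (one-sided at the ends)."""
    return np.gradient(x, t)


def _cross_down(t, x, level, start_idx):
    """First downward crossing of ``level`` at or after ``start_idx``,
    linearly interpolated; None if never crossed."""
    xs = x[start_idx:]
    below = np.nonzero(xs < level)[0]
    if below.size == 0:
        return None
    k = start_idx + below[0]
    if k == 0:
        return t[0]
    t0, t1 = t[k - 1], t[k]
    x0, x1 = x[k - 1], x[k]
    if x0 == x1:
        return t1
    return t0 + (level - x0) / (x1 - x0) * (t1 - t0)


def upstroke_time(t, vm):
    """Time of maximal dVm/dt; raises if no AP is present."""
    t, vm = _check_trace(t, vm)
    dv = _derivative(t, vm)
    i = int(np.argmax(dv))
    if dv[i] < AP_DETECTION_THRESHOLD:
        raise NoActionPotentialError(
            f"max dVm/dt {dv[i]:.3g} mV/ms below detection threshold "
            f"{AP_DETECTION_THRESHOLD} mV/ms")
    return t[i]


def apd(t, vm, repolarization_fraction: float = 0.9) -> float:
    """Action-potential duration (ms) at the given repolarization fraction.

    Measured from the time of maximal dVm/dt to the downstroke crossing of
    resting + (1 - fraction) * amplitude, where the resting potential is
    the pre-stimulus (first-sample) value and amplitude = peak - resting.
    """
    if not 0.0 < repolarization_fraction < 1.0:
        raise ValueError("repolarization fraction must lie in (0, 1)")
    t, vm = _check_trace(t, vm)
    t_up = upstroke_time(t, vm)
    rest = vm[0]
    i_peak = int(np.argmax(vm))
    amplitude = vm[i_peak] - rest
    level = rest + (1.0 - repolarization_fraction) * amplitude
    t_cross = _cross_down(t, vm, level, i_peak)
    if t_cross is None:
        raise ValueError(
            f"repolarization level {level:.3g} mV never crossed")
    return float(t_cross - t_up)


def erp(t, vm,
        repolarization_fraction: float = ERP_REPOLARIZATION_FRACTION,
        level_mV: float | None = None) -> float:
    """Effective refractory period (ms): upstroke to repolarization level.

    The level is either the configured repolarization fraction (default
    :data:`ERP_REPOLARIZATION_FRACTION`) or an absolute voltage
    ``level_mV``.  With fraction 0.9 this equals APD90 by construction.
    """
    t, vm = _check_trace(t, vm)
    t_up = upstroke_time(t, vm)
    if level_mV is None:
        rest = vm[0]
        amplitude = np.max(vm) - rest
        level_mV = rest + (1.0 - repolarization_fraction) * amplitude
    t_cross = _cross_down(t, vm, level_mV, int(np.argmax(vm)))
    if t_cross is None:
        raise ValueError(f"repolarization level {level_mV:.3g} mV never crossed")
    return float(t_cross - t_up)


def upstroke_velocity(t, x) -> float:
    """Maximal centered-difference first derivative, per ms.

    For Vm in mV this is mV/ms, numerically equal to V/s; for Ca in uM it
    is uM/ms (multiply by 1e3 for uM/s).
    """
    t, x = _check_trace(t, x)
    return float(np.max(_derivative(t, x)))


def transient_features(t, x, stim_onset: float = 0.0):
    """(peak, time_to_peak, amplitude, rate_of_development, RT50).

    peak = max; time_to_peak from ``stim_onset``; amplitude above the
    pre-stimulus diastolic (first-sample) value; rate of development =
    max first derivative (per ms); RT50 = time from the peak to the decay
    crossing of diastolic + amplitude/2, sub-sample interpolated (ms).
    """
    t, x = _check_trace(t, x)
    i_peak = int(np.argmax(x))
    if i_peak == 0 or i_peak == len(x) - 1:
        raise NoPeakError("signal has no interior peak")
    peak = float(x[i_peak])
    dia = float(x[0])
    amplitude = peak - dia
    if amplitude <= 0:
        raise NoPeakError("signal has no rise above its diastolic value")
    t_cross = _cross_down(t, x, dia + 0.5 * amplitude, i_peak)
    rt50 = float(t_cross - t[i_peak]) if t_cross is not None else np.nan
    return (peak, float(t[i_peak] - stim_onset), amplitude,
            float(np.max(_derivative(t, x))), rt50)


def extract_report(trace, stim_onset: float | None = None,
                   erp_repolarization_fraction: float = ERP_REPOLARIZATION_FRACTION,
                   ) -> BiomarkerReport:
    """Full per-beat biomarker panel from a :class:`SimulationTrace`.

    Time-like Ca/tension features are reported in seconds, velocities in
    per-second units, matching conventional reporting.
    """
    if stim_onset is None:
        stim_onset = float(trace.metadata.get("stim_onset_ms", 0.0))
    t, vm, ca, tension = trace.t, trace.vm, trace.ca_i, trace.tension
    ca_pk, ca_ttp, ca_amp, ca_rate, _ = transient_features(t, ca, stim_onset)
    tn_pk, _, _, tn_rate, tn_rt50 = transient_features(t, tension, stim_onset)
    return BiomarkerReport(
        apd90_ms=apd(t, vm, 0.9),
        resting_potential_mV=float(vm[0]),
        ap_amplitude_mV=float(np.max(vm) - vm[0]),
        ap_upstroke_velocity_V_per_s=upstroke_velocity(t, vm),
        erp_ms=erp(t, vm, erp_repolarization_fraction),
        cat_peak_uM=ca_pk,
        cat_time_to_peak_s=ca_ttp / 1e3,
        cat_upstroke_velocity_uM_per_s=upstroke_velocity(t, ca) * 1e3,
        cat_amplitude_uM=ca_amp,
        tension_peak_kPa=tn_pk,
        tension_dev_rate_kPa_per_s=tn_rate * 1e3,
        tension_rt50_s=tn_rt50 / 1e3,
    )


#: Printed reference panel (per-case columns A-D) used by the comparison
#: tooling; rows keyed by BiomarkerReport field names.
TABLE2_REFERENCE: dict[str, list[float]] = {
    "apd90_ms": [270.19, 301.91, 341.77, 399.89],
    "resting_potential_mV": [-80.55, -80.00, -79.17, -77.86],
    "ap_amplitude_mV": [123.36, 123.87, 123.86, 122.42],
    "ap_upstroke_velocity_V_per_s": [370.70, 354.71, 330.71, 291.18],
    "erp_ms": [261.06, 291.23, 330.00, 385.89],
    "cat_peak_uM": [0.9752, 0.6712, 0.4714, 0.3690],
    "cat_time_to_peak_s": [0.039, 0.054, 0.076, 0.106],
    "cat_upstroke_velocity_uM_per_s": [139.54, 45.97, 14.19, 5.10],
    "cat_amplitude_uM": [0.87, 0.56, 0.36, 0.25],
    "tension_peak_kPa": [9.87, 5.72, 3.85, 3.31],
    "tension_dev_rate_kPa_per_s": [211.96, 99.20, 43.62, 22.98],
    "tension_rt50_s": [0.182, 0.294, 0.412, 0.497],
}

#: Direction of each row along the healthy -> failing axis, as exhibited
#: by the reference panel itself ("+" increases A->D, "-" decreases;
#: AP amplitude is not monotone in the reference and is excluded).
SEVERITY_ORDERINGS: dict[str, str] = {
    "apd90_ms": "+",
    "resting_potential_mV": "+",
    "ap_upstroke_velocity_V_per_s": "-",
    "erp_ms": "+",
    "cat_peak_uM": "-",
    "cat_time_to_peak_s": "+",
    "cat_upstroke_velocity_uM_per_s": "-",
    "cat_amplitude_uM": "-",
    "tension_peak_kPa": "-",
    "tension_dev_rate_kPa_per_s": "-",
    "tension_rt50_s": "+",
}
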