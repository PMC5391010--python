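"""Analytic synthetic waveforms with known biomarker ground truth.

These emulate the geometric skeleton of a recorded beat (a triangular
action potential, Gaussian-bump Ca and tension transients) so that
feature extraction can be tested against closed forms.  They carry no
electrophysiological content beyond shape: amplitudes and time scales
default to physiological orders of magnitude, but nothing else about
real beats (notch/dome morphology, asymmetric decay) is represented.

Each generator returns ``(t, x, truth)`` where ``truth`` maps biomarker
names to the analytically exact values for that waveform.
"""

from __future__ import annotations

import numpy as np


def triangle_ap(rest_mV: float = -80.0, peak_mV: float = 40.0,
                rise_ms: float = 1.0, fall_ms: float = 300.0,
                t_start_ms: float = 10.0, total_ms: float = 500.0,
                dt_ms: float = 0.05):
    """Triangular AP: linear rise then linear fall back to rest.

    The analytic APD at repolarization fraction q, measured from the end
    of the rise (where the centered-difference upstroke locates within
    one sample of the corner), is q * fall_ms.
    """
    t = np.arange(0.0, total_ms + 0.5 * dt_ms, dt_ms)
    v = np.full_like(t, rest_mV)
    amp = peak_mV - rest_mV
    t1 = t_start_ms + rise_ms
    t2 = t1 + fall_ms
    rising = (t >= t_start_ms) & (t < t1)
    falling = (t >= t1) & (t < t2)
    v[rising] = rest_mV + amp * (t[rising] - t_start_ms) / rise_ms
    v[falling] = peak_mV - amp * (t[falling] - t1) / fall_ms
    truth = {
        "apd90_ms": 0.9 * fall_ms,
        "resting_potential_mV": rest_mV,
        "ap_amplitude_mV": amp,
        "ap_upstroke_velocity_V_per_s": amp / rise_ms,
        "upstroke_tolerance_ms": 2.0 * dt_ms + rise_ms,
    }
    return t, v, truth


def linear_ramp(x0: float = -80.0, x1: float = 20.0, rise_ms: float = 1.0,
                dt_ms: float = 0.01):
    """Pure linear ramp whose derivative is exactly (x1-x0)/rise_ms."""
    t = np.arange(0.0, rise_ms + 0.5 * dt_ms, dt_ms)
    x = x0 + (x1 - x0) * t / rise_ms
    return t, x, {"upstroke_velocity_per_ms": (x1 - x0) / rise_ms}


def gaussian_transient(baseline: float = 0.1, amplitude: float = 0.9,
                       t_peak_ms: float = 40.0, sigma_ms: float = 25.0,
                       total_ms: float = 400.0, dt_ms: float = 0.5):
    """Gaussian bump transient with closed-form features.

    x(t) = baseline + amplitude * exp(-(t - t_peak)^2 / (2 sigma^2)):
    peak at t_peak; maximal rise rate amplitude / (sigma sqrt(e)) at
    t_peak - sigma.  The diastolic value is the t = 0 sample (where the
    Gaussian tail e0 = exp(-t_peak^2 / (2 sigma^2)) is small but
    nonzero), so RT50 = sigma * sqrt(2 ln(2 / (1 + e0))).
    """
    t = np.arange(0.0, total_ms + 0.5 * dt_ms, dt_ms)
    x = baseline + amplitude * np.exp(-((t - t_peak_ms) ** 2)
                                      / (2.0 * sigma_ms**2))
    e0 = np.exp(-t_peak_ms**2 / (2.0 * sigma_ms**2))
    truth = {
        "peak": baseline + amplitude,
        "time_to_peak_ms": t_peak_ms,
        "amplitude": baseline + amplitude - x[0],
        "rate_of_development_per_ms": amplitude / (sigma_ms * np.exp(0.5)),
        "rt50_ms": sigma_ms * np.sqrt(2.0 * np.log(2.0 / (1.0 + e0))),
    }
    return t, x, truth
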