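"""Pacing, determinism, convergence and restartability."""

import numpy as np
import pytest

from cardioec.simulation import (SimulationTrace, SolverOptions,
                                 StimulusProtocol, paced_to_steady_state,
                                 simulate_myocyte)

FAST = SolverOptions(rtol=1e-6, atol=1e-9)


def test_protocol_validation():
    with pytest.raises(ValueError):
        StimulusProtocol(amplitude=-1.0)
    with pytest.raises(ValueError):
        StimulusProtocol(duration=1200.0, cycle_length=1000.0)
    with pytest.raises(ValueError):
        StimulusProtocol(n_record=0)


def test_trace_invariants_enforced():
    with pytest.raises(ValueError):
        SimulationTrace(t=np.array([0.0, 1.0, 0.5]), vm=np.zeros(3),
                        ca_i=np.zeros(3), tension=np.zeros(3))
    with pytest.raises(ValueError):
        SimulationTrace(t=np.arange(3.0), vm=np.zeros(2),
                        ca_i=np.zeros(3), tension=np.zeros(3))


def test_subthreshold_stimulus_stays_quiescent():
    """From a relaxed (unpaced) rest state, a vanishing stimulus elicits
    no action potential: Vm stays within 1 mV over a full cycle."""
    from scipy.integrate import solve_ivp

    from cardioec import _kernels as K
    from cardioec import registry as R
    from cardioec.disease import factors_for_case
    from cardioec.parameters import GPBParameters, NHSParameters

    p = GPBParameters().to_array()
    f = factors_for_case("A").to_array()
    n = NHSParameters().to_array()
    rest = solve_ivp(lambda t, y: K.full_rhs(y, p, f, n, 0.0, 1.0, 0.0),
                     (0.0, 60_000.0), R.default_initial_state(),
                     method="LSODA", rtol=1e-8, atol=1e-11,
                     t_eval=[60_000.0]).y[:, -1]
    prot = StimulusProtocol(amplitude=1e-6, n_prepace=0)
    tr = simulate_myocyte("A", prot, FAST, initial_state=rest)
    assert np.max(np.abs(tr.vm - tr.vm[0])) < 1.0


def test_identical_configs_are_bitwise_reproducible():
    prot = StimulusProtocol(n_prepace=2)
    a = simulate_myocyte("B", prot, FAST)
    b = simulate_myocyte("B", prot, FAST)
    assert np.array_equal(a.vm, b.vm)
    assert np.array_equal(a.ca_i, b.ca_i)
    assert np.array_equal(a.tension, b.tension)


def test_recorded_sampling_resolves_upstroke():
    prot = StimulusProtocol(n_prepace=0)
    tr = simulate_myocyte("A", prot, FAST)
    assert np.max(np.diff(tr.t)) <= 0.5  # <= 0.5 ms effective resolution
    assert tr.t[0] == 0.0


def test_multi_beat_recording_is_contiguous():
    prot = StimulusProtocol(n_prepace=0, n_record=2)
    tr = simulate_myocyte("A", prot, FAST)
    assert tr.t[-1] == pytest.approx(2 * prot.cycle_length)
    assert np.all(np.diff(tr.t) > 0)


def test_steady_state_with_infinite_tolerance_runs_fixed_beats():
    prot = StimulusProtocol(n_prepace=3)
    y, deltas = paced_to_steady_state("A", prot, tolerance=np.inf,
                                      solver=FAST)
    assert len(deltas) == 3
    assert np.all(np.isfinite(y))


def test_beat_to_beat_changes_shrink_toward_steady_state():
    prot = StimulusProtocol(n_prepace=1)
    _, deltas = paced_to_steady_state("A", prot, tolerance=0.0,
                                      max_beats=30, solver=FAST)
    assert len(deltas) == 30
    # convergence diagnostic: late changes much smaller than early ones
    assert np.mean(deltas[-5:]) < 0.2 * np.mean(deltas[:5])


def test_restart_from_steady_state_reproduces_next_beat():
    prot = StimulusProtocol(n_prepace=4)
    solver = SolverOptions(rtol=1e-8, atol=1e-11)
    full = simulate_myocyte("A", prot, solver)
    y, _ = paced_to_steady_state("A", prot, tolerance=np.inf, solver=solver)
    restart = simulate_myocyte("A", StimulusProtocol(n_prepace=0),
                               solver, initial_state=y)
    assert np.max(np.abs(full.vm - restart.vm)) < 0.05


def test_metadata_records_resolved_run(trace_A):
    md = trace_A.metadata
    assert md["protocol"]["n_prepace"] == 25
    assert md["factors"]["f_SRleak"] == 1.0
    assert md["nfev"] > 0
    assert md["stim_onset_ms"] == 0.0
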