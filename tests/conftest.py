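"""Shared fixtures: expensive paced simulations are computed once."""

from __future__ import annotations

import numpy as np
import pytest

from cardioec.biomarkers import extract_report
from cardioec.simulation import (SolverOptions, StimulusProtocol,
                                 simulate_myocyte)


@pytest.fixture(scope="session")
def default_protocol():
    return StimulusProtocol()


@pytest.fixture(scope="session")
def trace_A(default_protocol):
    """Case A (healthy) recorded beat under the default protocol."""
    return simulate_myocyte("A", default_protocol, SolverOptions())


@pytest.fixture(scope="session")
def four_case_panel(default_protocol):
    """Biomarker panels for cases A-D under the default protocol."""
    panel = {}
    for case in "ABCD":
        trace = simulate_myocyte(case, default_protocol, SolverOptions())
        panel[case] = extract_report(trace)
    return panel


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
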