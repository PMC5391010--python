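"""Configuration files, trace/report serialization, and fixture output.

Formats are deliberately plain text: YAML for configuration, CSV with
unit-bearing column names for traces, JSON for reports and resolved-run
sidecars.  Writing then reading reproduces values exactly (floats are
serialized with full round-trip precision).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .biomarkers import ERP_REPOLARIZATION_FRACTION
from .disease import FACTOR_NAMES, ImpactFactors, factors_for_case
from .parameters import (GPB_PARAM_NAMES, GPBParameters, HOParameters,
                         NHSParameters)
from .simulation import SimulationTrace, SolverOptions, StimulusProtocol

TRACE_COLUMNS = ["time_ms", "vm_mV", "ca_i_uM", "tension_kPa"]


class ConfigError(ValueError):
    """Malformed or inconsistent run configuration."""


@dataclass
class RunConfig:
    """Fully-resolved run configuration (model, protocol, solver, outputs,
    mechanics)."""

    case: str | float | None = "A"
    factors: ImpactFactors | None = None
    parameter_overrides: dict = field(default_factory=dict)
    nhs_overrides: dict = field(default_factory=dict)
    protocol: StimulusProtocol = field(default_factory=StimulusProtocol)
    solver: SolverOptions = field(default_factory=SolverOptions)
    erp_repolarization_fraction: float = ERP_REPOLARIZATION_FRACTION
    trace_path: str | None = None
    report_path: str | None = None
    mechanics: HOParameters = field(default_factory=HOParameters)

    def resolve_factors(self) -> ImpactFactors:
        if self.factors is not None:
            return self.factors
        return factors_for_case(self.case)

    def resolve_parameters(self) -> GPBParameters:
        unknown = set(self.parameter_overrides) - set(GPB_PARAM_NAMES)
        if unknown:
            raise ConfigError(f"unknown model parameter(s): {sorted(unknown)}")
        return GPBParameters().replace(**self.parameter_overrides)

    def resolve_nhs(self) -> NHSParameters:
        try:
            return NHSParameters().replace(**self.nhs_overrides)
        except TypeError as exc:
            raise ConfigError(f"unknown myofilament parameter: {exc}") from exc

    def to_dict(self) -> dict:
        return {
            "model": {
                "case": self.case,
                "factors": (self.factors.to_dict()
                            if self.factors is not None else None),
                "parameter_overrides": dict(self.parameter_overrides),
                "nhs_overrides": dict(self.nhs_overrides),
            },
            "protocol": dataclasses.asdict(self.protocol),
            "solver": dataclasses.asdict(self.solver),
            "outputs": {
                "trace_path": self.trace_path,
                "report_path": self.report_path,
                "erp_repolarization_fraction":
                    self.erp_repolarization_fraction,
            },
            "mechanics": self.mechanics.to_dict(),
        }


_SECTION_KEYS = {
    "model": {"case", "factors", "parameter_overrides", "nhs_overrides"},
    "protocol": {"amplitude", "duration", "cycle_length",
                 "n_prepace", "n_record"},
    "solver": {"method", "rtol", "atol", "output_dt"},
    "outputs": {"trace_path", "report_path", "erp_repolarization_fraction"},
    "mechanics": {f.name for f in dataclasses.fields(HOParameters)},
}


def config_from_dict(raw: dict) -> RunConfig:
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    unknown = set(raw) - set(_SECTION_KEYS)
    if unknown:
        raise ConfigError(f"unknown config section(s): {sorted(unknown)}")
    for sec, keys in _SECTION_KEYS.items():
        bad = set(raw.get(sec) or {}) - keys
        if bad:
            raise ConfigError(f"unknown key(s) in [{sec}]: {sorted(bad)}")
    model = raw.get("model") or {}
    factors = model.get("factors")
    if factors is not None:
        factors = ImpactFactors.from_dict(
            {k: float(v) for k, v in factors.items()})
    outputs = raw.get("outputs") or {}
    cfg = RunConfig(
        case=model.get("case", "A" if factors is None else None),
        factors=factors,
        parameter_overrides=dict(model.get("parameter_overrides") or {}),
        nhs_overrides=dict(model.get("nhs_overrides") or {}),
        protocol=StimulusProtocol(**(raw.get("protocol") or {})),
        solver=SolverOptions(**(raw.get("solver") or {})),
        erp_repolarization_fraction=float(outputs.get(
            "erp_repolarization_fraction", ERP_REPOLARIZATION_FRACTION)),
        trace_path=outputs.get("trace_path"),
        report_path=outputs.get("report_path"),
        mechanics=HOParameters(**(raw.get("mechanics") or {})),
    )
    return cfg


def load_config(path) -> RunConfig:
    """Load a YAML run configuration; unknown keys are rejected."""
    text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text) or {}
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f" at line {mark.line + 1}" if mark is not None else ""
        raise ConfigError(f"cannot parse {path}{where}: {exc}") from exc
    try:
        return config_from_dict(raw)
    except (TypeError, KeyError, ValueError) as exc:
        raise ConfigError(f"invalid configuration {path}: {exc}") from exc


def write_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))


def write_trace(trace: SimulationTrace, path) -> None:
    """Write a trace as CSV (columns name their units) plus JSON sidecar
    with the fully-resolved run metadata."""
    path = Path(path)
    df = trace.to_dataframe()
    df.to_csv(path, index=False, float_format="%.17g")
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps(
        {"version": __version__, **trace.metadata}, indent=1))


def read_trace(path) -> SimulationTrace:
    """Read a trace CSV; rejects non-monotone time grids."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TRACE_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise ValueError(f"trace {path} missing column(s) {missing}")
    t = df["time_ms"].to_numpy(dtype=float)
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValueError(f"trace {path}: time_ms must be strictly increasing")
    tension = (df["tension_kPa"].to_numpy(dtype=float)
               if "tension_kPa" in df.columns else np.zeros_like(t))
    meta = {}
    sidecar = Path(path).with_suffix(Path(path).suffix + ".meta.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return SimulationTrace(t=t, vm=df["vm_mV"].to_numpy(dtype=float),
                           ca_i=df["ca_i_uM"].to_numpy(dtype=float),
                           tension=tension, metadata=meta)


def write_report(report, path) -> None:
    """Write a biomarker report (or any mapping) as versioned JSON."""
    data = report.to_dict() if hasattr(report, "to_dict") else dict(report)
    Path(path).write_text(json.dumps(
        {"version": __version__, **data}, indent=1))


def generate_fixtures(outdir, seed: int = 0) -> list[Path]:
    """Write the synthetic waveform fixtures with their ground truth.

    The waveforms are deterministic; ``seed`` only feeds the jittered
    variants used for robustness checks.
    """
    from . import synthetic

    rng = np.random.default_rng(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    t, v, truth = synthetic.triangle_ap()
    # companion transients so the file supports a full biomarker report
    _, ca, _ = synthetic.gaussian_transient(
        baseline=0.1, amplitude=0.9, t_peak_ms=40.0, sigma_ms=25.0,
        total_ms=t[-1], dt_ms=t[1] - t[0])
    _, tension, _ = synthetic.gaussian_transient(
        baseline=0.0, amplitude=10.0, t_peak_ms=120.0, sigma_ms=60.0,
        total_ms=t[-1], dt_ms=t[1] - t[0])
    df = pd.DataFrame({"time_ms": t, "vm_mV": v, "ca_i_uM": ca,
                       "tension_kPa": tension})
    p = outdir / "triangle_ap.csv"
    df.to_csv(p, index=False, float_format="%.17g")
    (outdir / "triangle_ap.truth.json").write_text(
        json.dumps({"version": __version__, **truth}, indent=1))
    written += [p, outdir / "triangle_ap.truth.json"]

    t, x, truth = synthetic.gaussian_transient()
    noisy = x + 1e-6 * rng.standard_normal(x.size)
    df = pd.DataFrame({"time_ms": t, "vm_mV": np.full_like(t, -80.0),
                       "ca_i_uM": x, "tension_kPa": noisy})
    p = outdir / "gaussian_transient.csv"
    df.to_csv(p, index=False, float_format="%.17g")
    (outdir / "gaussian_transient.truth.json").write_text(
        json.dumps({"version": __version__, **truth}, indent=1))
    written += [p, outdir / "gaussian_transient.truth.json"]
    return written
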