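"""Configuration and serialization.

Run configuration is a flat TOML file (key = value with unit comments);
the canonical parameter file shipping with the package is the single
source of defaults, so an empty config yields the canonical model.
Traces and metrics are written as CSV with a ``#``-comment metadata
header and full-precision floats.
"""
from __future__ import annotations

import csv
import io as _io
import tomllib
from dataclasses import asdict, fields
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import AnalysisConfig, RhythmMetrics
from .params import KineticsConstants, ModelParameters
from .simulator import SolverConfig, Trace

__all__ = ["RunConfig", "load_config", "save_config", "canonical_config_path",
           "write_trace", "read_trace", "write_metrics"]

_MODEL_KEYS = {f.name for f in fields(ModelParameters)} - {"kinetics"}
_KIN_KEYS = {f.name for f in fields(KineticsConstants)}
_SOLVER_KEYS = {f.name for f in fields(SolverConfig)}
_ANALYSIS_KEYS = {f.name for f in fields(AnalysisConfig)}
_PROTOCOL_KEYS = {"transient", "record", "sample_dt", "ncell",
                  "ic_vm1", "ic_vm2", "ic_nai"}


class ConfigError(ValueError):
    pass


class RunConfig:
    """Validated parameters + solver + protocol + analysis blocks."""

    def __init__(self, params: ModelParameters | None = None,
                 solver: SolverConfig | None = None,
                 analysis: AnalysisConfig | None = None,
                 protocol: dict | None = None):
        self.params = params or ModelParameters()
        self.solver = solver or SolverConfig()
        self.analysis = analysis or AnalysisConfig()
        self.protocol = {"transient": 5000.0, "record": 2000.0,
                         "sample_dt": 2e-4, "ncell": 2,
                         "ic_vm1": -50.0, "ic_vm2": -60.0, "ic_nai": 15.0}
        if protocol:
            self.protocol.update(protocol)

    def __eq__(self, other):
        return (isinstance(other, RunConfig)
                and self.params == other.params
                and self.solver == other.solver
                and self.analysis == other.analysis
                and self.protocol == other.protocol)


def _build(doc: dict) -> RunConfig:
    model = dict(doc.pop("model", {}))
    solver = dict(doc.pop("solver", {}))
    analysis = dict(doc.pop("analysis", {}))
    protocol = dict(doc.pop("protocol", {}))
    if doc:
        raise ConfigError(f"unknown config sections: {sorted(doc)}")
    bad = set(model) - _MODEL_KEYS - _KIN_KEYS
    if bad:
        raise ConfigError(f"unknown model keys: {sorted(bad)}")
    bad = set(solver) - _SOLVER_KEYS
    if bad:
        raise ConfigError(f"unknown solver keys: {sorted(bad)}")
    bad = set(analysis) - _ANALYSIS_KEYS
    if bad:
        raise ConfigError(f"unknown analysis keys: {sorted(bad)}")
    bad = set(protocol) - _PROTOCOL_KEYS
    if bad:
        raise ConfigError(f"unknown protocol keys: {sorted(bad)}")
    try:
        params = ModelParameters().evolve(**model)
    except ValueError as e:
        raise ConfigError(str(e)) from e
    return RunConfig(params=params,
                     solver=SolverConfig(**solver),
                     analysis=AnalysisConfig(**analysis),
                     protocol=protocol)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Parse and validate a TOML config; omitted keys fall back to the
    canonical defaults.  ``None`` loads the shipped canonical file."""
    if path is None:
        text = (resources.files("hcosim") / "data/canonical.toml").read_text()
    else:
        text = Path(path).read_text()
    try:
        doc = tomllib.loads(text)
    except tomllib.TOMLDecodeError as e:
        raise ConfigError(f"unparseable config: {e}") from e
    return _build(doc)


def canonical_config_path() -> Path:
    with resources.as_file(resources.files("hcosim") / "data/canonical.toml") as p:
        return p


def _fmt(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, float):
        return repr(v)
    if isinstance(v, str):
        return f'"{v}"'
    return str(v)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Serialize so that parse -> serialize -> parse round-trips."""
    lines = ["# hcosim run configuration", "", "[model]"]
    defaults = ModelParameters()
    for f in fields(ModelParameters):
        if f.name == "kinetics":
            continue
        lines.append(f"{f.name} = {_fmt(getattr(cfg.params, f.name))}")
    for f in fields(KineticsConstants):
        lines.append(f"{f.name} = {_fmt(getattr(cfg.params.kinetics, f.name))}")
    lines += ["", "[solver]"]
    for f in fields(SolverConfig):
        lines.append(f"{f.name} = {_fmt(getattr(cfg.solver, f.name))}")
    lines += ["", "[analysis]"]
    for f in fields(AnalysisConfig):
        lines.append(f"{f.name} = {_fmt(getattr(cfg.analysis, f.name))}")
    lines += ["", "[protocol]"]
    for k in sorted(cfg.protocol):
        lines.append(f"{k} = {_fmt(cfg.protocol[k])}")
    Path(path).write_text("\n".join(lines) + "\n")
    del defaults


def write_trace(path: str | Path, trace: Trace, chunk: int = 1_000_000) -> None:
    """Stream a trace to CSV: comment header, then time_s plus channels."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write(f"# hcosim trace; sample_dt={trace.sample_dt!r}; "
                 f"t0={trace.t0!r}\n")
        meta = trace.meta
        if "transient" in meta:
            fh.write(f"# transient={meta['transient']!r}; "
                     f"record={meta.get('record')!r}; "
                     f"ncell={meta.get('ncell')!r}\n")
        w = csv.writer(fh)
        w.writerow(["time_s"] + list(trace.channels))
        times = trace.times
        n = trace.data.shape[0]
        for start in range(0, n, chunk):
            stop = min(start + chunk, n)
            block = np.column_stack([times[start:stop],
                                     trace.data[start:stop]])
            buf = _io.StringIO()
            np.savetxt(buf, block, delimiter=",", fmt="%.17g")
            fh.write(buf.getvalue())


def read_trace(path: str | Path) -> Trace:
    path = Path(path)
    sample_dt = None
    t0 = 0.0
    with path.open() as fh:
        header_lines = 0
        for line in fh:
            if line.startswith("#"):
                header_lines += 1
                for part in line[1:].split(";"):
                    part = part.strip()
                    if part.startswith("sample_dt="):
                        sample_dt = float(part.split("=", 1)[1])
                    elif part.startswith("t0="):
                        t0 = float(part.split("=", 1)[1])
            else:
                break
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    channels = tuple(c for c in df.columns if c != "time_s")
    if sample_dt is None:
        tt = df["time_s"].to_numpy()
        sample_dt = float(tt[1] - tt[0]) if len(tt) > 1 else 1.0
    return Trace(t0=t0, sample_dt=sample_dt, channels=channels,
                 data=df[list(channels)].to_numpy(),
                 meta={"source": str(path)})


def write_metrics(path: str | Path, metrics: RhythmMetrics) -> None:
    """One row per burst and per episode plus a summary block."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write("# hcosim rhythm metrics\n")
        w = csv.writer(fh)
        w.writerow(["kind", "index", "onset_s", "offset_s", "duration_s",
                    "n_items"])
        for i, b in enumerate(metrics.bursts):
            w.writerow(["burst", i, repr(b.onset), repr(b.offset),
                        repr(b.duration), b.n_spikes])
        for i, e in enumerate(metrics.episodes):
            w.writerow(["episode", i, repr(e.onset), repr(e.offset),
                        repr(e.duration), len(e.bursts)])
        fh.write("# summary\n")
        w.writerow(["series", "mean", "sd", "cv", "n", "", ""][:6])
        for name, s in metrics.summary.items():
            if isinstance(s, dict):
                w.writerow([name, repr(s["mean"]), repr(s["sd"]),
                            repr(s["cv"]), s["n"], ""])
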