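"""Scripted protocols: parameter sweeps, regime-boundary bisection,
bistability probing, the monensin comparison and the bifurcation-diagram
overlay.

These reproduce the model studies around the canonical parameter set:
one parameter is varied at a time (h-current conductance g_h, maximal
pump current I_PumpMax, the monensin rate constant M, or the tau_h scale
factor), each value is simulated past its transient, the regime is
classified (silence / episodic / continuous) and the rhythm metrics are
tabulated against the parameter.  Regime boundaries are located by
bisection on the classification, with a shortened transient per probe
and a confirmation run at the full transient at the final midpoint.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .analysis import (AnalysisConfig, RegimeLabel, analyze_trace,
                       classify_regime)
from .model_core import HCOState, steady_state_cell
from .params import ModelParameters
from .reduced import BifurcationDiagram, decouple
from .simulator import Trace, integrate

__all__ = ["SweepProtocol", "SweepResult", "parameter_sweep",
           "regime_boundary", "bistability_probe", "monensin_experiment",
           "bifurcation_overlay"]

SWEEPABLE = ("gh", "IPumpMax", "M", "tau_h_scale", "gSyn")


@dataclass(frozen=True)
class SweepProtocol:
    """Simulation lengths and thresholds shared by sweep/boundary runs."""

    transient: float = 5000.0
    record: float = 2000.0
    record_continuous: float = 200.0
    boundary_transient: float = 1000.0
    boundary_record: float = 400.0
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)


@dataclass
class SweepResult:
    parameter: str
    grid: np.ndarray
    labels: list[RegimeLabel]
    table: pd.DataFrame          # one row per grid value with metric summaries
    failed: list[float] = field(default_factory=list)


def _metric_row(metrics) -> dict:
    s = metrics.summary
    row = {}
    for name in ("EP", "ED", "IEI", "BP", "BD", "IBI"):
        row[f"{name}_mean"] = s[name]["mean"]
        row[f"{name}_sd"] = s[name]["sd"]
        row[f"{name}_cv"] = s[name]["cv"]
        row[f"{name}_n"] = s[name]["n"]
    return row


def _simulate_point(params: ModelParameters, protocol: SweepProtocol,
                    transient: float | None = None,
                    record: float | None = None,
                    init: HCOState | None = None) -> Trace:
    return integrate(params,
                     init=init,
                     transient=protocol.transient if transient is None else transient,
                     record=protocol.record if record is None else record)


def parameter_sweep(params: ModelParameters, name: str,
                    grid, protocol: SweepProtocol | None = None,
                    transient: float | None = None,
                    record: float | None = None) -> SweepResult:
    """Classify and measure the rhythm at each value of one parameter."""
    if name not in SWEEPABLE:
        raise ValueError(f"unknown sweep parameter {name!r}; one of {SWEEPABLE}")
    protocol = protocol or SweepProtocol()
    grid = np.sort(np.asarray(grid, dtype=float))
    labels, rows, failed = [], [], []
    for value in grid:
        p = params.evolve(**{name: float(value)})
        try:
            tr = _simulate_point(p, protocol, transient, record)
            label = classify_regime(tr, config=protocol.analysis)
            metrics = analyze_trace(tr, config=protocol.analysis)
        except Exception:
            failed.append(float(value))
            labels.append(RegimeLabel.MIXED)
            rows.append({})
            continue
        labels.append(label)
        row = _metric_row(metrics)
        row["label"] = label.value
        # duty cycle of continuous bursting ("plateau-like" above ~0.7)
        if label is RegimeLabel.CONTINUOUS and len(metrics.BD) and len(metrics.BP):
            row["duty_cycle"] = float(np.mean(metrics.BD) / np.mean(metrics.BP))
        rows.append(row)
    table = pd.DataFrame(rows, index=pd.Index(grid, name=name))
    return SweepResult(parameter=name, grid=grid, labels=labels,
                       table=table, failed=failed)


def _classify_at(params: ModelParameters, name: str, value: float,
                 protocol: SweepProtocol, transient: float, record: float,
                 init: HCOState | None = None) -> RegimeLabel:
    p = params.evolve(**{name: float(value)})
    tr = integrate(p, init=init, transient=transient, record=record)
    label = classify_regime(tr, config=protocol.analysis)
    if label is RegimeLabel.MIXED:
        # near-boundary ambiguity: extend the window once before labelling
        tr = integrate(p, init=init, transient=transient, record=2 * record)
        label = classify_regime(tr, config=protocol.analysis)
    return label


def regime_boundary(params: ModelParameters, name: str,
                    lo: float, hi: float,
                    from_label: RegimeLabel, to_label: RegimeLabel,
                    resolution: float = 1e-3,
                    protocol: SweepProtocol | None = None,
                    confirm: bool = True) -> dict:
    """Bisect a regime transition of one parameter.

    ``lo`` must classify as ``from_label`` and ``hi`` as ``to_label``
    (the bracket may be given in either numeric order).  Probes use the
    shortened boundary transient; the final midpoint is confirmed at the
    full transient, and a disagreeing confirmation widens the reported
    bracket instead of forcing a value.
    """
    protocol = protocol or SweepProtocol()
    tr_t, tr_r = protocol.boundary_transient, protocol.boundary_record

    lab_lo = _classify_at(params, name, lo, protocol, tr_t, tr_r)
    lab_hi = _classify_at(params, name, hi, protocol, tr_t, tr_r)
    if lab_lo != from_label or lab_hi != to_label:
        raise ValueError(
            f"no bracket: {name}={lo} -> {lab_lo.value}, "
            f"{name}={hi} -> {lab_hi.value} "
            f"(wanted {from_label.value} -> {to_label.value})")
    a, b = lo, hi
    while abs(b - a) > resolution:
        mid = 0.5 * (a + b)
        lab = _classify_at(params, name, mid, protocol, tr_t, tr_r)
        if lab == from_label:
            a = mid
        else:
            b = mid
    mid = 0.5 * (a + b)
    result = {"parameter": name, "bracket": (min(a, b), max(a, b)),
              "boundary": mid, "from": from_label.value, "to": to_label.value,
              "resolution": resolution}
    if confirm:
        lab = _classify_at(params, name, mid, protocol,
                           protocol.transient, tr_r)
        result["confirmed"] = lab.value in (from_label.value, to_label.value)
    return result


def bistability_probe(params: ModelParameters,
                      ic_rest: HCOState | None = None,
                      ic_burst: HCOState | None = None,
                      transient: float = 1000.0,
                      record: float = 400.0,
                      config: AnalysisConfig | None = None) -> dict:
    """Run the same parameters from a rest-like and a bursting-like
    initial condition; bistable iff the labels differ."""
    cfg = config or AnalysisConfig()
    if ic_rest is None:
        ic_rest = HCOState(steady_state_cell(-65.0, params, nai=26.0),
                           steady_state_cell(-66.0, params, nai=26.0))
    if ic_burst is None:
        ic_burst = HCOState(steady_state_cell(-45.0, params, nai=18.0),
                            steady_state_cell(-60.0, params, nai=18.0))
    labels = {}
    for tag, ic in (("rest", ic_rest), ("burst", ic_burst)):
        tr = integrate(params, init=ic, transient=transient, record=record)
        labels[tag] = classify_regime(tr, config=cfg)
    return {"labels": {k: v.value for k, v in labels.items()},
            "bistable": labels["rest"] != labels["burst"]}


def monensin_experiment(params: ModelParameters, M: float = 0.002,
                        transient: float = 5000.0, record: float = 2000.0,
                        config: AnalysisConfig | None = None) -> dict:
    """Paired canonical runs with and without the monensin Na+ influx.

    Monensin (a Na+/H+ antiporter) is modelled as a first-order Na+
    influx M ([Na]_e - [Na]_i), which raises intracellular Na+ and hence
    pump activity.  Returns both metric sets and their deltas.
    """
    if M < 0:
        raise ValueError("monensin rate constant must be >= 0")
    cfg = config or AnalysisConfig()
    out = {}
    for tag, m in (("control", 0.0), ("monensin", M)):
        tr = integrate(params.evolve(M=m), transient=transient, record=record)
        out[tag] = analyze_trace(tr, config=cfg).summary
    deltas = {}
    for name in ("EP", "ED", "IEI"):
        c, t = out["control"][name], out["monensin"][name]
        deltas[name] = {"control": c["mean"], "monensin": t["mean"],
                        "delta": t["mean"] - c["mean"],
                        "within_sd": abs(t["mean"] - c["mean"]) <= c["sd"]}
    deltas["EP_CV"] = {"control": out["control"]["EP"]["cv"],
                       "monensin": out["monensin"]["EP"]["cv"]}
    return {"control": out["control"], "monensin": out["monensin"],
            "comparison": deltas}


def bifurcation_overlay(trace: Trace, diagram: BifurcationDiagram,
                        config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Pair each intra-episode burst cycle of a full single-cell trace
    with the reduced-model branch at its mean m_h.

    For each burst cycle the mean m_h over the cycle is paired with its
    BD and IBI, and residuals against the constant-m_h diagram's
    mean_bd/mean_ibi at the nearest grid point are reported.  Cycles
    whose m_h falls outside the diagram's grid are flagged rather than
    extrapolated.
    """
    if not trace.has_channel("mh1"):
        raise ValueError("trace must record the m_h channel for the overlay")
    cfg = config or AnalysisConfig(burst_isi_gap=0.3)
    metrics = analyze_trace(trace, config=cfg)
    mh = trace["mh1"]
    t = trace.times
    grid = diagram.mh_grid
    pad = max(1e-9, 0.5 * (np.max(np.diff(grid)) if len(grid) > 1 else 0.01))
    rows = []
    for ep in metrics.episodes:
        bs = ep.bursts
        for b1, b2 in zip(bs, bs[1:]):
            sel = (t >= b1.onset) & (t < b2.onset)
            if not sel.any():
                continue
            mh_mean = float(mh[sel].mean())
            row = {"mh": mh_mean, "BD": b1.duration,
                   "IBI": b2.onset - b1.offset}
            if mh_mean < grid.min() - pad or mh_mean > grid.max() + pad:
                row["in_range"] = False
            else:
                pt = diagram.point(mh_mean)
                row["in_range"] = True
                row["bd_reduced"] = pt.mean_bd
                row["ibi_reduced"] = pt.mean_ibi
                row["bd_residual"] = row["BD"] - pt.mean_bd
                row["ibi_residual"] = row["IBI"] - pt.mean_ibi
            rows.append(row)
    return pd.DataFrame(rows)
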