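"""Reduced models: the decoupled cell, tau_h scaling, and the
constant-m_h fast subsystem with its bifurcation analysis.

Freezing the slow h-current activation m_h as a parameter exposes the
fast subsystem underlying episodic bursting.  Scanned over m_h it shows
two regimes only — a stationary rest state and a continuous bursting
state — with a window of coexistence; the rest state loses stability at
an Andronov-Hopf bifurcation located here both by eigenvalues of the
numerically differenced Jacobian along the continued equilibrium branch
and, independently, by two-initial-condition simulation.  The full
model's episodic rhythm is a slow hysteresis loop across this diagram
(elliptic bursting), which is why episodes disappear when m_h is held
constant.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import fsolve

from .analysis import AnalysisConfig, RegimeLabel, analyze_trace, classify_regime
from .model_core import steady_state_cell
from .params import ModelParameters
from .simulator import SolverConfig, Trace, integrate

__all__ = ["decouple", "ReducedPoint", "BifurcationDiagram",
           "scan_constant_mh", "rest_state_stability", "find_hopf",
           "scaled_tau_run"]


def decouple(params: ModelParameters) -> ModelParameters:
    """Single-cell parameters: remove the synapse (idempotent)."""
    return params.evolve(gSyn=0.0)


# state layout of the reduced (constant-m_h) equilibrium problem: the
# 11-state cell minus m_h -> 10 unknowns
_RED_IDX = [0, 1, 2, 3, 4, 5, 6, 7, 9, 10]


def _reduced_rhs(z: np.ndarray, mh: float, params: ModelParameters) -> np.ndarray:
    from .model_core import NeuronState, single_cell_derivatives
    y = np.empty(11)
    y[_RED_IDX] = z
    y[8] = mh
    d = single_cell_derivatives(NeuronState.from_array(y), params, mh_const=mh)
    return d[_RED_IDX]


@dataclass
class ReducedPoint:
    """One grid point of the constant-m_h scan."""

    mh: float
    regime: str                    # 'rest' | 'bursting' | 'coexistent' | 'failed'
    rest_vm: float = np.nan
    rest_stable: bool | None = None
    eig_real_max: float = np.nan
    vmax: float = np.nan           # bursting-orbit extremes
    vmin: float = np.nan
    mean_bd: float = np.nan
    mean_ibi: float = np.nan


@dataclass
class BifurcationDiagram:
    points: list[ReducedPoint] = field(default_factory=list)
    hopf_mh: float | None = None           # eigenvalue-based Hopf location
    rest_boundary_mh: float | None = None  # simulation-based loss of rest
    burst_boundary_mh: float | None = None # lowest m_h with a bursting attractor

    @property
    def mh_grid(self) -> np.ndarray:
        return np.array([p.mh for p in self.points])

    def point(self, mh: float) -> ReducedPoint:
        g = self.mh_grid
        return self.points[int(np.argmin(np.abs(g - mh)))]


def rest_state_stability(params: ModelParameters, mh: float,
                         guess: np.ndarray | None = None) -> dict:
    """Equilibrium of the constant-m_h cell and its local stability.

    The equilibrium is found by root solving; the Jacobian is built by
    central differences with per-variable steps (1e-6 relative, 1e-9
    absolute floor).  Returns the equilibrium state, the eigenvalue real
    parts, and the leading complex pair's real part (the quantity whose
    zero crossing locates the Andronov-Hopf bifurcation).
    """
    params = decouple(params)
    if guess is None:
        y = steady_state_cell(-57.0, params, nai=23.0, mh=mh).to_array()
        guess = y[_RED_IDX]
    z, info, ier, _ = fsolve(_reduced_rhs, guess, args=(mh, params),
                             xtol=1e-13, full_output=True)
    resid = float(np.max(np.abs(_reduced_rhs(z, mh, params))))
    if ier != 1 and resid > 1e-8:
        raise RuntimeError(f"no equilibrium found at m_h={mh} (resid {resid:.2e})")
    n = len(z)
    J = np.empty((n, n))
    for j in range(n):
        h = 1e-6 * max(abs(z[j]), 1e-3)
        zp, zm = z.copy(), z.copy()
        zp[j] += h
        zm[j] -= h
        J[:, j] = (_reduced_rhs(zp, mh, params) - _reduced_rhs(zm, mh, params)) / (2 * h)
    eig = np.linalg.eigvals(J)
    cplx = eig[np.abs(eig.imag) > 1.0]
    lead_cplx = float(cplx.real.max()) if len(cplx) else np.nan
    return {
        "state": z, "residual": resid, "eigenvalues": eig,
        "eig_real_max": float(eig.real.max()),
        "lead_complex_real": lead_cplx,
        "stable": bool(eig.real.max() < 0),
        "hopf_flag": bool(abs(lead_cplx) < 1e-2) if np.isfinite(lead_cplx) else False,
        "rest_vm": float(z[0]),
    }


def find_hopf(params: ModelParameters, lo: float = 0.55, hi: float = 1.05,
              tol: float = 1e-4) -> float | None:
    """Bisect the leading complex pair's real part over m_h."""
    def f(mh):
        return rest_state_stability(params, mh)["lead_complex_real"]
    flo, fhi = f(lo), f(hi)
    if not (np.isfinite(flo) and np.isfinite(fhi)) or flo * fhi > 0:
        return None
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if not np.isfinite(fm):
            return None
        if flo * fm <= 0:
            hi, fhi = mid, fm
        else:
            lo, flo = mid, fm
    return 0.5 * (lo + hi)


def _classify_point(params: ModelParameters, mh: float,
                    transient: float, record: float,
                    config: AnalysisConfig) -> dict:
    """Simulate the reduced cell from a rest-like and a bursting-like IC."""
    out = {}
    solver = SolverConfig()
    for name, (vm, nai) in {"rest": (-58.0, 24.0), "burst": (-48.0, 21.0)}.items():
        ic = steady_state_cell(vm, params, nai=nai, mh=mh)
        tr = integrate(params, init=ic, transient=transient, record=record,
                       solver=solver, mh_const=mh, ncell=1)
        label = classify_regime(tr, config=config)
        out[name] = (label, tr)
    return out


def scan_constant_mh(params: ModelParameters,
                     grid: np.ndarray | None = None,
                     transient: float = 150.0,
                     record: float = 60.0,
                     refine_to: float = 0.001,
                     config: AnalysisConfig | None = None,
                     compute_stability: bool = True) -> BifurcationDiagram:
    """Two-initial-condition scan of the constant-m_h model.

    Each grid point is simulated from a rest-like and a bursting-like
    initial condition and labelled rest / bursting / coexistent; detected
    regime transitions are refined by bisection to ``refine_to``.  The
    intracellular Na+ balance is part of the fast subsystem here, and is
    slow, hence the long per-point transient.
    """
    params = decouple(params)
    cfg = config or AnalysisConfig(burst_isi_gap=0.3, episode_gap=4.0,
                                   min_bursts_per_episode=1)
    if grid is None:
        grid = np.arange(0.70, 1.0 + 1e-9, 0.005)
    diagram = BifurcationDiagram()

    def label_point(mh: float) -> ReducedPoint:
        try:
            res = _classify_point(params, mh, transient, record, cfg)
        except Exception:
            return ReducedPoint(mh=mh, regime="failed")
        spiking = {k: lab is not RegimeLabel.SILENCE for k, (lab, _) in res.items()}
        if not any(spiking.values()):
            regime = "rest"
        elif all(spiking.values()):
            regime = "bursting"
        else:
            regime = "coexistent"
        pt = ReducedPoint(mh=mh, regime=regime)
        # bursting-branch waveform statistics from whichever IC spikes
        for _, (lab, tr) in res.items():
            if lab is not RegimeLabel.SILENCE:
                v = tr["Vm1"]
                pt.vmax, pt.vmin = float(v.max()), float(v.min())
                m = analyze_trace(tr, config=AnalysisConfig(
                    burst_isi_gap=0.1, min_spikes_per_burst=1,
                    min_bursts_per_episode=1))
                if len(m.BD):
                    pt.mean_bd = float(np.mean(m.BD))
                if len(m.IBI):
                    pt.mean_ibi = float(np.mean(m.IBI))
                break
        return pt

    for mh in grid:
        pt = label_point(float(mh))
        if compute_stability and pt.regime != "failed":
            try:
                st = rest_state_stability(params, float(mh))
                pt.rest_vm = st["rest_vm"]
                pt.rest_stable = st["stable"]
                pt.eig_real_max = st["eig_real_max"]
            except RuntimeError:
                pass
        diagram.points.append(pt)

    # simulation-based boundaries, refined by bisection
    def bisect(lo, hi, pred, steps=None):
        while hi - lo > refine_to:
            mid = 0.5 * (lo + hi)
            if pred(label_point(mid)):
                hi = mid
            else:
                lo = mid
        return 0.5 * (lo + hi)

    pts = diagram.points
    for a, b in zip(pts, pts[1:]):
        if a.regime == "rest" and b.regime in ("coexistent", "bursting"):
            diagram.burst_boundary_mh = bisect(
                a.mh, b.mh, lambda p: p.regime != "rest")
            break
    for a, b in zip(pts, pts[1:]):
        if a.regime in ("rest", "coexistent") and b.regime == "bursting":
            diagram.rest_boundary_mh = bisect(
                a.mh, b.mh, lambda p: p.regime == "bursting")
            break
    if compute_stability:
        diagram.hopf_mh = find_hopf(params)
    return diagram


def scaled_tau_run(params: ModelParameters, scale: float = 50.0,
                   transient: float = 5000.0, record: float = 2000.0,
                   **kwargs) -> Trace:
    """Single-cell run with tau_h multiplied by ``scale``.

    Slowing the leading slow variable stretches episode duration and the
    interepisode interval while leaving intra-episode burst structure
    nearly unchanged; overlaid on the constant-m_h diagram the slowed
    trajectory hugs the fast subsystem's attractors.
    """
    if scale < 1:
        raise ValueError("tau_h scale must be >= 1")
    p = decouple(params).evolve(tau_h_scale=scale)
    return integrate(p, ncell=1, transient=transient, record=record, **kwargs)
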