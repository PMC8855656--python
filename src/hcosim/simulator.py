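"""Numerical integration of the HCO / single-cell system.

The model is integrated with an adaptive embedded explicit Runge-Kutta
(Dormand-Prince 5(4), the highest-order embedded pair available in the
compiled kernel); tolerances default to abs 1e-8 / rel 1e-9.  A long
transient (default 5,000 s) is discarded before the recorded window so
every simulation is analysed in its stable regime, and the recorded
window is resampled onto a uniform grid (default 0.2 ms, 5 kHz) suitable
for spike detection.

The model is fully deterministic: two runs with identical configuration
produce identical traces.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import _kernels
from .model_core import HCOState, NeuronState, steady_state_cell, STATE_NAMES
from .params import ModelParameters

__all__ = ["SolverConfig", "Trace", "IntegrationError",
           "integrate", "integrate_single", "resample",
           "default_hco_initial_state", "default_cell_initial_state"]


class IntegrationError(RuntimeError):
    """Raised when the adaptive solver fails; carries the last valid time."""

    def __init__(self, message: str, t_last: float):
        super().__init__(f"{message} (last valid time {t_last:.6g} s)")
        self.t_last = t_last


@dataclass(frozen=True)
class SolverConfig:
    """Adaptive RK settings (tolerances as in the reference protocol)."""

    abs_tol: float = 1e-8
    rel_tol: float = 1e-9
    initial_step: float = 1e-8
    max_step: float = 1.0
    method: str = "dopri5(4)"

    def __post_init__(self):
        if self.abs_tol <= 0 or self.rel_tol <= 0 or self.initial_step <= 0:
            raise ValueError("solver tolerances and initial step must be > 0")


@dataclass
class Trace:
    """Uniformly sampled multivariate time series from one simulation.

    ``data`` has one column per entry of ``channels``; the time of row i
    is ``t0 + i * sample_dt``.  ``meta`` records everything needed to
    reproduce the run.
    """

    t0: float
    sample_dt: float
    channels: tuple[str, ...]
    data: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.data.shape[0]) * self.sample_dt

    @property
    def duration(self) -> float:
        return (self.data.shape[0] - 1) * self.sample_dt

    def __getitem__(self, channel: str) -> np.ndarray:
        return self.data[:, self.channels.index(channel)]

    def has_channel(self, channel: str) -> bool:
        return channel in self.channels


_CELL1 = tuple(f"{n}1" for n in STATE_NAMES)
_CELL2 = tuple(f"{n}2" for n in STATE_NAMES)
DEFAULT_CHANNELS = ("Vm1", "Vm2", "Nai1", "Nai2", "mh1", "mh2")
DEFAULT_CHANNELS_SINGLE = ("Vm1", "Nai1", "mh1")


def _channel_indices(channels: Sequence[str], ncell: int) -> np.ndarray:
    names = _CELL1 + (_CELL2 if ncell == 2 else ())
    idx = []
    for ch in channels:
        if ch not in names:
            raise ValueError(f"unknown channel {ch!r}; available: {names}")
        idx.append(names.index(ch))
    return np.asarray(idx, dtype=np.int64)


def default_cell_initial_state(params: ModelParameters, vm: float = -50.0,
                               nai: float = 15.0) -> NeuronState:
    return steady_state_cell(vm, params, nai=nai)


def default_hco_initial_state(params: ModelParameters) -> HCOState:
    """Canonical asymmetric initial condition.

    The HCO is symmetric, so a symmetric start would remain on the
    symmetric manifold forever in exact arithmetic; the two cells are
    therefore seeded at -50 and -60 mV (gates at steady state, Nai 15 mM).
    """
    return HCOState(steady_state_cell(-50.0, params, nai=15.0),
                    steady_state_cell(-60.0, params, nai=15.0))


def _run(y0: np.ndarray, pvec: np.ndarray, ncell: int, t0: float, t1: float,
         sample_dt: float, solver: SolverConfig, rec_idx: np.ndarray):
    out, yf, t_reached, status, nsteps = _kernels.integrate_adaptive(
        y0, pvec, ncell, t0, t1, sample_dt,
        solver.abs_tol, solver.rel_tol, solver.initial_step, solver.max_step,
        rec_idx)
    if status != 0:
        raise IntegrationError("adaptive step size underflow", t_reached)
    return out, yf, nsteps


def integrate(params: ModelParameters,
              init: HCOState | NeuronState | None = None,
              transient: float = 5000.0,
              record: float = 2000.0,
              solver: SolverConfig | None = None,
              sample_dt: float = 2e-4,
              channels: Sequence[str] | None = None,
              ncell: int = 2,
              mh_const: float | None = None) -> Trace:
    """Integrate the model and return the post-transient window.

    The transient is integrated with sparse sampling and discarded; only
    the final ``record`` seconds are returned, densely sampled every
    ``sample_dt``.  With ``ncell=1`` (or a ``NeuronState`` initial
    condition) the decoupled single cell is simulated.  ``mh_const``
    freezes the h-current activation (the reduced constant-m_h model).
    """
    if transient < 0 or record <= 0:
        raise ValueError("transient must be >= 0 and record > 0")
    if sample_dt > 1e-3:
        raise ValueError("sample_dt must be <= 1 ms to resolve spikes")
    solver = solver or SolverConfig()
    if isinstance(init, NeuronState):
        ncell = 1
    if init is None:
        init = (default_hco_initial_state(params) if ncell == 2
                else default_cell_initial_state(params))
    y0 = init.to_array()
    if ncell == 1 and y0.shape[0] != _kernels.NSTATE:
        raise ValueError("single-cell run needs an 11-state initial condition")
    pvec = params.to_vector(-1.0 if mh_const is None else float(mh_const))
    if channels is None:
        channels = DEFAULT_CHANNELS if ncell == 2 else DEFAULT_CHANNELS_SINGLE
    channels = tuple(channels)
    rec_idx = _channel_indices(channels, ncell)
    y = y0
    if transient > 0:
        # sparse sampling during the transient; only the end state is kept
        _, y, _ = _run(y, pvec, ncell, 0.0, transient, transient / 4.0,
                       solver, np.asarray([0], dtype=np.int64))
    data, y_end, nsteps = _run(y, pvec, ncell, 0.0, record, sample_dt,
                               solver, rec_idx)
    meta = {
        "params": params, "solver": solver, "transient": transient,
        "record": record, "ncell": ncell, "mh_const": mh_const,
        "initial_state": y0, "final_state": y_end, "n_steps": nsteps,
        "deterministic": True,
    }
    return Trace(t0=0.0, sample_dt=sample_dt, channels=channels,
                 data=data, meta=meta)


def integrate_single(params: ModelParameters,
                     init: NeuronState | None = None, **kwargs) -> Trace:
    """Decoupled single-cell convenience wrapper around :func:`integrate`."""
    return integrate(params, init=init, ncell=1, **kwargs)


def resample(trace: Trace, new_dt: float) -> Trace:
    """Linear-interpolation downsampling onto a coarser uniform grid."""
    if new_dt < trace.sample_dt - 1e-15:
        raise ValueError("upsampling refused: new_dt below native sample_dt")
    if abs(new_dt - trace.sample_dt) < 1e-15:
        return replace(trace, data=trace.data.copy())
    t_new = np.arange(trace.t0, trace.t0 + trace.duration + 1e-12, new_dt)
    t_new = t_new[t_new <= trace.t0 + trace.duration + 1e-12]
    data = np.column_stack([
        np.interp(t_new, trace.times, trace.data[:, j])
        for j in range(trace.data.shape[1])])
    return Trace(t0=trace.t0, sample_dt=new_dt, channels=trace.channels,
                 data=data, meta={**trace.meta, "resampled_from": trace.sample_dt})


def integrate_rk4_oracle(params: ModelParameters, init, dt: float = 1e-5,
                         duration: float = 5.0, sample_dt: float = 2e-4,
                         channels: Sequence[str] | None = None,
                         mh_const: float | None = None) -> Trace:
    """Fixed-step RK4 reference integration (solver cross-check only)."""
    ncell = 1 if isinstance(init, NeuronState) else 2
    y0 = init.to_array()
    pvec = params.to_vector(-1.0 if mh_const is None else float(mh_const))
    if channels is None:
        channels = DEFAULT_CHANNELS if ncell == 2 else DEFAULT_CHANNELS_SINGLE
    channels = tuple(channels)
    rec_idx = _channel_indices(channels, ncell)
    data, y_end = _kernels.integrate_rk4(y0, pvec, ncell, 0.0, duration, dt,
                                         sample_dt, rec_idx)
    return Trace(t0=0.0, sample_dt=sample_dt, channels=channels, data=data,
                 meta={"params": params, "method": "rk4", "dt": dt,
                       "final_state": y_end})
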