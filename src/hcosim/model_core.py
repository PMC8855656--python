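"""Pure reference implementation of the HCO vector field.

These functions spell out the model equations one current at a time, in
plain NumPy, and are the ground truth the compiled kernels in
:mod:`hcosim._kernels` are tested against.  They are convenient for
inspecting current decompositions (``membrane_currents``) and for root
finding / Jacobian work in :mod:`hcosim.reduced`; long simulations go
through :mod:`hcosim.simulator`, which uses the compiled path.

Sign convention: all ionic currents are positive-outward and the current
balance carries a leading minus,

    C dV/dt = -(I_NaF + I_NaP + I_KDR + I_KA + I_h-Na + I_h-K + I_CaS
                + I_L-Na + I_L-K + I_Pump + I_Syn).

Intracellular Na+ follows

    d[Na]_i/dt = M ([Na]_e - [Na]_i)
                 - alpha (I_h-Na + I_L-Na + I_NaF + I_NaP + 3 I_Pump)

with the factor 3 the pump's Na stoichiometry per translocated net charge.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .params import ModelParameters

__all__ = [
    "NeuronState", "HCOState", "CurrentBreakdown",
    "gating_steady_state", "mh_steady_state", "mh_time_constant",
    "gating_time_constants", "reversal_potentials", "leak_split",
    "pump_current", "membrane_currents", "state_derivatives",
    "steady_state_cell", "STATE_NAMES",
]

STATE_NAMES = ("Vm", "hNaF", "mNaP", "hNaP", "mKDR", "hKA",
               "mCaS", "hCaS", "mh", "mSyn", "Nai")


@dataclass
class NeuronState:
    """State of one cell: potential, gating fractions and internal Na+."""

    Vm: float
    hNaF: float
    mNaP: float
    hNaP: float
    mKDR: float
    hKA: float
    mCaS: float
    hCaS: float
    mh: float
    mSyn: float
    Nai: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, a) -> "NeuronState":
        return cls(*map(float, a))

    def validate(self) -> None:
        for n in STATE_NAMES[1:-1]:
            v = getattr(self, n)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"gating fraction {n}={v} outside [0, 1]")
        if self.Nai <= 0:
            raise ValueError("Nai must be > 0")


@dataclass
class HCOState:
    """Two coupled cells; the model is symmetric under cell swap."""

    cell1: NeuronState
    cell2: NeuronState

    def to_array(self) -> np.ndarray:
        return np.concatenate([self.cell1.to_array(), self.cell2.to_array()])

    @classmethod
    def from_array(cls, a) -> "HCOState":
        return cls(NeuronState.from_array(a[:11]), NeuronState.from_array(a[11:22]))

    def swapped(self) -> "HCOState":
        return HCOState(self.cell2, self.cell1)


@dataclass
class CurrentBreakdown:
    """Instantaneous membrane currents of one cell (pA, positive outward)."""

    INaF: float
    INaP: float
    IKDR: float
    IKA: float
    IhNa: float
    IhK: float
    ICaS: float
    ILNa: float
    ILK: float
    IPump: float
    ISyn: float

    def total(self) -> float:
        return sum(asdict(self).values())

    def sodium_influx(self) -> float:
        """The Na-carrying sum that enters the [Na]_i balance (pA)."""
        return self.IhNa + self.ILNa + self.INaF + self.INaP + 3.0 * self.IPump


def gating_steady_state(a: float, v_half: float, vm) -> np.ndarray | float:
    """Boltzmann steady state f_inf(a, V_1/2, V) = 1/(1 + exp((V-V_1/2)/a)).

    Negative slope ``a`` gives an activation curve (increasing with V),
    positive ``a`` an inactivation curve.
    """
    if a == 0:
        raise ValueError("Boltzmann slope a must be nonzero")
    return 1.0 / (1.0 + np.exp((np.asarray(vm, dtype=float) - v_half) / a))


def mh_steady_state(vm, params: ModelParameters | None = None):
    """h-current activation steady state.

    m_h_inf(V) = 1/(1 + 2 exp(k1 (V - vh)) + exp(k2 (V - vh))), a strictly
    decreasing double-exponential Boltzmann equal to 1/4 at V = vh exactly.
    """
    k = (params or ModelParameters()).kinetics
    x = np.asarray(vm, dtype=float) - k.vh_mh
    return 1.0 / (1.0 + 2.0 * np.exp(k.k1_mh * x) + np.exp(k.k2_mh * x))


def mh_time_constant(vm, params: ModelParameters | None = None,
                     tau_h_scale: float | None = None):
    """h-current activation time constant (s), bounded in
    [base, base+amp] times ``tau_h_scale``."""
    p = params or ModelParameters()
    k = p.kinetics
    scale = p.tau_h_scale if tau_h_scale is None else tau_h_scale
    v = np.asarray(vm, dtype=float)
    return scale * (k.tauh_base
                    + k.tauh_amp / (1.0 + np.exp(k.s_tauh * (v - k.vh_tauh))))


def gating_time_constants(vm, params: ModelParameters | None = None) -> dict:
    """Voltage-dependent time constants (s) of hNaF, mKDR and mCaS.

    The fixed constants (mNaP 1 ms, hNaP 100 ms, hKA 20 ms, hCaS 340 ms,
    mSyn 50 ms) are included for completeness.
    """
    k = (params or ModelParameters()).kinetics
    v = np.asarray(vm, dtype=float)
    x1 = v - k.tau_hNaF_c
    x2 = v - k.tau_mKDR_c
    return {
        "tau_hNaF": k.tau_hNaF_A / (np.exp(x1 / k.tau_hNaF_s1)
                                    + np.exp(-x1 / k.tau_hNaF_s2)),
        "tau_mKDR": k.tau_mKDR_A / (np.exp(x2 / k.tau_mKDR_s1)
                                    + np.exp(-x2 / k.tau_mKDR_s2)),
        "tau_mCaS": k.tau_mCaS_scale * (
            k.tau_mCaS_floor
            + k.tau_mCaS_a1 / (1.0 + np.exp((v - k.tau_mCaS_c1) / k.tau_mCaS_s))
            + k.tau_mCaS_a2 / (1.0 + np.exp(-(v - k.tau_mCaS_c2) / k.tau_mCaS_s))),
        "tau_mNaP": 0.001, "tau_hNaP": 0.1, "tau_hKA": 0.02,
        "tau_hCaS": 0.34, "tau_mSyn": 0.05,
    }


def reversal_potentials(params: ModelParameters, nai: float) -> dict:
    """Nernst potentials for Na+ (depends on [Na]_i) and K+ (constant)."""
    if np.any(np.asarray(nai) <= 0):
        raise ValueError("Nai must be > 0 for a Nernst potential")
    return {"ENa": params.RTF * np.log(params.Nae / nai), "EK": params.EK}


def leak_split(gL: float, ELRef: float, ENaRef: float, EK: float) -> dict:
    """Split of the total leak into Na+ and K+ components.

    Chosen so gL_Na + gL_K = gL and the net leak reverses at ELRef when
    ENa is at its reference value.
    """
    if ENaRef == EK:
        raise ValueError("degenerate reversal: ENaRef equals EK")
    gLNa = gL * (ELRef - EK) / (ENaRef - EK)
    gLK = gL * (ELRef - ENaRef) / (EK - ENaRef)
    return {"gLNa": gLNa, "gLK": gLK}


def pump_current(nai, params: ModelParameters):
    """Na+/K+ pump current (pA), sigmoidally activated by [Na]_i
    (half-activation 25 mM, slope 3 mM) and by [K]_e (half 6 mM)."""
    nai = np.asarray(nai, dtype=float)
    if np.any(nai <= 0):
        raise ValueError("Nai must be > 0")
    na_gate = 1.0 / (1.0 + np.exp((25.0 - nai) / 3.0))
    k_gate = 1.0 / (1.0 + np.exp(6.0 - params.Ke))
    return params.IPumpMax * na_gate * k_gate


def membrane_currents(state: NeuronState, mSyn_pre: float,
                      params: ModelParameters) -> CurrentBreakdown:
    """All instantaneous membrane currents of one cell (pA)."""
    p = params
    V = state.Vm
    rev = reversal_potentials(p, state.Nai)
    ENa, EK = rev["ENa"], rev["EK"]
    gLNa, gLK = p.leak_conductances()
    mNaF = gating_steady_state(-7.8, -15.0, V)
    mKA = gating_steady_state(-10.0, -20.0, V)
    ghm2 = p.gh * state.mh ** 2
    return CurrentBreakdown(
        INaF=p.gNaF * mNaF ** 3 * state.hNaF * (V - ENa),
        INaP=p.gNaP * state.mNaP * state.hNaP * (V - ENa),
        IKDR=p.gKDR * state.mKDR ** 4 * (V - EK),
        IKA=p.gKA * mKA * state.hKA * (V - EK),
        IhNa=(3.0 / 7.0) * ghm2 * (V - ENa),
        IhK=(4.0 / 7.0) * ghm2 * (V - EK),
        ICaS=p.gCaS * state.mCaS ** 3 * state.hCaS * (V - p.ECa),
        ILNa=gLNa * (V - ENa),
        ILK=gLK * (V - EK),
        IPump=float(pump_current(state.Nai, p)),
        ISyn=p.gSyn * mSyn_pre * (V - p.ESyn),
    )


def _cell_derivatives(state: NeuronState, mSyn_pre: float,
                      params: ModelParameters,
                      mh_const: float | None = None) -> np.ndarray:
    p = params
    k = p.kinetics
    s = state if mh_const is None else NeuronState(
        **{**asdict(state), "mh": mh_const})
    cur = membrane_currents(s, mSyn_pre, p)
    V = state.Vm
    taus = gating_time_constants(V, p)
    d = np.empty(11)
    d[0] = -cur.total() / p.C
    d[1] = (gating_steady_state(k.a_hNaF, k.vh_hNaF, V) - state.hNaF) / taus["tau_hNaF"]
    d[2] = (gating_steady_state(-4.1, -43.0, V) - state.mNaP) / taus["tau_mNaP"]
    d[3] = (gating_steady_state(5.0, -57.0, V) - state.hNaP) / taus["tau_hNaP"]
    d[4] = (gating_steady_state(-15.0, -18.0, V) - state.mKDR) / taus["tau_mKDR"]
    d[5] = (gating_steady_state(5.0, -59.8, V) - state.hKA) / taus["tau_hKA"]
    d[6] = (gating_steady_state(-4.27, -45.6, V) - state.mCaS) / taus["tau_mCaS"]
    d[7] = (gating_steady_state(k.a_hCaS, k.vh_hCaS, V) - state.hCaS) / taus["tau_hCaS"]
    if mh_const is None:
        d[8] = (float(mh_steady_state(V, p)) - state.mh) / float(mh_time_constant(V, p))
    else:
        d[8] = 0.0
    d[9] = (gating_steady_state(-0.4, -25.0, V) - state.mSyn) / taus["tau_mSyn"]
    d[10] = p.M * (p.Nae - state.Nai) - p.alpha_pA * cur.sodium_influx()
    return d


def state_derivatives(hco: HCOState, params: ModelParameters,
                      mh_const: float | None = None) -> np.ndarray:
    """Time derivatives of the full two-cell state (22-vector).

    Each cell's synaptic current is driven by the *other* cell's mSyn.
    """
    d1 = _cell_derivatives(hco.cell1, hco.cell2.mSyn, params, mh_const)
    d2 = _cell_derivatives(hco.cell2, hco.cell1.mSyn, params, mh_const)
    out = np.concatenate([d1, d2])
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite state derivative")
    return out


def single_cell_derivatives(state: NeuronState, params: ModelParameters,
                            mh_const: float | None = None) -> np.ndarray:
    """Decoupled single-cell derivatives (no synaptic input)."""
    return _cell_derivatives(state, 0.0, params, mh_const)


def steady_state_cell(vm: float, params: ModelParameters,
                      nai: float = 15.0, mh: float | None = None) -> NeuronState:
    """A cell with every gating variable at its steady state for ``vm``.

    Standard way to build initial conditions; ``mh`` can be pinned for the
    reduced model.
    """
    k = params.kinetics
    return NeuronState(
        Vm=vm,
        hNaF=float(gating_steady_state(k.a_hNaF, k.vh_hNaF, vm)),
        mNaP=float(gating_steady_state(-4.1, -43.0, vm)),
        hNaP=float(gating_steady_state(5.0, -57.0, vm)),
        mKDR=float(gating_steady_state(-15.0, -18.0, vm)),
        hKA=float(gating_steady_state(5.0, -59.8, vm)),
        mCaS=float(gating_steady_state(-4.27, -45.6, vm)),
        hCaS=float(gating_steady_state(k.a_hCaS, k.vh_hCaS, vm)),
        mh=float(mh_steady_state(vm, params)) if mh is None else mh,
        mSyn=float(gating_steady_state(-0.4, -25.0, vm)),
        Nai=nai,
    )
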