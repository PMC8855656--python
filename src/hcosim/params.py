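"""Model parameters for the half-center oscillator (HCO) model.

The model describes two identical, mutually inhibitory conductance-based
neurons of the neonatal mouse locomotor CPG.  Each cell carries fast and
persistent Na+ currents, delayed-rectifier and A-type K+ currents, a slow
low-threshold Ca2+ current, a hyperpolarization-activated mixed-cation
h-current split into Na+ and K+ components, a split Na+/K+ leak, an
intracellular-Na+-activated Na+/K+ pump current and the inhibitory synapse.
Intracellular Na+ is a dynamic state variable; all other ion concentrations
are fixed parameters.

Two records configure a simulation:

* :class:`ModelParameters` — conductances, reversal potentials, pump and
  synaptic constants.  The defaults are the canonical parameter set.
* :class:`KineticsConstants` — the numeric constants of the gating kinetics
  (Boltzmann slopes/half-voltages and time-constant shapes).  A handful of
  these are genuinely uncertain in the literature this model derives from
  (typeset-damaged slope factors and one half-voltage sign); they are
  collected here as named, documented constants rather than buried in the
  vector field, and the defaults were fixed by requiring the canonical
  simulation to reproduce the published episodic-bursting behaviour.

Unit system: mV, s, nS, pA, nF, mM (nS*mV = pA and nF*mV/s = pA, so the
current-balance equation is dimensionally closed).  The Na+ flux conversion
factor ``alpha`` = 1/(v*F) is stored in its native mM/(nA*s); the vector
field converts to pA internally.
"""
from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Iterator

import numpy as np

__all__ = [
    "ModelParameters",
    "KineticsConstants",
    "canonical_parameters",
    "PARAM_VECTOR_NAMES",
]


@dataclass(frozen=True)
class KineticsConstants:
    """Gating-kinetics constants, including every ambiguity-resolved value.

    Slopes are in 1/mV unless noted; half-voltages in mV; times in s.
    """

    # h-current activation m_h: steady state
    #   m_h_inf(V) = 1 / (1 + 2 exp(k1 (V - vh_mh)) + exp(k2 (V - vh_mh)))
    # The double-exponential form pins m_h_inf(vh_mh) = 0.25 exactly.
    k1_mh: float = 1.42
    k2_mh: float = 3.9444
    vh_mh: float = -52.1
    # h-current time constant tau_h(V) = base + amp / (1 + exp(s (V - vh)))
    tauh_base: float = 0.5
    tauh_amp: float = 1.0
    s_tauh: float = 0.45
    vh_tauh: float = -73.0
    # fast-Na inactivation h_NaF: Boltzmann half-voltage and slope.
    # Written with the conventional hyperpolarized half-voltage; the
    # depolarized alternative latches the spike generator open.
    vh_hNaF: float = -26.0
    a_hNaF: float = 7.0
    # slow-Ca inactivation h_CaS slope (mV).  Steepness controls how deeply
    # the Ca current inactivates across an intra-episode burst.
    a_hCaS: float = 0.86
    vh_hCaS: float = -56.34
    # voltage-dependent time constants (two-exponential wells):
    #   tau(V) = A / (exp((V - c)/s1) + exp(-(V - c)/s2))
    tau_hNaF_A: float = 0.03
    tau_hNaF_c: float = -43.0
    tau_hNaF_s1: float = 15.0
    tau_hNaF_s2: float = 16.0
    tau_mKDR_A: float = 0.007
    tau_mKDR_c: float = -43.0
    tau_mKDR_s1: float = 40.0
    tau_mKDR_s2: float = 50.0
    # slow-Ca activation time constant (sum of two sigmoids, s):
    #   tau_mCaS(V) = floor + a1/(1+exp((V-c1)/4.5)) + a2/(1+exp(-(V-c2)/4.5))
    tau_mCaS_floor: float = 0.001
    tau_mCaS_a1: float = 0.02
    tau_mCaS_c1: float = -48.01
    tau_mCaS_a2: float = 0.05
    tau_mCaS_c2: float = -51.01
    tau_mCaS_s: float = 4.5
    tau_mCaS_scale: float = 3.45


@dataclass(frozen=True)
class ModelParameters:
    """Canonical HCO parameter set (defaults) plus the kinetics table.

    All conductances in nS, potentials in mV, currents in pA,
    capacitance in nF, concentrations in mM, times in s.
    """

    C: float = 0.001            # membrane capacitance (nF)
    gNaF: float = 105.0         # fast Na+ (nS)
    gNaP: float = 4.97          # persistent Na+ (nS)
    gKDR: float = 79.0          # delayed-rectifier K+ (nS)
    gKA: float = 1.13           # A-type K+ (nS)
    gh: float = 0.34            # h-current (nS)
    gCaS: float = 3.3           # slow Ca2+ (nS)
    gL: float = 1.88            # total leak (nS), split into Na/K parts
    gSyn: float = 1.02          # inhibitory synapse (nS)
    ECa: float = 160.0          # Ca2+ reversal (mV), fixed
    ELRef: float = -55.0        # leak reference reversal (mV)
    ENaRef: float = 65.0        # Na+ reference reversal for the leak split (mV)
    ESyn: float = -70.0         # synaptic reversal (mV)
    IPumpMax: float = 40.26     # maximal Na+/K+ pump current (pA)
    Nae: float = 120.0          # extracellular Na+ (mM), fixed
    Ke: float = 9.0             # extracellular K+ (mM), fixed
    Ki: float = 130.0           # intracellular K+ (mM), fixed
    M: float = 0.0              # monensin Na+-influx rate constant (1/s)
    # Na+ flux conversion 1/(v*F) in mM/(nA*s); v is the intracellular
    # volume (~2214 um^3) and F Faraday's constant.
    alpha: float = 4.682255338155292
    tau_h_scale: float = 1.0    # dimensionless multiplier on tau_h
    RTF: float = 26.45          # Nernst slope RT/F (mV)
    kinetics: KineticsConstants = field(default_factory=KineticsConstants)

    def __post_init__(self) -> None:
        for name in ("gNaF", "gNaP", "gKDR", "gKA", "gh", "gCaS", "gL", "gSyn"):
            if getattr(self, name) < 0:
                raise ValueError(f"conductance {name} must be >= 0")
        if self.C <= 0:
            raise ValueError("capacitance C must be > 0")
        for name in ("Nae", "Ke", "Ki"):
            if getattr(self, name) <= 0:
                raise ValueError(f"concentration {name} must be > 0")
        if self.M < 0:
            raise ValueError("monensin rate constant M must be >= 0")
        if self.tau_h_scale <= 0:
            raise ValueError("tau_h_scale must be > 0")

    # -- derived quantities ------------------------------------------------

    @property
    def EK(self) -> float:
        """K+ Nernst potential (mV); constant because [K]e, [K]i are fixed."""
        return self.RTF * float(np.log(self.Ke / self.Ki))

    @property
    def alpha_pA(self) -> float:
        """Na+ flux conversion in mM/(pA*s)."""
        return self.alpha * 1e-3

    def leak_conductances(self) -> tuple[float, float]:
        """Split of gL into (gL_Na, gL_K), see :func:`model_core.leak_split`."""
        EK = self.EK
        if self.ENaRef == EK:
            raise ValueError("degenerate reversal: ENaRef equals EK")
        gLNa = self.gL * (self.ELRef - EK) / (self.ENaRef - EK)
        gLK = self.gL * (self.ELRef - self.ENaRef) / (EK - self.ENaRef)
        return gLNa, gLK

    def evolve(self, **changes) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        kin_changes = {
            k: changes.pop(k) for k in list(changes)
            if k in {f.name for f in fields(KineticsConstants)}
        }
        p = replace(self, **changes)
        if kin_changes:
            p = replace(p, kinetics=replace(p.kinetics, **kin_changes))
        return p

    # -- kernel interface --------------------------------------------------

    def to_vector(self, mh_const: float = -1.0) -> np.ndarray:
        """Pack into the flat float64 vector consumed by the compiled RHS.

        ``mh_const`` >= 0 freezes the h-current activation at that value
        (the reduced constant-m_h model); -1 keeps m_h dynamic.
        """
        k = self.kinetics
        gLNa, gLK = self.leak_conductances()
        vec = np.array([
            self.C, self.gNaF, self.gNaP, self.gKDR, self.gKA, self.gh,
            self.gCaS, self.gL, self.gSyn, self.ECa, self.ELRef, self.ENaRef,
            self.ESyn, self.IPumpMax, self.Nae, self.Ke, self.Ki, self.M,
            self.alpha_pA, self.tau_h_scale, self.RTF,
            k.k1_mh, k.k2_mh, k.vh_mh, k.s_tauh, k.vh_tauh, k.tauh_base,
            k.tauh_amp, k.vh_hNaF, k.a_hNaF, k.a_hCaS, k.vh_hCaS,
            k.tau_hNaF_A, k.tau_hNaF_c, k.tau_hNaF_s1, k.tau_hNaF_s2,
            k.tau_mKDR_A, k.tau_mKDR_c, k.tau_mKDR_s1, k.tau_mKDR_s2,
            k.tau_mCaS_floor, k.tau_mCaS_a1, k.tau_mCaS_c1, k.tau_mCaS_a2,
            k.tau_mCaS_c2, k.tau_mCaS_s, k.tau_mCaS_scale,
            self.EK, gLNa, gLK, float(mh_const),
        ], dtype=np.float64)
        return vec


# Index names of the kernel parameter vector, in order.
PARAM_VECTOR_NAMES: tuple[str, ...] = (
    "C", "gNaF", "gNaP", "gKDR", "gKA", "gh", "gCaS", "gL", "gSyn",
    "ECa", "ELRef", "ENaRef", "ESyn", "IPumpMax", "Nae", "Ke", "Ki", "M",
    "alpha_pA", "tau_h_scale", "RTF",
    "k1_mh", "k2_mh", "vh_mh", "s_tauh", "vh_tauh", "tauh_base", "tauh_amp",
    "vh_hNaF", "a_hNaF", "a_hCaS", "vh_hCaS",
    "tau_hNaF_A", "tau_hNaF_c", "tau_hNaF_s1", "tau_hNaF_s2",
    "tau_mKDR_A", "tau_mKDR_c", "tau_mKDR_s1", "tau_mKDR_s2",
    "tau_mCaS_floor", "tau_mCaS_a1", "tau_mCaS_c1", "tau_mCaS_a2",
    "tau_mCaS_c2", "tau_mCaS_s", "tau_mCaS_scale",
    "EK", "gLNa", "gLK", "mh_const",
)


def canonical_parameters(**overrides) -> ModelParameters:
    """The canonical HCO parameter set, optionally with field overrides."""
    return ModelParameters().evolve(**overrides)


def _vec_index(name: str) -> int:
    return PARAM_VECTOR_NAMES.index(name)


def iter_param_names() -> Iterator[str]:
    yield from (f.name for f in fields(ModelParameters) if f.name != "kinetics")
    yield from (f.name for f in fields(KineticsConstants))
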