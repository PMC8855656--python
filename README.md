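# hcosim

A biophysical model of how one spinal locomotor circuit produces both
*episodic* and *continuous* rhythms.  Developing spinal cords (e.g. the
neonatal mouse lumbar cord under dopamine) generate episodes of fast
bursting — tens of seconds of ~1 Hz bursts separated by long quiet
intervals — and can switch to uninterrupted bursting or fall silent as
neuromodulatory tone changes.  `hcosim` implements a half-center
oscillator (HCO) of two mutually inhibitory conductance-based neurons
in which these transitions emerge from two slow processes: the
hyperpolarization-activated h-current (activation m_h, the leading slow
gating variable) and the Na⁺/K⁺ pump current driven by intracellular
Na⁺.  The package is aimed at computational neuroscientists studying
multi-timescale bursting and central pattern generators.

Each cell follows the current balance

    C dV/dt = −(I_NaF + I_NaP + I_KDR + I_KA + I_h-Na + I_h-K + I_CaS
               + I_L-Na + I_L-K + I_Pump + I_Syn)

with Hodgkin–Huxley gating, a split h-current and leak (Na⁺/K⁺
components), a pump current activated by [Na]_i (half-activation 25 mM)
and a dynamic intracellular Na⁺ pool,

    d[Na]_i/dt = M([Na]_e − [Na]_i) − α(I_h-Na + I_L-Na + I_NaF + I_NaP + 3 I_Pump).

Episodic bursting is elliptic-type second-order bursting: holding m_h
constant exposes a fast subsystem with only two regimes (rest and
continuous bursting) whose rest state loses stability at a subcritical
Andronov–Hopf bifurcation; the full model's episodes are a slow
hysteresis loop across that diagram.  See `docs/methods.md` for the
complete equations, the kinetics-constants table, and an account of which
published quantities the calibrated model does and does not reproduce.

## Worked example

```python
import hcosim as H

params = H.canonical_parameters()          # the canonical HCO
trace = H.integrate(params, transient=5000.0, record=2000.0)
metrics = H.analyze_trace(trace)
s = metrics.summary
print(H.classify_regime(trace).value)
print(f"EP  {s['EP']['mean']:.1f} s   ED {s['ED']['mean']:.2f} s   "
      f"IEI {s['IEI']['mean']:.1f} s   BD {s['BD']['mean']:.2f} s")
```

prints

```
episodic
EP  48.6 s   ED 1.51 s   IEI 47.1 s   BD 0.44 s
```

i.e. the two cells burst in alternation (burst duration ≈ 0.44 s) in
episodes recurring every ≈ 49 s.  Lowering the h-current conductance
`gh` below ≈ 0.31 nS silences the model; raising it, or raising
`IPumpMax`, shortens the interepisode interval until bursting becomes
continuous:

```python
from hcosim.experiments import regime_boundary
from hcosim.analysis import RegimeLabel
b = regime_boundary(params, "gh", 0.30, 0.34,
                    RegimeLabel.SILENCE, RegimeLabel.EPISODIC,
                    resolution=0.002)
print(b["boundary"])      # ≈ 0.31 nS
```

The command line mirrors the library:

```
hcosim simulate --transient 5000 --record 2000 --out trace.csv
hcosim analyze  --trace trace.csv --out metrics.csv
hcosim sweep    --param gh --grid 0.32:0.37:0.01 --out sweep.csv
hcosim bifurcate --grid 0.7:1.0:0.01 --out diagram.csv
hcosim synth    --mode neurogram --ep 50 --ed 20 --out synthetic.csv
```

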