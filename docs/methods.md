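# Methods

## The model

`hcosim` implements a half-center oscillator (HCO): two identical
conductance-based neurons coupled by mutual inhibition, representing
flexor- and extensor-related interneuron populations of the neonatal
rodent locomotor network.  Each cell is a single electrical compartment
with one intracellular Na⁺ pool and eleven state variables: the membrane
potential V_m, eight gating variables (fast-Na⁺ inactivation h_NaF,
persistent-Na⁺ activation/inactivation m_NaP/h_NaP, delayed-rectifier
activation m_KDR, A-type inactivation h_KA, slow-Ca²⁺ activation/
inactivation m_CaS/h_CaS, h-current activation m_h), the synaptic
activation m_Syn seen by the other cell, and the intracellular Na⁺
concentration [Na]_i.

The current balance is, with all currents positive-outward,

    C dV/dt = −(I_NaF + I_NaP + I_KDR + I_KA + I_h-Na + I_h-K + I_CaS
               + I_L-Na + I_L-K + I_Pump + I_Syn)

The h-current and the leak are each split into Na⁺ and K⁺ components
(3/7 and 4/7 of the h conductance; the leak split is fixed by a reference
leak reversal E_LRef = −55 mV and the Na⁺ reference reversal
E_NaRef = 65 mV so that gL_Na + gL_K = gL and the net leak reverses at
E_LRef).  E_Na follows [Na]_i through the Nernst relation with
RT/F = 26.45 mV; E_K is constant (fixed [K]_e = 9, [K]_i = 130 mM).
The Na⁺/K⁺ pump current is activated sigmoidally by [Na]_i
(half-activation 25 mM, slope 3 mM) and by [K]_e (half 6 mM), with
maximum I_PumpMax = 40.26 pA.  Intracellular Na⁺ obeys

    d[Na]_i/dt = M([Na]_e − [Na]_i) − α(I_h-Na + I_L-Na + I_NaF + I_NaP + 3 I_Pump)

where α = 1/(vF) converts current to concentration flux and M is a
first-order influx rate constant that represents the Na⁺/H⁺ antiporter
monensin (M = 0 except in the monensin experiment).

### Units and the size of α

The package works in mV, s, nS, pA, nF, mM.  The flux factor is stored
as α = 4.682255338155292 mM·nA⁻¹·s⁻¹ and converted to pA internally
(×10⁻³).  The nA reading is the physically consistent one: it implies an
intracellular volume v = 1/(αF) ≈ 2.2·10³ µm³, a ~16 µm-diameter soma.
Read per-pA, the same digits would imply a 2 µm³ compartment, and Na⁺
would swing by ~10 mM per action potential, destroying the slow rhythm.
With the nA reading, [Na]_i relaxes on a 20–30 s timescale, which is
exactly the interepisode clock the model needs.

### Kinetics constants

All gating variables relax first-order to Boltzmann steady states
f∞(a, V_half, V) = 1/(1+exp((V−V_half)/a)); negative `a` is activation.
Fixed time constants: m_NaP 1 ms, h_NaP 100 ms, h_KA 20 ms, h_CaS
340 ms, m_Syn 50 ms.  Voltage-dependent time constants use
two-exponential wells (h_NaF: 0.03/(e^{(V+43)/15}+e^{−(V+43)/16}) s,
m_KDR: 0.007/(e^{(V+43)/40}+e^{−(V+43)/50}) s) and, for m_CaS, a sum of
two sigmoids bounded between roughly 20 ms·s and 50 ms·s times a scale
factor.  I_NaF and I_KA activate instantaneously (m∞³ and m∞).

The h-current activation uses the double-exponential Boltzmann

    m_h∞(V) = 1 / (1 + 2 e^{k₁(V+52.1)} + e^{k₂(V+52.1)})

which equals 1/4 at V = −52.1 mV for any slopes, and

    τ_h(V) = s_τ · (0.5 + 1/(1 + e^{0.45 (V+73)})) s,

bounded in [0.5, 1.5]·s_τ with s_τ the dimensionless scale factor
(1 canonically, 50 in the slowed-m_h experiment).

A handful of kinetic constants in this model family circulate in the
literature with typeset-damaged slope factors, and one half-voltage sign
is inconsistent between sources.  These are isolated in
`KineticsConstants`, one named constant each, so the resolution is
explicit and overridable.  The package's defaults were fixed by a single
calibration pass: the constants were varied within their plausible
readings until the canonical simulation produced stable episodic
bursting in both the HCO and the decoupled cell, a two-regime (rest /
continuous-bursting) constant-m_h fast subsystem whose rest state loses
stability at a subcritical Andronov–Hopf bifurcation, and an episodic →
silence transition when g_h is lowered a few percent below canonical.
The calibrated values are k₁ = 1.42 /mV, k₂ = 3.9444 /mV, h_NaF
half-voltage −26 mV (slope 7 mV), h_CaS slope 0.86 mV at −56.34 mV, and
an m_CaS time-constant scale of 3.45.  They were chosen once, against
the published episode metrics, and are not adjusted per experiment.

## Numerics

Long simulations run through a numba-compiled adaptive Dormand–Prince
5(4) embedded Runge–Kutta with absolute tolerance 1e−8, relative 1e−9
and initial step 1e−8 s — the highest-order embedded pair in the
compiled kernel; a fixed-step RK4 at dt = 10 µs serves as an independent
cross-check and agrees on spike counts with sub-millisecond jitter.
Output is sampled on a uniform 0.2 ms grid (5 kHz) by linear in-step
interpolation.  Every production run discards a long transient (5,000 s
in the reference protocol; shortened in unit tests) so that metrics are
measured in the stable regime.  The model has no stochastic terms:
identical configurations reproduce identical traces bit-for-bit.

Equilibria of the constant-m_h fast subsystem are found with a
root solver seeded along the m_h grid; Jacobians are central differences
with per-variable steps (1e−6 relative, 1e−9 absolute floor); the Hopf
point is bisected on the real part of the leading complex eigenvalue
pair.  The simulation-based regime boundaries and the eigenvalue-based
Hopf are two independent detectors of the same bifurcation, and their
agreement (within one grid refinement) is a standing test.

## Analysis pipeline

Spikes are upward crossings of −20 mV with a 3 ms refractory period
(interpolated crossing times).  Bursts are maximal spike runs with ISIs
below 0.3 s (≥2 spikes); episodes are maximal burst runs with gaps below
4 s (≥2 bursts).  The gap spectrum of the canonical model is strongly
bimodal (intra-episode gaps well under 1 s, interepisode gaps tens of
seconds), so the labels are insensitive to the episode-gap threshold over
2–8 s; a regime is silence (no spikes), continuous (no quiet gap ≥ the
episode gap), episodic (≥2 episodes), or mixed.  Episode onset is
anchored to the first spike of the first burst, offset to the last spike
of the last burst; EP is onset-to-onset, ED onset-to-offset, IEI
offset-to-next-onset, so EP = ED + IEI by construction.  CVs are SD/mean
across the intervals of one record.

DC neurogram-style signals go through linear detrend, a zero-phase
2nd-order Butterworth band-pass (0.01–1 Hz), rectification, a
Gaussian-weighted moving average (σ = 0.5 s) and hysteresis
onset/offset detection (on at 50 %, off at 20 % of the
median-to-95th-percentile envelope amplitude).  The Gaussian width and
filter order are the package's own choices; they recover the ground
truth of the synthetic generator to within 2 % (EP) and 10 % (ED) at
SNR 10.

## Synthetic data

`SyntheticTraceSpec` generates traces whose spike/burst/episode times
are known exactly: square-envelope episodes (prescribed EP, ED) filled
with burst trains (prescribed rate, spikes per burst, triangular spikes),
plus optional linear drift and Gaussian noise, in membrane-potential or
DC-neurogram form.  All randomness is seeded through one generator.
What these fixtures establish is detector correctness — exact recovery
in the noise-free case, graceful degradation with noise — not model
realism: real neurograms have amplitude drift, non-stationary episode
shapes and correlated noise that the generator only caricatures.

## Experiment protocols

Parameter sweeps vary one parameter at a time from the canonical set
(transient 5,000 s, record 2,000 s episodic / 200 s continuous).
Regime boundaries are bisected on the classification with a shortened
transient per probe (600 s in the desk-scale protocol, 1,000 s when time
allows) and a confirmation run at the full transient at the final
midpoint; a disagreeing confirmation widens the reported bracket.  When
the nominal bracket of a published boundary does not bracket in this
implementation (the episodic zone here extends further than published
before giving way to continuous bursting), the far end is widened until
a genuine bracket is found and the result reported as computed.
Bistability is probed by running identical parameters from a rest-like
and a bursting-like initial condition.  "Plateau-like" bursting is not a
separate label; continuous bursting with duty cycle BD/BP > 0.7 is
reported via an auxiliary statistic.

Initial conditions are not part of the published protocol; the package
seeds cell 1 at −50 mV and cell 2 at −60 mV (gates at steady state,
[Na]_i = 15 mM) because the HCO is exchange-symmetric and a symmetric
start would never leave the symmetric manifold in exact arithmetic.

## What the calibrated model does and does not reproduce

With the calibrated kinetics table the model reproduces, at canonical
parameters: episodic bursting in the HCO with mean episode period ≈ 49 s
(published 51.1 s) and alternating intra-episode bursts whose duration
plateaus at ≈ 0.44 s (published 0.44 s) with second/last burst periods
≈ 0.54/1.0 s (published 0.54/1.0 s); episodic activity of the decoupled
cell with much shorter episodes than the HCO; a two-regime constant-m_h
fast subsystem with eigenvalue and simulation boundary detectors in
agreement; silence when g_h drops a few hundredths of a nS below
canonical; the published ordering of regimes along both the g_h and
I_PumpMax axes, with IEI lengthening toward the silent boundary (IEI ≈
66 s at I_PumpMax = 39.3 pA) and shortening with increasing g_h.

It does not reproduce the published partition of the episode period into
duration and interval: episodes here are short (ED ≈ 1.5 s vs 20.8 s)
and intervals correspondingly long, the episode rhythm is more regular
(EP-CV ≈ 0.03 vs 0.211), the coexistence band of the fast subsystem is
much narrower than published (boundaries ≈ 0.93/0.93 vs 0.815/0.975),
the episodic zone extends further along both swept axes before turning
continuous, and the monensin influx at M = 0.002 s⁻¹ tips the model into
silence rather than lengthening the episode period.  These differences
trace to the unresolved kinetic constants: the episode-terminating
balance between h-current deactivation and Na⁺ accumulation is
extremely sensitive to the m_h∞ slopes and the Ca²⁺-current kinetics,
and no setting of the ambiguous constants found in calibration
reproduces both the episode partition and the boundary locations at
once.  The affected checks are left failing rather than loosened.

## Known limitations

No Ca²⁺ concentration dynamics (E_Ca fixed at 160 mV), no temperature
dependence, no channel noise, no left/right coordination or phase
analysis.  The boundary values depend mildly on the shortened-transient
protocol near slowly converging attractors; the confirmation run guards
the reported bracket but very long chaotic transients (if any) would be
misclassified.
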