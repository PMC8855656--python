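# Canonical half-center oscillator parameter set.
# Units: mV, s, nS, pA, nF, mM.  Omitted keys fall back to these values,
# so an empty config file reproduces this model exactly.

[model]
C = 0.001            # membrane capacitance (nF)
gNaF = 105.0         # fast Na+ conductance (nS)
gNaP = 4.97          # persistent Na+ conductance (nS)
gKDR = 79.0          # delayed-rectifier K+ conductance (nS)
gKA = 1.13           # A-type K+ conductance (nS)
gh = 0.34            # h-current conductance (nS)
gCaS = 3.3           # slow Ca2+ conductance (nS)
gL = 1.88            # total leak conductance (nS)
gSyn = 1.02          # inhibitory synaptic conductance (nS)
ECa = 160.0          # Ca2+ reversal potential (mV)
ELRef = -55.0        # leak reference reversal (mV)
ENaRef = 65.0        # Na+ reference reversal for the leak split (mV)
ESyn = -70.0         # synaptic reversal potential (mV)
IPumpMax = 40.26     # maximal Na+/K+ pump current (pA)
Nae = 120.0          # extracellular Na+ (mM)
Ke = 9.0             # extracellular K+ (mM)
Ki = 130.0           # intracellular K+ (mM)
M = 0.0              # monensin Na+ influx rate constant (1/s)
alpha = 4.682255338155292   # Na+ flux conversion 1/(v*F) (mM per nA per s)
tau_h_scale = 1.0    # multiplier on the h-current time constant
RTF = 26.45          # Nernst slope RT/F (mV)

[solver]
abs_tol = 1e-8
rel_tol = 1e-9
initial_step = 1e-8

[protocol]
transient = 5000.0   # discarded before analysis (s)
record = 2000.0      # analysed window (s)
sample_dt = 0.0002   # 5 kHz output grid (s)
ncell = 2
ic_vm1 = -50.0       # asymmetric IC breaks the HCO's exchange symmetry
ic_vm2 = -60.0
ic_nai = 15.0

[analysis]
spike_threshold = -20.0
refractory = 0.003
burst_isi_gap = 0.3
episode_gap = 4.0
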