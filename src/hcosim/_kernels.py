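"""Compiled vector field and integrator kernels.

Everything here operates on flat float64 arrays so numba can compile it:
the parameter vector comes from :meth:`hcosim.params.ModelParameters.to_vector`
(see ``PARAM_VECTOR_NAMES`` for the layout) and the state vector holds one
or two cells of 11 variables each:

    [Vm, hNaF, mNaP, hNaP, mKDR, hKA, mCaS, hCaS, mh, mSyn, Nai]

The integrator is an adaptive embedded Dormand-Prince 5(4) pair with FSAL,
PI-free standard step control and linear in-step sampling onto a uniform
output grid.  A fixed-step classical RK4 is provided as an independent
cross-check oracle.
"""
from __future__ import annotations

import numpy as np
from numba import njit

NSTATE = 11  # per cell

# state indices
IV, IHNAF, IMNAP, IHNAP, IMKDR, IHKA, IMCAS, IHCAS, IMH, IMSYN, INAI = range(11)


@njit(cache=True)
def cell_rhs(y, off, d, mSynPre, p):
    """Single-cell derivatives written into d[off:off+11].

    ``mSynPre`` is the synaptic activation of the presynaptic cell.
    """
    V = y[off + 0]
    hNaF = y[off + 1]; mNaP = y[off + 2]; hNaP = y[off + 3]
    mKDR = y[off + 4]; hKA = y[off + 5]; mCaS = y[off + 6]; hCaS = y[off + 7]
    mh = y[off + 8]; Nai = y[off + 10]
    mh_const = p[50]
    if mh_const >= 0.0:
        mh = mh_const
    RTF = p[20]
    ENa = RTF * np.log(p[14] / Nai)
    EK = p[47]
    # instantaneous activations
    mNaF = 1.0 / (1.0 + np.exp((V + 15.0) / (-7.8)))
    mKA = 1.0 / (1.0 + np.exp((V + 20.0) / (-10.0)))
    # membrane currents (pA, positive outward)
    INaF = p[1] * mNaF * mNaF * mNaF * hNaF * (V - ENa)
    INaP = p[2] * mNaP * hNaP * (V - ENa)
    IKDR = p[3] * mKDR * mKDR * mKDR * mKDR * (V - EK)
    IKA = p[4] * mKA * hKA * (V - EK)
    ghm2 = p[5] * mh * mh
    IhNa = (3.0 / 7.0) * ghm2 * (V - ENa)
    IhK = (4.0 / 7.0) * ghm2 * (V - EK)
    ICaS = p[6] * mCaS * mCaS * mCaS * hCaS * (V - p[9])
    ILNa = p[48] * (V - ENa)
    ILK = p[49] * (V - EK)
    IPump = p[13] / (1.0 + np.exp((25.0 - Nai) / 3.0)) / (1.0 + np.exp(6.0 - p[15]))
    ISyn = p[8] * mSynPre * (V - p[12])
    d[off + 0] = -(INaF + INaP + IKDR + IKA + IhNa + IhK + ICaS
                   + ILNa + ILK + IPump + ISyn) / p[0]
    # voltage-dependent time constants
    x1 = V - p[33]
    tau_hNaF = p[32] / (np.exp(x1 / p[34]) + np.exp(-x1 / p[35]))
    x2 = V - p[37]
    tau_mKDR = p[36] / (np.exp(x2 / p[38]) + np.exp(-x2 / p[39]))
    tau_mCaS = p[46] * (p[40]
                        + p[41] / (1.0 + np.exp((V - p[42]) / p[45]))
                        + p[43] / (1.0 + np.exp(-(V - p[44]) / p[45])))
    # first-order gating relaxation
    d[off + 1] = (1.0 / (1.0 + np.exp((V - p[28]) / p[29])) - hNaF) / tau_hNaF
    d[off + 2] = (1.0 / (1.0 + np.exp((V + 43.0) / (-4.1))) - mNaP) / 0.001
    d[off + 3] = (1.0 / (1.0 + np.exp((V + 57.0) / 5.0)) - hNaP) / 0.1
    d[off + 4] = (1.0 / (1.0 + np.exp((V + 18.0) / (-15.0))) - mKDR) / tau_mKDR
    d[off + 5] = (1.0 / (1.0 + np.exp((V + 59.8) / 5.0)) - hKA) / 0.02
    d[off + 6] = (1.0 / (1.0 + np.exp((V + 45.6) / (-4.27))) - mCaS) / tau_mCaS
    d[off + 7] = (1.0 / (1.0 + np.exp((V - p[31]) / p[30])) - hCaS) / 0.34
    if mh_const >= 0.0:
        d[off + 8] = 0.0
    else:
        xm = V - p[23]
        mh_inf = 1.0 / (1.0 + 2.0 * np.exp(p[21] * xm) + np.exp(p[22] * xm))
        tau_h = p[19] * (p[26] + p[27] / (1.0 + np.exp(p[24] * (V - p[25]))))
        d[off + 8] = (mh_inf - mh) / tau_h
    d[off + 9] = (1.0 / (1.0 + np.exp((V + 25.0) / (-0.4))) - y[off + 9]) / 0.05
    # intracellular Na+: monensin influx, Na-carrying currents, pump (3 Na/cycle)
    d[off + 10] = p[17] * (p[14] - Nai) - p[18] * (IhNa + ILNa + INaF + INaP
                                                   + 3.0 * IPump)


@njit(cache=True)
def rhs(y, d, p, ncell):
    if ncell == 1:
        cell_rhs(y, 0, d, 0.0, p)
    else:
        cell_rhs(y, 0, d, y[NSTATE + IMSYN], p)
        cell_rhs(y, NSTATE, d, y[IMSYN], p)


@njit(cache=True)
def _dp45_step(y, h, p, ncell, k1, k2, k3, k4, k5, k6, k7, ytmp, y5, err):
    n = y.shape[0]
    for i in range(n):
        ytmp[i] = y[i] + h * 0.2 * k1[i]
    rhs(ytmp, k2, p, ncell)
    for i in range(n):
        ytmp[i] = y[i] + h * (3.0 / 40.0 * k1[i] + 9.0 / 40.0 * k2[i])
    rhs(ytmp, k3, p, ncell)
    for i in range(n):
        ytmp[i] = y[i] + h * (44.0 / 45.0 * k1[i] - 56.0 / 15.0 * k2[i]
                              + 32.0 / 9.0 * k3[i])
    rhs(ytmp, k4, p, ncell)
    for i in range(n):
        ytmp[i] = y[i] + h * (19372.0 / 6561.0 * k1[i] - 25360.0 / 2187.0 * k2[i]
                              + 64448.0 / 6561.0 * k3[i] - 212.0 / 729.0 * k4[i])
    rhs(ytmp, k5, p, ncell)
    for i in range(n):
        ytmp[i] = y[i] + h * (9017.0 / 3168.0 * k1[i] - 355.0 / 33.0 * k2[i]
                              + 46732.0 / 5247.0 * k3[i] + 49.0 / 176.0 * k4[i]
                              - 5103.0 / 18656.0 * k5[i])
    rhs(ytmp, k6, p, ncell)
    for i in range(n):
        y5[i] = y[i] + h * (35.0 / 384.0 * k1[i] + 500.0 / 1113.0 * k3[i]
                            + 125.0 / 192.0 * k4[i] - 2187.0 / 6784.0 * k5[i]
                            + 11.0 / 84.0 * k6[i])
    rhs(y5, k7, p, ncell)
    for i in range(n):
        err[i] = h * ((35.0 / 384.0 - 5179.0 / 57600.0) * k1[i]
                      + (500.0 / 1113.0 - 7571.0 / 16695.0) * k3[i]
                      + (125.0 / 192.0 - 393.0 / 640.0) * k4[i]
                      + (-2187.0 / 6784.0 + 92097.0 / 339200.0) * k5[i]
                      + (11.0 / 84.0 - 187.0 / 2100.0) * k6[i]
                      - 1.0 / 40.0 * k7[i])


@njit(cache=True)
def integrate_adaptive(y0, p, ncell, t0, t1, sample_dt,
                       abs_tol, rel_tol, h0, hmax, rec_idx):
    """Adaptive DP5(4) integration with uniform-grid recording.

    Returns (samples, y_final, t_reached, status, n_steps); status 0 on
    success, -1 if the step size underflowed (non-finite state).
    """
    n = y0.shape[0]
    nrec = rec_idx.shape[0]
    nsamp = int(np.floor((t1 - t0) / sample_dt + 1e-9)) + 1
    out = np.empty((nsamp, nrec), dtype=np.float64)
    y = y0.copy()
    k1 = np.empty(n); k2 = np.empty(n); k3 = np.empty(n); k4 = np.empty(n)
    k5 = np.empty(n); k6 = np.empty(n); k7 = np.empty(n)
    ytmp = np.empty(n); y5 = np.empty(n); err = np.empty(n)
    t = t0
    h = h0
    rhs(y, k1, p, ncell)
    for j in range(nrec):
        out[0, j] = y[rec_idx[j]]
    isamp = 1
    nstep = 0
    while t < t1 and isamp < nsamp:
        if h > hmax:
            h = hmax
        if t + h > t1:
            h = t1 - t
        _dp45_step(y, h, p, ncell, k1, k2, k3, k4, k5, k6, k7, ytmp, y5, err)
        enorm = 0.0
        for i in range(n):
            sc = abs_tol + rel_tol * max(abs(y[i]), abs(y5[i]))
            q = err[i] / sc
            enorm += q * q
        enorm = np.sqrt(enorm / n)
        if not np.isfinite(enorm):
            h *= 0.25
            if h < 1e-14:
                return out[:isamp], y, t, -1, nstep
            rhs(y, k1, p, ncell)
            continue
        if enorm <= 1.0:
            tnew = t + h
            while isamp < nsamp:
                ts = t0 + isamp * sample_dt
                if ts > tnew:
                    break
                w = (ts - t) / h if h > 0 else 0.0
                for j in range(nrec):
                    i_ = rec_idx[j]
                    out[isamp, j] = y[i_] + w * (y5[i_] - y[i_])
                isamp += 1
            t = tnew
            for i in range(n):
                y[i] = y5[i]
                k1[i] = k7[i]  # FSAL
            nstep += 1
            fac = 0.9 * enorm ** (-0.2) if enorm > 1e-10 else 5.0
            h *= min(fac, 5.0)
        else:
            h *= max(0.9 * enorm ** (-0.2), 0.1)
            if h < 1e-14:
                return out[:isamp], y, t, -1, nstep
    return out[:isamp], y, t, 0, nstep


@njit(cache=True)
def integrate_rk4(y0, p, ncell, t0, t1, dt, sample_dt, rec_idx):
    """Fixed-step classical RK4; independent oracle for solver checks."""
    n = y0.shape[0]
    nrec = rec_idx.shape[0]
    nsamp = int(np.floor((t1 - t0) / sample_dt + 1e-9)) + 1
    out = np.empty((nsamp, nrec), dtype=np.float64)
    y = y0.copy()
    k1 = np.empty(n); k2 = np.empty(n); k3 = np.empty(n); k4 = np.empty(n)
    ytmp = np.empty(n)
    for j in range(nrec):
        out[0, j] = y[rec_idx[j]]
    isamp = 1
    nstep = int(np.round((t1 - t0) / dt))
    stride = max(1, int(np.round(sample_dt / dt)))
    for s in range(1, nstep + 1):
        rhs(y, k1, p, ncell)
        for i in range(n):
            ytmp[i] = y[i] + 0.5 * dt * k1[i]
        rhs(ytmp, k2, p, ncell)
        for i in range(n):
            ytmp[i] = y[i] + 0.5 * dt * k2[i]
        rhs(ytmp, k3, p, ncell)
        for i in range(n):
            ytmp[i] = y[i] + dt * k3[i]
        rhs(ytmp, k4, p, ncell)
        for i in range(n):
            y[i] += dt / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
        if s % stride == 0 and isamp < nsamp:
            for j in range(nrec):
                out[isamp, j] = y[rec_idx[j]]
            isamp += 1
    return out[:isamp], y
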