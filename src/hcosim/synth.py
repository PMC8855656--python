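"""Synthetic trace generation with exact ground truth.

The generator builds detector-test inputs whose spike, burst and episode
times are known exactly: square-envelope episodes of spike-like events
with prescribed episode period/duration and intra-episode burst trains,
plus optional slow drift and band-limited noise to emulate DC
neurograms.  All randomness is seed-controlled; the dynamical model
itself has none.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulator import Trace

__all__ = ["SyntheticTraceSpec", "GroundTruth", "generate_synthetic_trace"]


@dataclass(frozen=True)
class SyntheticTraceSpec:
    """Ground-truth layout of a synthetic trace.

    mode 'vm' produces a membrane-potential-like signal (baseline -60 mV,
    triangular spikes peaking at +20 mV); 'neurogram' produces a DC
    signal whose episodes carry a burst-rate modulation envelope.
    """

    mode: str = "vm"                 # 'vm' | 'neurogram'
    duration: float = 200.0          # s
    episode_period: float = 50.0     # EP (s)
    episode_duration: float = 20.0   # ED (s); must be < EP
    burst_rate: float = 1.0          # intra-episode bursts per second
    spikes_per_burst: int = 5
    intra_burst_isi: float = 0.05    # s
    spike_width: float = 0.004       # s (triangular)
    spike_amplitude: float = 80.0    # mV above baseline
    baseline: float = -60.0          # mV
    noise_sd: float = 0.0
    drift_slope: float = 0.0         # units/s linear drift
    sample_dt: float = 2e-4          # s
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.episode_duration < self.episode_period:
            raise ValueError("need 0 < episode_duration < episode_period")
        if self.duration <= 0 or self.sample_dt <= 0:
            raise ValueError("duration and sample_dt must be > 0")
        if self.mode not in ("vm", "neurogram"):
            raise ValueError("mode must be 'vm' or 'neurogram'")


@dataclass
class GroundTruth:
    spike_times: np.ndarray
    burst_onsets: np.ndarray
    burst_offsets: np.ndarray
    episode_onsets: np.ndarray
    episode_offsets: np.ndarray


def _layout(spec: SyntheticTraceSpec) -> GroundTruth:
    gap = spec.episode_period - spec.episode_duration
    ep_on = np.arange(gap / 2.0, spec.duration, spec.episode_period)
    ep_on = ep_on[ep_on + spec.episode_duration < spec.duration]
    ep_off = ep_on + spec.episode_duration
    burst_period = 1.0 / spec.burst_rate
    spikes, b_on, b_off = [], [], []
    bd = (spec.spikes_per_burst - 1) * spec.intra_burst_isi
    for on, off in zip(ep_on, ep_off):
        starts = np.arange(on, off - bd + 1e-12, burst_period)
        for s in starts:
            st = s + np.arange(spec.spikes_per_burst) * spec.intra_burst_isi
            spikes.extend(st)
            b_on.append(st[0])
            b_off.append(st[-1])
    return GroundTruth(np.asarray(spikes), np.asarray(b_on), np.asarray(b_off),
                       ep_on, ep_off)


def generate_synthetic_trace(spec: SyntheticTraceSpec
                             ) -> tuple[Trace, GroundTruth]:
    """Build the trace and return it with its exact ground truth."""
    rng = np.random.default_rng(spec.seed)
    truth = _layout(spec)
    n = int(round(spec.duration / spec.sample_dt)) + 1
    t = np.arange(n) * spec.sample_dt
    if spec.mode == "vm":
        sig = np.full(n, spec.baseline)
        half = spec.spike_width / 2.0
        for st in truth.spike_times:
            apex = st + half  # threshold crossings sit on the rising flank
            i0 = max(0, int(np.ceil((apex - half) / spec.sample_dt)))
            i1 = min(n - 1, int(np.floor((apex + half) / spec.sample_dt)))
            if i1 <= i0:
                continue
            tt = t[i0:i1 + 1]
            tri = 1.0 - np.abs(tt - apex) / half
            sig[i0:i1 + 1] = spec.baseline + spec.spike_amplitude * np.clip(tri, 0, 1)
    else:
        sig = np.zeros(n)
        for on, off in zip(truth.episode_onsets, truth.episode_offsets):
            sel = (t >= on) & (t < off)
            # burst-rate amplitude modulation inside the episode envelope
            sig[sel] = 1.0 + 0.5 * np.sin(
                2 * np.pi * spec.burst_rate * (t[sel] - on))
    if spec.drift_slope:
        sig = sig + spec.drift_slope * t
    if spec.noise_sd:
        sig = sig + rng.normal(0.0, spec.noise_sd, size=n)
    channel = "Vm1" if spec.mode == "vm" else "dc1"
    trace = Trace(t0=0.0, sample_dt=spec.sample_dt, channels=(channel,),
                  data=sig[:, None],
                  meta={"synthetic": True, "spec": spec, "seed": spec.seed})
    return trace, truth
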