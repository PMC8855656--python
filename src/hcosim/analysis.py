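"""Rhythm analysis: spike -> burst -> episode segmentation and metrics.

The hierarchy mirrors how the traces are read in the electrophysiology
this model emulates.  Spikes are upward threshold crossings of the
membrane potential; maximal runs of spikes whose inter-spike intervals
stay below a gap form bursts; maximal runs of bursts whose inter-burst
gaps stay below a (much larger) episode gap form episodes.  From the
segmentation come the burst metrics (BP period, BD duration, IBI
interval) and the episode metrics (EP period, ED duration, IEI
interepisode interval, EP-CV regularity), with the identities
BP = BD + IBI and EP = ED + IEI holding by construction.

Defaults (threshold -20 mV, refractory 3 ms, burst gap 0.3 s, episode
gap 4 s) are set for the model's canonical output, where the gap
spectrum is strongly bimodal: intra-episode inter-burst gaps sit well
below a second, interepisode intervals in the tens of seconds.

For experimental-style DC neurograms, :func:`neurogram_envelope`
implements the standard pipeline: linear detrend, zero-phase 0.01-1 Hz
band-pass, Gaussian-weighted moving average and hysteresis onset/offset
detection on the envelope.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import signal as _signal

from .simulator import Trace

__all__ = [
    "SpikeTrain", "Burst", "Episode", "RhythmMetrics", "RegimeLabel",
    "AnalysisConfig", "detect_spikes", "segment_bursts", "segment_episodes",
    "rhythm_metrics", "analyze_trace", "classify_regime", "neurogram_envelope",
]


class RegimeLabel(str, Enum):
    SILENCE = "silence"
    CONTINUOUS = "continuous"
    EPISODIC = "episodic"
    MIXED = "mixed"


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds of the segmentation pipeline."""

    spike_threshold: float = -20.0   # mV, upward crossing
    refractory: float = 0.003        # s
    burst_isi_gap: float = 0.3       # s, max ISI within a burst
    min_spikes_per_burst: int = 2
    episode_gap: float = 4.0         # s, min quiet gap between episodes
    min_bursts_per_episode: int = 2


@dataclass
class SpikeTrain:
    times: np.ndarray                # strictly increasing spike times (s)
    threshold: float
    channel: str = "Vm1"

    def __len__(self):
        return len(self.times)


@dataclass
class Burst:
    onset: float
    offset: float
    n_spikes: int

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class Episode:
    onset: float
    offset: float
    bursts: list[Burst]

    @property
    def duration(self) -> float:
        return self.offset - self.onset


def _series_stats(x: np.ndarray) -> dict:
    if len(x) == 0:
        return {"mean": np.nan, "sd": np.nan, "cv": np.nan, "n": 0}
    m = float(np.mean(x))
    sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
    return {"mean": m, "sd": sd, "cv": sd / m if m != 0 else np.nan, "n": len(x)}


@dataclass
class RhythmMetrics:
    """Burst and episode interval series with summary statistics.

    Interval series follow the usual conventions: BP_k is the onset-to-onset
    period of bursts within one episode, EP_j the onset-to-onset period of
    episodes.  ``intra_episode_bp`` holds, per episode, the BP of the first
    and second burst cycle, the last complete cycle, and the mean BP of each
    episode half.
    """

    bursts: list[Burst] = field(default_factory=list)
    episodes: list[Episode] = field(default_factory=list)
    BP: np.ndarray = field(default_factory=lambda: np.empty(0))
    BD: np.ndarray = field(default_factory=lambda: np.empty(0))
    IBI: np.ndarray = field(default_factory=lambda: np.empty(0))
    EP: np.ndarray = field(default_factory=lambda: np.empty(0))
    ED: np.ndarray = field(default_factory=lambda: np.empty(0))
    IEI: np.ndarray = field(default_factory=lambda: np.empty(0))
    intra_episode_bp: list[dict] = field(default_factory=list)

    @property
    def summary(self) -> dict:
        out = {}
        for name in ("BP", "BD", "IBI", "EP", "ED", "IEI"):
            out[name] = _series_stats(getattr(self, name))
        out["episode_stats_defined"] = len(self.episodes) >= 2
        return out


def detect_spikes(trace: Trace, channel: str = "Vm1",
                  threshold: float = -20.0, refractory: float = 0.003
                  ) -> SpikeTrain:
    """One spike per upward threshold crossing, refractory-filtered.

    Spike times are linearly interpolated between the samples bracketing
    the crossing.
    """
    v = trace[channel]
    t = trace.times
    dt = trace.sample_dt
    if dt <= 0:
        raise ValueError("trace must have a uniform positive sample_dt")
    below = v[:-1] < threshold
    above = v[1:] >= threshold
    idx = np.flatnonzero(below & above)
    if len(idx) == 0:
        return SpikeTrain(np.empty(0), threshold, channel)
    frac = (threshold - v[idx]) / (v[idx + 1] - v[idx])
    times = t[idx] + frac * dt
    keep = [0]
    for i in range(1, len(times)):
        if times[i] - times[keep[-1]] >= refractory:
            keep.append(i)
    return SpikeTrain(times[keep], threshold, channel)


def segment_bursts(spikes: SpikeTrain, isi_gap: float = 0.3,
                   min_spikes: int = 2) -> list[Burst]:
    """Maximal runs of spikes with consecutive ISIs below ``isi_gap``."""
    t = spikes.times
    if len(t) == 0:
        return []
    breaks = np.flatnonzero(np.diff(t) >= isi_gap)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(t) - 1]])
    return [Burst(onset=float(t[s]), offset=float(t[e]), n_spikes=int(e - s + 1))
            for s, e in zip(starts, ends) if e - s + 1 >= min_spikes]


def segment_episodes(bursts: list[Burst], episode_gap: float = 4.0,
                     min_bursts: int = 2) -> list[Episode]:
    """Maximal runs of bursts with inter-burst gaps below ``episode_gap``."""
    if not bursts:
        return []
    groups: list[list[Burst]] = [[bursts[0]]]
    for b in bursts[1:]:
        if b.onset - groups[-1][-1].offset < episode_gap:
            groups[-1].append(b)
        else:
            groups.append([b])
    return [Episode(onset=g[0].onset, offset=g[-1].offset, bursts=g)
            for g in groups if len(g) >= min_bursts]


def rhythm_metrics(bursts: list[Burst], episodes: list[Episode]
                   ) -> RhythmMetrics:
    """All interval series and the intra-episode burst-period profile."""
    m = RhythmMetrics(bursts=bursts, episodes=episodes)
    # burst metrics within episodes (BP defined between bursts of one episode)
    bp, bd, ibi = [], [], []
    for ep in episodes:
        on = np.array([b.onset for b in ep.bursts])
        off = np.array([b.offset for b in ep.bursts])
        bd.extend(off - on)
        if len(on) > 1:
            bp.extend(np.diff(on))
            ibi.extend(on[1:] - off[:-1])
        prof = {}
        if len(on) > 1:
            periods = np.diff(on)
            prof["first"] = float(periods[0])
            prof["second"] = float(periods[1]) if len(periods) > 1 else np.nan
            prof["last"] = float(periods[-1])
            half = max(1, len(periods) // 2)
            prof["bin1"] = float(np.mean(periods[:half]))
            prof["bin2"] = float(np.mean(periods[half:])) if len(periods) > half else np.nan
            m.intra_episode_bp.append(prof)
    m.BP, m.BD, m.IBI = (np.asarray(x) for x in (bp, bd, ibi))
    if episodes:
        on = np.array([e.onset for e in episodes])
        off = np.array([e.offset for e in episodes])
        m.ED = off - on
        if len(on) > 1:
            m.EP = np.diff(on)
            m.IEI = on[1:] - off[:-1]
    return m


def analyze_trace(trace: Trace, channel: str = "Vm1",
                  config: AnalysisConfig | None = None) -> RhythmMetrics:
    """Full pipeline: spikes -> bursts -> episodes -> metrics."""
    cfg = config or AnalysisConfig()
    spikes = detect_spikes(trace, channel, cfg.spike_threshold, cfg.refractory)
    bursts = segment_bursts(spikes, cfg.burst_isi_gap, cfg.min_spikes_per_burst)
    episodes = segment_episodes(bursts, cfg.episode_gap,
                                cfg.min_bursts_per_episode)
    return rhythm_metrics(bursts, episodes)


def classify_regime(trace: Trace, channel: str = "Vm1",
                    config: AnalysisConfig | None = None) -> RegimeLabel:
    """Label a post-transient trace.

    silence: no spikes at all; continuous: spiking/bursting with no quiet
    gap of at least the episode gap; episodic: at least two episodes
    separated by such gaps; mixed: anything in between (e.g. a single
    onset or offset caught in the window).
    """
    cfg = config or AnalysisConfig()
    spikes = detect_spikes(trace, channel, cfg.spike_threshold, cfg.refractory)
    if len(spikes) == 0:
        return RegimeLabel.SILENCE
    bursts = segment_bursts(spikes, cfg.burst_isi_gap, cfg.min_spikes_per_burst)
    if not bursts:
        return RegimeLabel.SILENCE if len(spikes) < 3 else RegimeLabel.MIXED
    # quiet gaps: before first burst, between bursts, after last burst
    t_end = trace.t0 + trace.duration
    gaps = [bursts[0].onset - trace.t0]
    gaps.extend(b2.onset - b1.offset for b1, b2 in zip(bursts, bursts[1:]))
    gaps.append(t_end - bursts[-1].offset)
    inner = gaps[1:-1]
    if not any(g >= cfg.episode_gap for g in gaps):
        return RegimeLabel.CONTINUOUS
    episodes = segment_episodes(bursts, cfg.episode_gap, min_bursts=1)
    n_inner_gaps = sum(g >= cfg.episode_gap for g in inner)
    if len(episodes) >= 2 and n_inner_gaps >= 1:
        return RegimeLabel.EPISODIC
    return RegimeLabel.MIXED


def neurogram_envelope(sig: np.ndarray, fs: float,
                       band: tuple[float, float] = (0.01, 1.0),
                       smooth_sigma: float = 0.5,
                       on_frac: float = 0.5, off_frac: float = 0.2) -> dict:
    """Episode detection on a DC neurogram-style signal.

    Pipeline: linear detrend -> zero-phase band-pass (2nd-order
    Butterworth, ``band`` in Hz) -> Gaussian-weighted moving average
    (sigma in s) -> hysteresis threshold on the smoothed signal, on at
    ``on_frac`` and off at ``off_frac`` of the robust amplitude (median
    to 95th percentile).  Episodes appear as positive excursions of the
    band-passed signal, interepisode intervals as negative ones.

    Returns the envelope and the episode onset/offset times.
    """
    sig = np.asarray(sig, dtype=float)
    if fs < 2.0 * band[1]:
        raise ValueError("sampling rate must be at least twice the band edge")
    n = len(sig)
    warn = n / fs < 3.0 / band[0]
    x = _signal.detrend(sig, type="linear")
    nyq = fs / 2.0
    sos = _signal.butter(2, [band[0] / nyq, band[1] / nyq], btype="band",
                         output="sos")
    x = _signal.sosfiltfilt(sos, x)
    width = int(round(6 * smooth_sigma * fs)) | 1
    g = _signal.windows.gaussian(width, smooth_sigma * fs)
    g /= g.sum()
    env = _signal.convolve(x, g, mode="same")
    lo = np.median(env)
    hi = np.percentile(env, 95)
    amp = hi - lo
    # degenerate signals (constant, pure trend) leave only numerical dust
    scale = max(1.0, float(np.max(np.abs(sig))))
    if amp < 1e-9 * scale:
        return {"envelope": env, "onsets": np.empty(0),
                "offsets": np.empty(0),
                "low_frequency_unreliable": bool(warn)}
    on_th = lo + on_frac * amp
    off_th = lo + off_frac * amp
    onsets, offsets = [], []
    active = False
    for i in range(n):
        if not active and env[i] >= on_th:
            active = True
            onsets.append(i / fs)
        elif active and env[i] < off_th:
            active = False
            offsets.append(i / fs)
    if active:
        offsets.append((n - 1) / fs)
    return {"envelope": env, "onsets": np.asarray(onsets),
            "offsets": np.asarray(offsets),
            "low_frequency_unreliable": bool(warn)}


def episode_metrics_from_onsets(onsets: np.ndarray, offsets: np.ndarray) -> dict:
    """EP/ED/IEI summaries from envelope-detected onset/offset times."""
    onsets = np.asarray(onsets, float)
    offsets = np.asarray(offsets, float)
    k = min(len(onsets), len(offsets))
    onsets, offsets = onsets[:k], offsets[:k]
    ED = offsets - onsets
    EP = np.diff(onsets)
    IEI = onsets[1:] - offsets[:-1]
    return {"EP": _series_stats(EP), "ED": _series_stats(ED),
            "IEI": _series_stats(IEI)}
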