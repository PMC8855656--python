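"""Segmentation and metric tests against constructed ground truth."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import hcosim as H
from hcosim.analysis import (AnalysisConfig, Burst, RegimeLabel,
                             episode_metrics_from_onsets, neurogram_envelope,
                             rhythm_metrics, segment_bursts, segment_episodes)
from hcosim.simulator import Trace
from hcosim.synth import SyntheticTraceSpec, generate_synthetic_trace


def _vm_trace(v, dt=1e-3):
    return Trace(t0=0.0, sample_dt=dt, channels=("Vm1",),
                 data=np.asarray(v, float)[:, None])


class TestDetectSpikes:
    def test_constant_trace_empty(self):
        tr = _vm_trace(np.full(1000, -60.0))
        assert len(H.detect_spikes(tr)) == 0

    def test_threshold_above_max_empty(self, synthetic_vm):
        tr, _ = synthetic_vm
        assert len(H.detect_spikes(tr, threshold=50.0)) == 0

    def test_triangular_spikes_at_known_times(self):
        spec = SyntheticTraceSpec(mode="vm", duration=2.0, episode_period=1.5,
                                  episode_duration=0.9, burst_rate=2.0,
                                  spikes_per_burst=5, seed=0)
        tr, truth = generate_synthetic_trace(spec)
        got = H.detect_spikes(tr, threshold=-20.0)
        assert len(got) == len(truth.spike_times)
        # crossing of -20 mV sits on the rising flank within the spike width
        np.testing.assert_allclose(got.times, truth.spike_times,
                                   atol=spec.spike_width)

    def test_refractory_suppresses_double_counts(self):
        t = np.arange(0, 1, 1e-4)
        v = np.full_like(t, -60.0)
        # a noisy double crossing 1 ms apart must count once
        for tt in (0.5, 0.501):
            v[np.abs(t - tt) < 2e-4] = 0.0
        got = H.detect_spikes(_vm_trace(v, 1e-4), refractory=0.003)
        assert len(got) == 1


class TestSegmentation:
    def test_empty_spike_train(self):
        train = H.SpikeTrain(np.empty(0), -20.0)
        assert segment_bursts(train) == []

    def test_three_burst_arithmetic(self):
        # 3 groups of 5 spikes, intra-ISI 0.05 s, separated by 0.6 s
        groups = [np.arange(5) * 0.05 + off for off in (0.0, 0.8, 1.6)]
        train = H.SpikeTrain(np.concatenate(groups), -20.0)
        bursts = segment_bursts(train, isi_gap=0.3, min_spikes=2)
        assert len(bursts) == 3
        for b in bursts:
            assert b.duration == pytest.approx(0.2)
            assert b.n_spikes == 5
        ibis = [b2.onset - b1.offset for b1, b2 in zip(bursts, bursts[1:])]
        assert ibis == pytest.approx([0.6, 0.6])

    def test_min_spikes_drops_isolated(self):
        train = H.SpikeTrain(np.array([0.0, 0.05, 0.1, 5.0]), -20.0)
        bursts = segment_bursts(train, isi_gap=0.3, min_spikes=2)
        assert len(bursts) == 1 and bursts[0].n_spikes == 3

    def test_single_cluster_single_episode(self):
        bursts = [Burst(0.0, 0.2, 5), Burst(1.0, 1.2, 5)]
        eps = segment_episodes(bursts, episode_gap=4.0)
        assert len(eps) == 1
        m = rhythm_metrics(bursts, eps)
        assert len(m.IEI) == 0 and len(m.EP) == 0

    def test_constructed_episode_arithmetic(self):
        # episodes at 0, 50, 100 s each lasting 20 s with bursts every 1 s
        bursts = []
        for on in (0.0, 50.0, 100.0):
            bursts += [Burst(on + k, on + k + 0.4, 4) for k in range(20)]
        eps = segment_episodes(bursts, episode_gap=4.0)
        assert len(eps) == 3
        m = rhythm_metrics(bursts, eps)
        np.testing.assert_allclose(m.EP, [50.0, 50.0])
        np.testing.assert_allclose(m.ED, 19.4)
        np.testing.assert_allclose(m.IEI, [30.6, 30.6])
        assert np.std(m.EP) / np.mean(m.EP) == pytest.approx(0.0)

    def test_reconstruction_identities(self):
        bursts = []
        for on in (10.0, 60.0, 110.0, 160.0):
            bursts += [Burst(on + 0.7 * k, on + 0.7 * k + 0.3, 3)
                       for k in range(10)]
        eps = segment_episodes(bursts, episode_gap=4.0)
        m = rhythm_metrics(bursts, eps)
        np.testing.assert_allclose(m.EP, m.ED[:-1] + m.IEI, rtol=1e-12)
        # per-episode: BP = BD + IBI for consecutive bursts
        for ep in eps:
            on = np.array([b.onset for b in ep.bursts])
            off = np.array([b.offset for b in ep.bursts])
            np.testing.assert_allclose(np.diff(on),
                                       (off - on)[:-1] + (on[1:] - off[:-1]),
                                       rtol=1e-12)


class TestGroundTruthRecovery:
    def test_exact_recovery_on_noise_free_fixture(self, synthetic_vm):
        tr, truth = synthetic_vm
        m = H.analyze_trace(tr, config=AnalysisConfig(burst_isi_gap=0.3,
                                                      episode_gap=4.0))
        assert len(m.episodes) == len(truth.episode_onsets)
        got_on = np.array([e.onset for e in m.episodes])
        np.testing.assert_allclose(got_on, truth.episode_onsets, atol=0.005)
        np.testing.assert_allclose(np.diff(got_on),
                                   np.diff(truth.episode_onsets), atol=0.005)

    @given(ep=st.floats(20, 120), duty=st.floats(0.2, 0.8),
           rate=st.floats(0.5, 3.0))
    @settings(max_examples=15, deadline=None)
    def test_recovery_property(self, ep, duty, rate):
        """Noise-free segmentation recovers every episode onset/offset to
        within one sample for generator settings across the realistic range."""
        ed = duty * ep
        spec = SyntheticTraceSpec(mode="vm", duration=3 * ep + 10,
                                  episode_period=ep, episode_duration=ed,
                                  burst_rate=rate, sample_dt=1e-3, seed=0)
        tr, truth = generate_synthetic_trace(spec)
        if len(truth.episode_onsets) < 2:
            return
        # burst gap strictly between the intra-burst ISI (0.05 s) and the
        # shortest inter-burst gap (1/rate - 0.2 >= 0.13 s)
        m = H.analyze_trace(tr, config=AnalysisConfig(
            burst_isi_gap=0.06, episode_gap=min(4.0, 0.5 * (ep - ed))))
        assert len(m.episodes) == len(truth.episode_onsets)
        got_on = np.array([e.onset for e in m.episodes])
        got_off = np.array([e.offset for e in m.episodes])
        np.testing.assert_allclose(got_on, truth.episode_onsets, atol=0.01)
        exp_off = [truth.burst_offsets[(truth.burst_onsets >= on - 1e-9)
                                       & (truth.burst_offsets <= off + 1e-9)].max()
                   for on, off in zip(truth.episode_onsets,
                                      truth.episode_offsets)]
        np.testing.assert_allclose(got_off, exp_off, atol=0.01)


class TestClassification:
    def test_silence(self):
        tr = _vm_trace(np.full(5000, -60.0))
        assert H.classify_regime(tr) is RegimeLabel.SILENCE

    def test_episodic_label_on_fixture(self, synthetic_vm):
        tr, _ = synthetic_vm
        assert H.classify_regime(tr) is RegimeLabel.EPISODIC

    def test_continuous_fixture(self):
        spec = SyntheticTraceSpec(mode="vm", duration=200.0,
                                  episode_period=199.0,
                                  episode_duration=198.0, burst_rate=1.0,
                                  seed=0)
        tr, _ = generate_synthetic_trace(spec)
        assert H.classify_regime(tr) is RegimeLabel.CONTINUOUS

    def test_stability_to_episode_gap_choice(self, short_hco_trace):
        """The gap spectrum of the canonical model is bimodal, so the
        label is insensitive to the episode-gap threshold."""
        labels = {
            H.classify_regime(short_hco_trace,
                              config=AnalysisConfig(episode_gap=g)).value
            for g in (2.0, 4.0, 8.0)}
        assert labels == {"episodic"}


class TestNeurogramEnvelope:
    def test_linear_ramp_killed(self):
        fs = 20.0
        t = np.arange(0, 400, 1 / fs)
        env = neurogram_envelope(0.05 * t, fs)
        assert np.max(env["envelope"]) < 1e-6
        assert len(env["onsets"]) == 0 or len(env["onsets"]) < 3

    def test_constant_signal_no_onsets(self):
        env = neurogram_envelope(np.full(8000, 2.0), 20.0)
        assert len(env["onsets"]) == 0

    def test_square_episode_recovery(self, synthetic_neurogram):
        tr, truth = synthetic_neurogram
        fs = 1.0 / tr.sample_dt
        env = neurogram_envelope(tr["dc1"], fs)
        stats = episode_metrics_from_onsets(env["onsets"], env["offsets"])
        true_ep = np.diff(truth.episode_onsets).mean()
        true_ed = (truth.episode_offsets - truth.episode_onsets).mean()
        assert stats["EP"]["mean"] == pytest.approx(true_ep, rel=0.02)
        assert stats["ED"]["mean"] == pytest.approx(true_ed, rel=0.10)

    def test_short_record_flagged(self):
        env = neurogram_envelope(np.random.default_rng(0).normal(size=2000),
                                 20.0)
        assert env["low_frequency_unreliable"]
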