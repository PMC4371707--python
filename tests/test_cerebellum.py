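"""Cerebellar microcomplex: lookback, storage rules, corrections, RBF recall."""

import numpy as np
import pytest

from cbreach.cerebellum import (
    CONTEXT_DIM,
    CerebellarStore,
    FeatureEntry,
    HistoryBuffer,
    Microcomplex,
    context_lookback_time,
    correction_from_efference,
    correction_from_muscle,
    correction_model4,
    pack_context,
)
from cbreach.olive import SpikeEvent


class TestLookback:
    def test_standard_delays_give_150ms(self):
        # tau_v = 150 ms, tau_p = 25 ms, episode tail 50 ms -> 150 ms
        assert context_lookback_time(1.0, 1.050, 0.150, 0.025) == pytest.approx(0.150)

    def test_at_spike_time(self):
        assert context_lookback_time(1.0, 1.0, 0.150, 0.025) == pytest.approx(0.125)

    def test_at_episode_cap(self):
        assert context_lookback_time(1.0, 1.250, 0.150, 0.025) == pytest.approx(0.250)

    def test_episode_before_spike_rejected(self):
        with pytest.raises(ValueError):
            context_lookback_time(1.0, 0.9, 0.150, 0.025)


class TestHistoryBuffer:
    def test_nearest_lookup(self):
        h = HistoryBuffer(horizon=0.5)
        for k in range(100):
            h.record(k * 1e-3, context=np.array([float(k)]))
        assert h.lookup(0.0503)["context"][0] == 50.0

    def test_window_selection(self):
        h = HistoryBuffer(horizon=0.5)
        for k in range(100):
            h.record(k * 1e-3, efference=np.array([float(k)]))
        w = h.window(0.010, 0.020)
        assert [s["efference"][0] for s in w] == list(range(10, 21))


def _fill_history(micro, efference_fn, n=700, dt=1e-3):
    for k in range(n):
        t = k * dt
        ctx = np.full(CONTEXT_DIM, np.sin(t))
        eff = efference_fn(t)
        micro.observe(t, ctx, eff, l=np.full(11, 0.3 + 0.01 * np.sin(t)),
                      v=np.full(11, 0.01 * np.cos(t)))


class TestCorrections:
    def test_efference_average_constant(self):
        store = CerebellarStore(gamma_k=-1.0)
        micro = Microcomplex(store)
        c = np.arange(11.0)
        _fill_history(micro, lambda t: c)
        w = correction_from_efference(micro.history, 0.5, 0.6, 0.150, 0.025, gain=2.0)
        assert np.allclose(w, 2.0 * c)

    def test_efference_average_linear_ramp(self):
        store = CerebellarStore(gamma_k=-1.0)
        micro = Microcomplex(store)
        _fill_history(micro, lambda t: np.full(11, t))
        # ramp over the shifted window [t_cs - 0.125, t - 0.125]
        w = correction_from_efference(micro.history, 0.4, 0.6, 0.150, 0.025, gain=1.0)
        assert np.allclose(w, (0.275 + 0.475) / 2.0, atol=1e-3)

    def test_efference_empty_window_uses_start_sample(self):
        store = CerebellarStore(gamma_k=-1.0)
        micro = Microcomplex(store)
        _fill_history(micro, lambda t: np.full(11, t))
        w = correction_from_efference(micro.history, 0.4, 0.4, 0.150, 0.025)
        assert np.allclose(w, 0.275, atol=2e-3)

    def test_muscle_correction_one_hot(self):
        w = correction_from_muscle(3, 0.02)
        expected = np.zeros(11)
        expected[3] = 0.02
        assert np.array_equal(w, expected)
        assert np.array_equal(correction_from_muscle(5, 0.0), np.zeros(11))
        with pytest.raises(ValueError):
            correction_from_muscle(11, 0.02)

    def test_model4_product(self):
        lam = np.full(11, 0.30)
        l_avg = lam + 0.02
        ldot = np.full(11, 0.5)
        w = correction_model4(l_avg, lam, ldot, gain=1.0)
        assert np.allclose(w, 0.01)
        # positive parts gate both factors
        assert np.allclose(correction_model4(lam - 0.01, lam, ldot), 0.0)
        assert np.allclose(correction_model4(l_avg, lam, -ldot), 0.0)

    def test_model4_cap(self):
        lam = np.full(11, 0.30)
        w = correction_model4(lam + 0.1, lam, np.full(11, 1.0), gain=10.0, w_cap=0.04)
        assert np.allclose(w, 0.04)


class TestStoreOnSpike:
    def _micro(self, **kw):
        store = CerebellarStore(gamma_k=-1.0, fusion_threshold=1e-9, m_f=500)
        return Microcomplex(store, **kw), store

    def test_discard_after_250ms_episode(self):
        micro, store = self._micro()
        _fill_history(micro, lambda t: np.full(11, 0.1))
        micro.add_spikes([SpikeEvent(time=0.3, source="visual")])
        micro.handle_pending(0.551, edot=+1.0)   # still increasing past cap
        assert len(store) == 0 and micro.n_discarded == 1 and not micro.pending

    def test_store_with_lookback_feature(self):
        micro, store = self._micro()
        _fill_history(micro, lambda t: np.full(11, 0.1))
        micro.add_spikes([SpikeEvent(time=0.4, source="visual")])
        micro.handle_pending(0.5, edot=-0.1)
        assert len(store) == 1
        # lookback = 150 - 25 + 50 = 175 ms before the spike
        e = store.entries[0]
        assert e.t_feature == pytest.approx(0.4 - 0.175)
        assert np.allclose(e.f, np.full(CONTEXT_DIM, np.sin(0.225)), atol=1e-3)

    def test_pending_spike_waits_for_episode_end(self):
        micro, store = self._micro()
        _fill_history(micro, lambda t: np.full(11, 0.1))
        micro.add_spikes([SpikeEvent(time=0.4, source="visual")])
        micro.handle_pending(0.45, edot=+1.0)
        assert len(store) == 0 and len(micro.pending) == 1
        micro.handle_pending(0.5, edot=0.0)
        assert len(store) == 1 and not micro.pending

    def test_two_spikes_stored_independently(self):
        micro, store = self._micro()
        _fill_history(micro, lambda t: np.full(11, 0.1))
        micro.add_spikes([SpikeEvent(time=0.40, source="visual"),
                          SpikeEvent(time=0.45, source="visual")])
        micro.handle_pending(0.5, edot=-0.1)
        assert len(store) == 2

    def test_causal_metadata(self):
        # every stored entry's feature time precedes its spike
        micro, store = self._micro()
        _fill_history(micro, lambda t: np.full(11, 0.1))
        micro.add_spikes([SpikeEvent(time=0.4 + 0.01 * i, source="visual")
                          for i in range(5)])
        micro.handle_pending(0.5, edot=-0.1)
        for e in store.entries:
            assert e.t_feature < e.t_cs


class TestRecall:
    def literal_recall(self, store, v):
        """Second, literal transcription of the D / D_N / F formulas."""
        if not store.entries:
            return np.zeros(11)
        d = np.array(
            [np.sum(((e.f - v) * store.scales) ** 2) for e in store.entries]
        )
        norm = np.sqrt(np.sum(d * d))
        d_n = np.zeros_like(d) if norm == 0 else store.m_f * d / norm
        return sum(
            e.w * np.exp(store.gamma_k * dn) for e, dn in zip(store.entries, d_n)
        )

    def test_empty_store_returns_zero(self):
        store = CerebellarStore(gamma_k=-2.0)
        assert np.array_equal(store.recall(np.zeros(CONTEXT_DIM)), np.zeros(11))

    def test_exact_match_single_entry_returns_w(self, rng):
        store = CerebellarStore(gamma_k=-2.0)
        f = rng.normal(size=CONTEXT_DIM)
        w = rng.normal(size=11)
        store.add(FeatureEntry(f=f, w=w))
        assert np.allclose(store.recall(f), w)

    def test_equidistant_entries_weighted_equally(self, rng):
        store = CerebellarStore(gamma_k=-2.0, fusion_threshold=1e-12)
        v = np.zeros(CONTEXT_DIM)
        f = np.zeros(CONTEXT_DIM)
        f[2] = 0.3
        g = np.zeros(CONTEXT_DIM)
        g[3] = 0.3
        store.add(FeatureEntry(f=f, w=np.ones(11)))
        store.add(FeatureEntry(f=g, w=3 * np.ones(11)))
        out = store.recall(v)
        # equal kernel weights: output proportional to w1 + w2
        assert np.allclose(out / out[0] * 4.0, np.full(11, 4.0))

    def test_matches_literal_transcription_random_stores(self, rng):
        for _ in range(100):
            store = CerebellarStore(
                gamma_k=float(-rng.uniform(0.5, 8)), m_f=int(rng.integers(4, 64)),
                fusion_threshold=1e-12,
                scales=rng.uniform(0.5, 5.0, CONTEXT_DIM),
            )
            for _ in range(5):
                store.add(FeatureEntry(f=rng.normal(size=CONTEXT_DIM),
                                       w=rng.normal(size=11)))
            v = rng.normal(size=CONTEXT_DIM)
            assert np.allclose(store.recall(v), self.literal_recall(store, v),
                               atol=1e-10)

    def test_recall_bounded_by_total_correction_mass(self, rng):
        store = CerebellarStore(gamma_k=-1.0, fusion_threshold=1e-12)
        total = 0.0
        for _ in range(10):
            w = rng.normal(size=11)
            store.add(FeatureEntry(f=rng.normal(size=CONTEXT_DIM), w=w))
            total += np.linalg.norm(w)
        for _ in range(20):
            out = store.recall(rng.normal(size=CONTEXT_DIM))
            assert np.linalg.norm(out) <= total + 1e-9

    def test_positive_gamma_rejected(self):
        with pytest.raises(ValueError):
            CerebellarStore(gamma_k=0.5)


class TestFusion:
    def test_identical_parents_yield_same_child(self, rng):
        store = CerebellarStore(gamma_k=-1.0, fusion_threshold=0.5)
        f = rng.normal(size=CONTEXT_DIM)
        w = rng.normal(size=11)
        store.add(FeatureEntry(f=f, w=w))
        store.add(FeatureEntry(f=f.copy(), w=w.copy()))
        assert len(store) == 1
        assert np.allclose(store.entries[0].f, f)
        assert np.allclose(store.entries[0].w, w)

    def test_store_never_exceeds_mf(self, rng):
        store = CerebellarStore(gamma_k=-1.0, m_f=8, fusion_threshold=1e-12)
        for _ in range(100):
            store.add(FeatureEntry(f=rng.normal(size=CONTEXT_DIM),
                                   w=rng.normal(size=11)))
            assert len(store) <= 8
        assert len(store) == 8

    def test_child_on_segment_between_parents(self, rng):
        for _ in range(20):
            a = rng.uniform(0.1, 0.9)
            store = CerebellarStore(gamma_k=-1.0, fusion_threshold=100.0,
                                    fusion_midpoint=a)
            f1, f2 = rng.normal(size=(2, CONTEXT_DIM))
            w1, w2 = rng.normal(size=(2, 11))
            store.add(FeatureEntry(f=f1, w=w1))
            store.add(FeatureEntry(f=f2, w=w2))  # forced fusion (huge threshold)
            child = store.entries[0]
            assert np.allclose(child.f, (1 - a) * f1 + a * f2, atol=1e-12)
            assert np.allclose(child.w, (1 - a) * w1 + a * w2, atol=1e-12)


class TestSerialization:
    def test_store_round_trip(self, tmp_path, rng):
        store = CerebellarStore(gamma_k=-3.0, m_f=16, fusion_threshold=1e-12)
        for _ in range(5):
            store.add(FeatureEntry(f=rng.normal(size=CONTEXT_DIM),
                                   w=rng.normal(size=11), t_cs=1.0, t_feature=0.8))
        p = tmp_path / "store.json"
        store.to_json(p)
        loaded = CerebellarStore.from_json(p)
        v = rng.normal(size=CONTEXT_DIM)
        assert np.allclose(loaded.recall(v), store.recall(v), atol=1e-12)


class TestRecordOnlyCausality:
    def test_record_only_matches_connected_until_first_recall(self, cfg, geometry,
                                                              targets):
        # with the output disconnected, the stored entries are identical to a
        # connected run up to the moment recall first alters the trajectory
        from cbreach.runner import make_store, run_reach

        s_on = make_store("1", cfg)
        run_reach("1", targets[6], 0, cfg=cfg, geometry=geometry, store=s_on)
        s_off = make_store("1", cfg)
        run_reach("1", targets[6], 0, cfg=cfg, geometry=geometry, store=s_off,
                  record_only=True)
        n = min(len(s_on), len(s_off))
        assert n > 0
        agree = 0
        for a, b in zip(s_on.entries[:n], s_off.entries[:n]):
            if np.allclose(a.f, b.f, atol=1e-12) and np.allclose(a.w, b.w, atol=1e-12):
                agree += 1
            else:
                break
        assert agree >= 1
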