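"""Filtering, CDP detection, dictionary building, and classification."""

import numpy as np
import pytest

import cdpstates as cs
from cdpstates.waveform_dictionary import (
    CDPSnippet,
    bandpass_filter,
    build_dictionary,
    classify_events,
    classify_snippet,
    detect_events,
    match_templates,
    read_dictionary,
    write_dictionary,
)

from .conftest import aligned_true_templates, match_events_to_truth


def _recording(signal, fs=5000.0, channels=("chA",)):
    return cs.RawRecording(signal=np.atleast_2d(signal), fs=fs,
                           channel_ids=channels)


class TestBandpass:
    def test_dc_removed(self):
        rec = _recording(np.full(50_000, 10.0))
        out = bandpass_filter(rec)
        assert np.max(np.abs(out.signal)) < 0.1  # <1% of the DC input

    def test_passband_tone_preserved(self):
        t = np.arange(50_000) / 5000.0
        rec = _recording(np.sin(2 * np.pi * 100.0 * t))
        out = bandpass_filter(rec)
        mid = out.signal[0, 10_000:40_000]
        assert abs(mid.max() - 1.0) < 0.05

    def test_stopband_tone_attenuated(self):
        t = np.arange(50_000) / 5000.0
        rec = _recording(np.sin(2 * np.pi * 2000.0 * t))
        out = bandpass_filter(rec)
        mid = out.signal[0, 10_000:40_000]
        assert mid.max() < 10 ** (-20 / 20)  # >= 20 dB down

    def test_band_outside_nyquist_rejected(self):
        rec = _recording(np.zeros(1000))
        with pytest.raises(ValueError):
            bandpass_filter(rec, low=0.3, high=3000.0)


class TestDetectEvents:
    def test_all_zero_signal_empty(self):
        assert detect_events(_recording(np.zeros(10_000))) == []

    def test_dead_time_merges_close_events(self, rng):
        w = cs.render_waveform(cs.TemplateParams(amp_neg=50.0, width_neg_ms=10.0))
        x = rng.normal(0, 1.0, 20_000)
        for start in (5000, 5000 + 100):  # 20 ms apart at 5 kHz
            x[start:start + len(w)] += w
        snips = detect_events(_recording(x), threshold_k=4.0, dead_time_s=0.05)
        assert len(snips) == 1

    def test_boundary_events_dropped(self):
        w = cs.render_waveform(cs.TemplateParams(amp_neg=50.0, width_neg_ms=10.0))
        x = np.zeros(2000)
        x[:len(w)] += w  # peak < 50 ms from the start: no full snippet window
        assert detect_events(_recording(x), threshold_k=4.0) == []

    def test_recall_and_precision_on_synthetic(self, noisy_recording, small_state):
        rec, truth = noisy_recording
        snips = detect_events(bandpass_filter(rec), threshold_k=4.0,
                              dead_time_s=0.05)
        tp = fp = fn = 0
        for ch in small_state.channel_ids:
            tt = truth[truth.channel == ch].time_s.to_numpy()
            dd = [s.peak_time_s for s in snips if s.channel_id == ch]
            a, b, c = match_events_to_truth(dd, tt)
            tp, fp, fn = tp + a, fp + b, fn + c
        assert tp / (tp + fn) >= 0.95
        assert tp / (tp + fp) >= 0.95


class TestBuildDictionary:
    def _snippets_from_templates(self, templates, n_each, noise_frac, rng,
                                 channel="chA"):
        out = []
        t = 0.0
        for k, w in enumerate(templates):
            amp = np.abs(w).max()
            for _ in range(n_each):
                noisy = w + rng.normal(0, noise_frac * amp, w.size)
                out.append(CDPSnippet(waveform=noisy, peak_time_s=t, channel_id=channel))
                t += 1.0
        return out

    def test_three_separated_templates_recovered(self, rng):
        fs = 5000.0
        params = [cs.TemplateParams(kind="n", amp_neg=30.0, width_neg_ms=15.0),
                  cs.TemplateParams(kind="np", amp_neg=60.0, amp_pos=30.0,
                                    width_neg_ms=25.0),
                  cs.TemplateParams(kind="n", amp_neg=100.0, width_neg_ms=40.0)]
        true = np.stack([cs.align_template(cs.render_waveform(p, fs), fs)
                         for p in params])
        snips = self._snippets_from_templates(true, n_each=40, noise_frac=0.05,
                                              rng=rng)
        d = build_dictionary(snips, n_classes=3)
        mapping = match_templates(d, true)
        for cls, ref in mapping.items():
            r = np.corrcoef(d.templates[cls - 1], true[ref - 1])[0, 1]
            assert r >= 0.95
        assert set(mapping.values()) == {1, 2, 3}

    def test_twelve_class_dictionary_from_defaults(self, rng):
        fs = 5000.0
        state = cs.GenerativeState(channel_ids=("chA",))
        true = aligned_true_templates(state, fs)
        # uneven class abundances: class k gets 30 - k snippets
        snips = []
        for k, w in enumerate(true):
            snips += self._snippets_from_templates([w], n_each=30 - k,
                                                   noise_frac=0.03, rng=rng)
        d = build_dictionary(snips, n_classes=12)
        assert d.n_classes == 12
        assert d.templates.shape[0] == 12
        # classes ordered by descending control frequency
        assert all(d.control_counts[i] >= d.control_counts[i + 1]
                   for i in range(11))
        assert d.control_counts[0] == 30

    def test_too_few_snippets_rejected(self, rng):
        w = cs.render_waveform(cs.TemplateParams(amp_neg=40.0))
        snips = self._snippets_from_templates([w], n_each=5, noise_frac=0.01,
                                              rng=rng)
        with pytest.raises(ValueError):
            build_dictionary(snips, n_classes=3)

    def test_deterministic(self, rng):
        fs = 5000.0
        params = [cs.TemplateParams(kind="n", amp_neg=a) for a in (30.0, 80.0)]
        true = np.stack([cs.align_template(cs.render_waveform(p, fs), fs)
                         for p in params])
        snips = self._snippets_from_templates(true, 15, 0.05, rng)
        d1 = build_dictionary(snips, 2)
        d2 = build_dictionary(snips, 2)
        assert np.array_equal(d1.templates, d2.templates)


class TestClassification:
    def test_templates_classify_as_themselves(self, rng):
        fs = 5000.0
        state = cs.GenerativeState(channel_ids=("chA",))
        true = aligned_true_templates(state, fs)
        d = cs.Dictionary(channel_id="chA", templates=true,
                          control_counts=np.arange(12, 0, -1))
        for k in range(12):
            assert classify_snippet(true[k], d) == k + 1

    def test_length_mismatch_rejected(self):
        d = cs.Dictionary(channel_id="chA", templates=np.zeros((2, 100)) - 1.0,
                          control_counts=np.array([2, 1]))
        with pytest.raises(ValueError):
            classify_snippet(np.zeros(50), d)

    def test_noiseless_pipeline_reproduces_ground_truth_exactly(self):
        """Detection + classification at sigma=0 recovers every event."""
        sched = cs.ConditionSchedule(phases=(("control", 2),), step_length_s=120.0)
        state = cs.GenerativeState(channel_ids=("L5rL",), event_rate=1.0,
                                  sync_rho=0.0, noise_sigma=0.0, dead_time_s=0.4)
        rec, truth = cs.synthesize_recording(sched, state, seed=7)
        snips = detect_events(rec, threshold_k=4.0, dead_time_s=0.05)
        assert len(snips) == len(truth)
        dt = np.sort([s.peak_time_s for s in snips]) - np.sort(truth.time_s.to_numpy())
        assert np.max(np.abs(dt)) <= 1.0 / rec.fs
        d = build_dictionary(list(snips), 12)
        mapping = match_templates(d, aligned_true_templates(state, rec.fs))
        ev = classify_events(list(snips), d, sched)
        tt = truth.time_s.to_numpy()
        tc = truth["class"].to_numpy()
        for t, cl in zip(ev.time_s, ev["class"]):
            i = int(np.argmin(np.abs(tt - t)))
            assert tc[i] == mapping[cl]

    def test_noisy_pipeline_label_accuracy(self, noisy_recording, small_schedule,
                                           small_state):
        """At SNR >= 5 the end-to-end label accuracy stays above 0.90."""
        rec, truth = noisy_recording
        filt = bandpass_filter(rec)
        snips = detect_events(filt, threshold_k=4.0, dead_time_s=0.05)
        ch = "L5rL"
        ch_snips = [s for s in snips if s.channel_id == ch]
        control_end = 2 * small_schedule.step_length_s
        d = build_dictionary([s for s in ch_snips if s.peak_time_s < control_end], 12)
        mapping = match_templates(d, aligned_true_templates(small_state, rec.fs))
        ev = classify_events(ch_snips, d, small_schedule)
        sub = truth[truth.channel == ch]
        tt = sub.time_s.to_numpy()
        tc = sub["class"].to_numpy()
        hits = total = 0
        for t, cl in zip(ev.time_s, ev["class"]):
            i = int(np.argmin(np.abs(tt - t)))
            if abs(tt[i] - t) <= 0.01:
                total += 1
                hits += tc[i] == mapping[cl]
        assert total > 100
        assert hits / total >= 0.90

    def test_step_and_condition_assignment(self, small_schedule):
        snips = [CDPSnippet(waveform=np.array([-1.0, 0.0]), peak_time_s=t,
                            channel_id="chA") for t in (10.0, 100.0, 200.0, 300.0)]
        d = cs.Dictionary(channel_id="chA", templates=np.array([[-1.0, 0.0]]),
                          control_counts=np.array([4]))
        ev = classify_events(snips, d, small_schedule)
        assert ev["step"].tolist() == [1, 2, 3, 4]
        assert ev["condition"].tolist() == ["control", "control",
                                            "capsaicin", "capsaicin"]


def test_dictionary_json_roundtrip(tmp_path):
    d = cs.Dictionary(channel_id="L5rL", templates=np.arange(12.0).reshape(3, 4) - 6,
                      control_counts=np.array([5, 3, 2]))
    path = tmp_path / "dict.json"
    write_dictionary(path, d)
    back = read_dictionary(path)
    assert back.channel_id == d.channel_id
    assert np.allclose(back.templates, d.templates)
    assert np.array_equal(back.control_counts, d.control_counts)
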