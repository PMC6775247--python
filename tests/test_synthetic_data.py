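"""Generator tests: Markov sampling, waveform rendering, recording synthesis."""

import numpy as np
import pandas as pd
import pytest

import cdpstates as cs
from cdpstates.synthetic_data import _renewal_times


class TestConditionSchedule:
    def test_step_bookkeeping(self):
        s = cs.ConditionSchedule(phases=(("control", 3), ("capsaicin", 2)),
                                 step_length_s=10.0)
        assert s.n_steps == 5
        assert s.total_s == 50.0
        assert s.step_conditions == ["control"] * 3 + ["capsaicin"] * 2
        assert s.step_of(0.0) == 0
        assert s.step_of(29.999) == 2
        assert s.phase_position(3) == ("capsaicin", 0, 2)

    @pytest.mark.parametrize("phases", [(), (("control", 0),), (("nope", 3),)])
    def test_invalid_phases_rejected(self, phases):
        with pytest.raises(ValueError):
            cs.ConditionSchedule(phases=phases)


class TestSampleClassSequence:
    def test_single_state_chain(self):
        seq = cs.sample_class_sequence(np.array([[1.0]]), 5, 0)
        assert seq.tolist() == [1, 1, 1, 1, 1]

    def test_deterministic_alternation(self):
        P = np.array([[0.0, 1.0], [1.0, 0.0]])
        seq = cs.sample_class_sequence(P, 4, 0, initial=np.array([1.0, 0.0]))
        assert seq.tolist() == [1, 2, 1, 2]

    def test_empirical_transition_frequencies_match(self, rng):
        # ~830 visits per row at n=10,000 put the per-cell standard error
        # near 0.017; 0.04 bounds the max over all 144 cells for this seed
        P = rng.dirichlet(np.ones(12), size=12)
        seq = cs.sample_class_sequence(P, 10_000, 42)
        m = cs.fit_markov(seq, 12)
        observed = m.observed_rows
        assert np.max(np.abs(m.transition_probs[observed] - P[observed])) < 0.04

    def test_non_stochastic_matrix_rejected(self):
        with pytest.raises(ValueError):
            cs.sample_class_sequence(np.array([[0.5, 0.4], [0.5, 0.5]]), 10, 0)

    def test_seed_reproducibility(self):
        P = cs.preset_transition_matrix("control")
        a = cs.sample_class_sequence(P, 500, 7)
        b = cs.sample_class_sequence(P, 500, 7)
        assert np.array_equal(a, b)

    def test_marginals_converge_to_stationary(self):
        P = cs.preset_transition_matrix("capsaicin")
        pi = cs.stationary_distribution(P)
        seq = cs.sample_class_sequence(P, 100_000, 5)
        freq = np.bincount(seq, minlength=13)[1:] / seq.size
        assert np.abs(freq - pi).sum() < 0.01


class TestPresets:
    @pytest.mark.parametrize("kind", ["control", "capsaicin", "spinal"])
    def test_row_stochastic_and_positive(self, kind):
        P = cs.preset_transition_matrix(kind)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-9)
        assert P.min() > 0.01  # uniform floor keeps all transitions possible

    def test_control_favors_small_classes_capsaicin_large(self):
        pc = cs.stationary_distribution(cs.preset_transition_matrix("control"))
        pk = cs.stationary_distribution(cs.preset_transition_matrix("capsaicin"))
        # small CDP classes (low indices) dominate control; capsaicin boosts
        # the largest classes
        assert pc[:4].sum() > pk[:4].sum()
        assert pk[-4:].sum() > pc[-4:].sum()


class TestRenderWaveform:
    def test_zero_amplitude_gives_zero_trace(self):
        w = cs.render_waveform(cs.TemplateParams(kind="n", amp_neg=0.0))
        assert np.allclose(w, 0.0)

    def test_ncdp_single_negative_extremum(self):
        w = cs.render_waveform(cs.TemplateParams(kind="n", amp_neg=50.0,
                                                 width_neg_ms=30.0), fs=5000)
        # exactly one falling-to-rising sign change (a single trough,
        # tolerating the sample-grid plateau at the extremum)
        d = np.sign(np.diff(w))
        d = d[d != 0]
        assert np.sum((d[:-1] < 0) & (d[1:] > 0)) == 1
        assert abs(w[0]) < 0.5 and abs(w[-1]) < 0.5
        assert np.isclose(w.min(), -50.0, atol=0.01)

    def test_npcdp_negative_before_positive(self):
        w = cs.render_waveform(cs.TemplateParams(kind="np", amp_neg=40.0,
                                                 amp_pos=20.0))
        assert np.argmin(w) < np.argmax(w)
        assert np.isclose(w.min(), -40.0, atol=0.01)
        assert np.isclose(w.max(), 20.0, atol=0.01)

    @pytest.mark.parametrize("pre,sign", [("neg", -1.0), ("pos", 1.0)])
    def test_slow_pre_component_sign(self, pre, sign):
        p = cs.TemplateParams(kind="n", amp_neg=50.0, pre=pre, pre_amp=15.0)
        w = cs.render_waveform(p)
        n_pre = int(round(p.pre_width_ms * 1e-3 * 5000))
        assert sign * w[:n_pre].sum() > 0

    def test_nonfinite_parameters_rejected(self):
        with pytest.raises(ValueError):
            cs.TemplateParams(amp_neg=np.nan)


class TestSynthesizeRecording:
    def test_single_noiseless_event_equals_template(self):
        # force exactly the template at the event time, zero elsewhere
        sched = cs.ConditionSchedule(phases=(("control", 1),), step_length_s=20.0)
        state = cs.GenerativeState(channel_ids=("L5rL",), event_rate=0.08,
                                   sync_rho=0.0, noise_sigma=0.0, dead_time_s=0.05)
        rec, truth = cs.synthesize_recording(sched, state, seed=1)
        assert len(truth) >= 1
        x = rec.signal[0].astype(float)
        total = 0.0
        for row in truth.itertuples(index=False):
            w = cs.render_waveform(state.templates[int(row[2]) - 1], rec.fs)
            total += np.abs(w).sum()
        assert np.isclose(np.abs(x).sum(), total, rtol=1e-4)

    def test_sync_rho_one_shares_event_times(self):
        sched = cs.ConditionSchedule(phases=(("control", 1),), step_length_s=30.0)
        state = cs.GenerativeState(channel_ids=("L5rL", "L6rL"), event_rate=2.0,
                                   sync_rho=1.0, noise_sigma=0.0)
        truth = cs.synthesize_events(sched, state, seed=2)
        t1 = truth[truth.channel == "L5rL"].time_s.to_numpy()
        t2 = truth[truth.channel == "L6rL"].time_s.to_numpy()
        assert np.array_equal(t1, t2)

    def test_event_count_near_rate_times_duration(self):
        sched = cs.ConditionSchedule(phases=(("control", 1),), step_length_s=200.0)
        state = cs.GenerativeState(channel_ids=("L5rL",), event_rate=3.0,
                                   sync_rho=0.0, noise_sigma=0.0)
        truth = cs.synthesize_events(sched, state, seed=9)
        expected = 3.0 * 200.0
        assert abs(len(truth) - expected) < 4 * np.sqrt(expected)

    def test_bit_reproducible_under_fixed_seed(self, small_schedule, small_state):
        r1, t1 = cs.synthesize_recording(small_schedule, small_state, seed=5)
        r2, t2 = cs.synthesize_recording(small_schedule, small_state, seed=5)
        assert np.array_equal(r1.signal, r2.signal)
        pd.testing.assert_frame_equal(t1, t2)

    def test_event_times_respect_dead_time(self):
        sched = cs.ConditionSchedule(phases=(("control", 1),), step_length_s=100.0)
        state = cs.GenerativeState(channel_ids=("L5rL", "L6rL"), event_rate=8.0,
                                   sync_rho=0.5, noise_sigma=0.0, dead_time_s=0.05)
        truth = cs.synthesize_events(sched, state, seed=4)
        for ch in state.channel_ids:
            t = truth[truth.channel == ch].time_s.to_numpy()
            assert np.all(np.diff(t) >= 0.05 - 1e-12)

    def test_incompatible_rate_and_dead_time_rejected(self):
        with pytest.raises(ValueError):
            cs.GenerativeState(channel_ids=("a",), event_rate=25.0, dead_time_s=0.05)


def test_renewal_rate_matches_nominal():
    rng = np.random.default_rng(0)
    times = _renewal_times(rate=5.0, dead=0.05, t0=0.0, t1=400.0, rng=rng)
    assert abs(times.size - 2000) < 4 * np.sqrt(2000)
    assert np.all(np.diff(times) >= 0.05)


def test_lidocaine_phase_restores_then_relapses():
    sched = cs.ConditionSchedule(phases=(("control", 2), ("capsaicin", 3),
                                         ("lidocaine1", 10), ("spinal", 1)),
                                 step_length_s=60.0)
    state = cs.GenerativeState(channel_ids=("a",))
    regimes = [state.regime_of_step(sched, s) for s in range(sched.n_steps)]
    assert regimes[:2] == ["control"] * 2
    assert regimes[2:5] == ["capsaicin"] * 3
    # restore_fraction=0.8 of 10 lidocaine steps are control-like, the tail relapses
    assert regimes[5:13] == ["control"] * 8
    assert regimes[13:15] == ["capsaicin", "capsaicin"]
    assert regimes[15] == "spinal"
    Pc = state.transition_matrices["control"]
    assert np.allclose(state.step_transition_matrix(sched, 5), Pc)


def test_h5_roundtrip(tmp_path, small_schedule, small_state):
    rec, _ = cs.synthesize_recording(small_schedule, small_state, seed=1)
    path = tmp_path / "rec.h5"
    cs.synthetic_data.write_recording_h5(path, rec)
    back = cs.synthetic_data.read_recording_h5(path)
    assert back.fs == rec.fs
    assert back.channel_ids == rec.channel_ids
    assert np.array_equal(back.signal, rec.signal)
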