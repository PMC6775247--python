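import numpy as np
import pytest

import cdpstates as cs


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_schedule():
    """Two control + two capsaicin steps of 90 s."""
    return cs.ConditionSchedule(phases=(("control", 2), ("capsaicin", 2)),
                                step_length_s=90.0)


@pytest.fixture(scope="session")
def small_state():
    """Two channels, moderate rate, SNR >= 5 (min amplitude 20 µV, noise 4 µV)."""
    return cs.GenerativeState(channel_ids=("L5rL", "L6rL"), event_rate=1.5,
                              sync_rho=0.2, noise_sigma=4.0, dead_time_s=0.3)


@pytest.fixture(scope="session")
def noisy_recording(small_schedule, small_state):
    """One seeded synthetic recording shared by the extraction tests."""
    rec, truth = cs.synthesize_recording(small_schedule, small_state, seed=3)
    return rec, truth


def aligned_true_templates(state: cs.GenerativeState, fs: float) -> np.ndarray:
    """Generator templates embedded in snippet-length, peak-aligned windows."""
    return np.stack([
        cs.align_template(cs.render_waveform(p, fs), fs) for p in state.templates
    ])


def match_events_to_truth(times, truth_times, tol_s=0.01):
    """Greedy matching of detection times to ground-truth times.

    Returns (n_true_positive, n_false_positive, n_false_negative).
    """
    truth_times = np.asarray(truth_times)
    used = np.zeros(truth_times.size, dtype=bool)
    tp = fp = 0
    for t in sorted(times):
        i = int(np.argmin(np.abs(truth_times - t))) if truth_times.size else -1
        if i >= 0 and abs(truth_times[i] - t) <= tol_s and not used[i]:
            tp += 1
            used[i] = True
        else:
            fp += 1
    return tp, fp, int((~used).sum())
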