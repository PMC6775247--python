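"""Ground-truthed synthetic multi-segment CDP recordings.

Spontaneous cord dorsum potentials (CDPs) are brief field potentials recorded
from the dorsal surface of the spinal cord.  Their class-to-class sequencing
carries information about the functional connectivity of the dorsal-horn
ensembles that generate them, and pharmacological maneuvers (intradermal
capsaicin, systemic lidocaine, spinalization) reorganize that sequencing.

This module emulates such experiments: multi-channel recordings over the
L4-L7 segments in which each channel carries a stream of CDP events whose
shape-class labels follow condition-specific order-1 Markov chains.  Event
times follow a dead-time renewal process, a tunable fraction of event times
is shared across channels (segmental synchronization), and waveforms are
superimposed on Gaussian background noise.  Every generated event is
returned as ground truth so detection, classification and the downstream
state-transition analysis can all be scored exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger("cdpstates")

#: Condition tags in the canonical order of the experimental protocol.
CONDITIONS = ("control", "capsaicin", "lidocaine1", "spinal", "lidocaine2")

#: Default number of CDP shape classes.
DEFAULT_N_CLASSES = 12

#: Default sampling rate, Hz (comfortably above the 1 kHz analog filter edge).
DEFAULT_FS = 5000.0

#: Default channel labels: rostral L4-L7, both sides.
DEFAULT_CHANNELS = (
    "L4rL", "L4rR", "L5rL", "L5rR", "L6rL", "L6rR", "L7rL", "L7rR",
)


# ---------------------------------------------------------------------------
# Condition schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConditionSchedule:
    """Ordered experimental phases, each a run of fixed-length time steps.

    Parameters
    ----------
    phases
        Ordered ``(condition_tag, n_steps)`` pairs; tags must be members of
        :data:`CONDITIONS`.
    step_length_s
        Length of one analysis time step in seconds (the protocol uses
        5-10 min windows; default 600 s).
    """

    phases: tuple[tuple[str, int], ...]
    step_length_s: float = 600.0

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("schedule needs at least one phase")
        object.__setattr__(self, "phases", tuple((str(c), int(n)) for c, n in self.phases))
        for cond, n in self.phases:
            if cond not in CONDITIONS:
                raise ValueError(f"unknown condition tag {cond!r}; expected one of {CONDITIONS}")
            if n < 1:
                raise ValueError(f"phase {cond!r} must contain at least one step, got {n}")
        if self.step_length_s <= 0:
            raise ValueError("step_length_s must be positive")

    @property
    def n_steps(self) -> int:
        return sum(n for _, n in self.phases)

    @property
    def total_s(self) -> float:
        return self.n_steps * self.step_length_s

    @property
    def step_conditions(self) -> list[str]:
        """Condition tag of every step, in step order (steps are 0-based here)."""
        out: list[str] = []
        for cond, n in self.phases:
            out.extend([cond] * n)
        return out

    def phase_position(self, step: int) -> tuple[str, int, int]:
        """Return ``(condition, index_within_phase, phase_length)`` for a step."""
        if not 0 <= step < self.n_steps:
            raise ValueError(f"step {step} outside schedule of {self.n_steps} steps")
        offset = 0
        for cond, n in self.phases:
            if step < offset + n:
                return cond, step - offset, n
            offset += n
        raise AssertionError("unreachable")

    def step_of(self, time_s: float) -> int:
        """Map a time (s) to its step index; times at a boundary join the later step."""
        if not 0 <= time_s < self.total_s:
            raise ValueError(f"time {time_s} s outside the schedule (0-{self.total_s} s)")
        return int(time_s // self.step_length_s)


# ---------------------------------------------------------------------------
# Markov chain presets and sampling
# ---------------------------------------------------------------------------

def validate_stochastic(matrix: np.ndarray, atol: float = 1e-9) -> np.ndarray:
    """Validate a row-stochastic matrix and return it as a float array."""
    P = np.asarray(matrix, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError(f"transition matrix must be square, got shape {P.shape}")
    if np.any(P < -atol) or not np.all(np.isfinite(P)):
        raise ValueError("transition matrix entries must be finite and non-negative")
    rows = P.sum(axis=1)
    if not np.allclose(rows, 1.0, atol=atol):
        raise ValueError(f"transition matrix rows must sum to 1 (got sums {rows})")
    return np.clip(P, 0.0, None)


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (leading left eigenvector)."""
    P = validate_stochastic(P)
    vals, vecs = np.linalg.eig(P.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def preset_transition_matrix(kind: str, n_classes: int = DEFAULT_N_CLASSES,
                             pref_ratio: float = 0.93,
                             kernel_shift: float = 4.0,
                             kernel_sigma: float = 1.5,
                             weights: tuple[float, float, float] = (0.25, 0.35, 0.40),
                             ) -> np.ndarray:
    """Condition-specific order-1 transition matrix over CDP shape classes.

    Each preset mixes three row-stochastic components::

        P = w_u * uniform + w_p * preference + w_k * cyclic kernel

    The *preference* profile (identical rows) sets the marginal class
    frequencies and encodes the pharmacology: under control the small,
    frequent CDP classes (low indices) dominate (geometric decay with ratio
    ``pref_ratio``); capsaicin suppresses the small-amplitude classes and
    boosts the largest ones (the profile reversed); spinalization produces
    a third regime with a mid-class hump.  The *cyclic kernel* (a wrapped
    Gaussian of width ``kernel_sigma`` centered ``kernel_shift`` classes
    away: 0 for control, +shift for capsaicin, -shift for spinal) makes
    the class-to-class sequencing itself condition-specific, so regimes
    differ in transition structure and not only in marginals.  The uniform
    floor keeps every transition probability bounded away from zero, which
    the unsmoothed maximum-likelihood similarity index requires of
    sequences of realistic per-step length.

    Parameters
    ----------
    kind
        ``"control"``, ``"capsaicin"`` or ``"spinal"``.
    n_classes
        Number of CDP shape classes.
    pref_ratio
        Geometric decay of the class-preference profile (closer to 1 is
        flatter).
    kernel_shift, kernel_sigma
        Center offset (classes) and width of the wrapped persistence
        kernel.
    weights
        Mixture weights ``(uniform, preference, kernel)``; must sum to 1.
    """
    w_u, w_p, w_k = weights
    if not np.isclose(w_u + w_p + w_k, 1.0):
        raise ValueError("mixture weights must sum to 1")
    i = np.arange(n_classes, dtype=float)
    if kind == "control":
        pref = pref_ratio ** i
        shift = 0.0
    elif kind == "capsaicin":
        pref = pref_ratio ** (n_classes - 1 - i)
        shift = +kernel_shift
    elif kind == "spinal":
        pref = 1.0 + 0.6 * np.exp(-0.5 * ((i - n_classes / 2) / 2.0) ** 2)
        shift = -kernel_shift
    else:
        raise ValueError(f"unknown preset kind {kind!r}")
    pref = pref / pref.sum()

    d = (i[None, :] - i[:, None] - shift) % n_classes
    d = np.minimum(d, n_classes - d)
    kernel = np.exp(-0.5 * (d / kernel_sigma) ** 2)
    kernel /= kernel.sum(axis=1, keepdims=True)
    kernel = 0.85 * kernel + 0.15 / n_classes

    P = (w_u / n_classes
         + w_p * np.tile(pref, (n_classes, 1))
         + w_k * kernel)
    P /= P.sum(axis=1, keepdims=True)
    return validate_stochastic(P)


def sample_class_sequence(transition_probs: np.ndarray, n_events: int,
                          rng: np.random.Generator | int,
                          initial: np.ndarray | None = None) -> np.ndarray:
    """Sample a CDP class-label sequence from an order-1 Markov chain.

    Labels are 1-based (class 1 .. C).  The first label is drawn from
    ``initial`` when given, otherwise from the chain's stationary
    distribution (each time step of the experiment is analyzed
    independently, so the chain is started at equilibrium).

    Parameters
    ----------
    transition_probs
        C x C row-stochastic matrix.
    n_events
        Number of labels to draw (>= 1).
    rng
        :class:`numpy.random.Generator` or integer seed.
    initial
        Optional distribution of the first label.

    Returns
    -------
    numpy.ndarray of int, shape ``(n_events,)`` with values in 1..C.
    """
    P = validate_stochastic(transition_probs)
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    C = P.shape[0]
    p0 = stationary_distribution(P) if initial is None else np.asarray(initial, dtype=float)
    if p0.shape != (C,) or np.any(p0 < 0) or not np.isclose(p0.sum(), 1.0, atol=1e-9):
        raise ValueError("initial distribution must be a length-C probability vector")

    # inverse-CDF sampling against row-wise cumulative sums; vectorized draw
    cum = np.cumsum(P, axis=1)
    cum[:, -1] = 1.0
    u = rng.random(n_events)
    labels = np.empty(n_events, dtype=np.int64)
    labels[0] = np.searchsorted(np.cumsum(p0), u[0], side="right")
    for t in range(1, n_events):
        labels[t] = np.searchsorted(cum[labels[t - 1]], u[t], side="right")
    return labels + 1


# ---------------------------------------------------------------------------
# Waveform templates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TemplateParams:
    """Parameters of one CDP shape class.

    ``kind`` selects the waveform family seen on the cord dorsum: ``"n"`` is
    a purely negative deflection (nCDP); ``"np"`` a negative deflection
    followed by a positive one (npCDP).  ``pre`` optionally prepends a slow
    component of the given sign, emulating CDPs preceded by slow negative or
    positive potentials.

    Amplitudes are in microvolts and widths in milliseconds; ``amp_neg`` is
    the magnitude of the (dominant) negative peak.
    """

    kind: str = "n"                       # "n" | "np"
    amp_neg: float = 50.0                 # µV, magnitude of negative peak
    amp_pos: float = 0.0                  # µV, positive lobe (np only)
    width_neg_ms: float = 25.0
    width_pos_ms: float = 30.0
    pre: str | None = None                # None | "neg" | "pos"
    pre_amp: float = 0.0                  # µV
    pre_width_ms: float = 60.0

    def __post_init__(self) -> None:
        if self.kind not in ("n", "np"):
            raise ValueError(f"kind must be 'n' or 'np', got {self.kind!r}")
        if self.pre not in (None, "neg", "pos"):
            raise ValueError(f"pre must be None, 'neg' or 'pos', got {self.pre!r}")
        for name in ("amp_neg", "amp_pos", "width_neg_ms", "width_pos_ms",
                     "pre_amp", "pre_width_ms"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
        if self.amp_neg < 0 or self.amp_pos < 0 or self.pre_amp < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.width_neg_ms <= 0 or self.width_pos_ms <= 0 or self.pre_width_ms <= 0:
            raise ValueError("widths must be positive")


def _hann_bump(n: int) -> np.ndarray:
    """Unit-amplitude raised-cosine bump on n samples, zero at both ends."""
    t = np.arange(n) / max(n - 1, 1)
    return np.sin(np.pi * t) ** 2


def render_waveform(params: TemplateParams, fs: float = DEFAULT_FS) -> np.ndarray:
    """Render one CDP template as a µV time series at sampling rate ``fs``.

    The trace starts and ends at baseline (exactly zero endpoints).  For an
    nCDP it contains a single negative extremum; for an npCDP the negative
    extremum precedes the positive one.  An optional slow pre-component of
    the requested sign is prepended.
    """
    if fs <= 0 or not np.isfinite(fs):
        raise ValueError("fs must be positive and finite")

    n_neg = max(int(round(params.width_neg_ms * 1e-3 * fs)), 3)
    main = -params.amp_neg * _hann_bump(n_neg)
    if params.kind == "np":
        n_pos = max(int(round(params.width_pos_ms * 1e-3 * fs)), 3)
        main = np.concatenate([main, params.amp_pos * _hann_bump(n_pos)])
    if params.pre is not None and params.pre_amp > 0:
        n_pre = max(int(round(params.pre_width_ms * 1e-3 * fs)), 3)
        sign = -1.0 if params.pre == "neg" else 1.0
        main = np.concatenate([sign * params.pre_amp * _hann_bump(n_pre), main])
    return main


def default_templates(n_classes: int = DEFAULT_N_CLASSES) -> list[TemplateParams]:
    """Default shape-class dictionary used by the generator.

    Classes span the observed taxonomy: purely negative CDPs, negative-
    positive CDPs, and CDPs preceded by slow negative or positive
    components.  Peak amplitude grows with class index (20 to 100 µV), so
    low-index classes are the small CDPs that dominate control recordings
    and high-index classes the large CDPs boosted by capsaicin.
    """
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    out: list[TemplateParams] = []
    for c in range(n_classes):
        frac = c / max(n_classes - 1, 1)
        # geometric spacing: constant relative amplitude gap between
        # neighbouring classes, as amplitude discrimination is relative
        amp = 20.0 * (100.0 / 20.0) ** frac
        width = 18.0 + 14.0 * frac
        kind = "np" if c % 2 == 1 else "n"
        pre: str | None = None
        pre_amp = 0.0
        if n_classes >= 8 and c >= n_classes - 4:
            pre = "neg" if c % 2 == 0 else "pos"
            pre_amp = 0.35 * amp
        out.append(TemplateParams(
            kind=kind, amp_neg=amp, amp_pos=0.5 * amp if kind == "np" else 0.0,
            width_neg_ms=width, width_pos_ms=width * 1.3,
            pre=pre, pre_amp=pre_amp, pre_width_ms=40.0,
        ))
    return out


# ---------------------------------------------------------------------------
# Generative state
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenerativeState:
    """Everything the generator needs besides the schedule.

    Parameters
    ----------
    channel_ids
        Segment/side labels of the recording channels.
    n_classes
        Number of CDP shape classes C.
    transition_matrices
        Mapping ``{"control": P, "capsaicin": P, "spinal": P}``; lidocaine
        phases are derived from these (see :meth:`step_transition_matrix`).
        All channels share the same condition dynamics.
    event_rate
        Mean CDP rate per channel, events/s.
    sync_rho
        Probability in [0, 1] that an event time is shared across all
        channels (cross-segment synchronization).
    noise_sigma
        Standard deviation of the additive Gaussian background noise, µV.
    templates
        Per-class waveform parameters (length C).
    dead_time_s
        Minimum inter-event interval per channel, seconds.
    restore_fraction
        Fraction of each lidocaine1 phase during which control-like dynamics
        are restored; the remaining steps relapse to capsaicin-like dynamics.
    """

    channel_ids: tuple[str, ...] = DEFAULT_CHANNELS
    n_classes: int = DEFAULT_N_CLASSES
    transition_matrices: dict[str, np.ndarray] = field(default_factory=dict)
    event_rate: float = 4.0
    sync_rho: float = 0.3
    noise_sigma: float = 4.0
    templates: tuple[TemplateParams, ...] = ()
    dead_time_s: float = 0.05
    restore_fraction: float = 0.8

    def __post_init__(self) -> None:
        if not self.channel_ids:
            raise ValueError("channel set must be non-empty")
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ValueError("channel_ids must be unique")
        if not 0.0 <= self.sync_rho <= 1.0:
            raise ValueError("sync_rho must lie in [0, 1]")
        if self.event_rate <= 0:
            raise ValueError("event_rate must be positive")
        if self.event_rate * self.dead_time_s >= 1.0:
            raise ValueError("event_rate incompatible with dead time "
                             f"(need rate < 1/dead_time = {1.0 / self.dead_time_s:.1f}/s)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if not 0.0 <= self.restore_fraction <= 1.0:
            raise ValueError("restore_fraction must lie in [0, 1]")
        mats = dict(self.transition_matrices)
        for kind in ("control", "capsaicin", "spinal"):
            if kind not in mats:
                mats[kind] = preset_transition_matrix(kind, self.n_classes)
            mats[kind] = validate_stochastic(mats[kind])
            if mats[kind].shape != (self.n_classes, self.n_classes):
                raise ValueError(f"{kind} matrix shape {mats[kind].shape} != C={self.n_classes}")
        object.__setattr__(self, "transition_matrices", mats)
        tmpl = tuple(self.templates) if self.templates else tuple(default_templates(self.n_classes))
        if len(tmpl) != self.n_classes:
            raise ValueError(f"need {self.n_classes} templates, got {len(tmpl)}")
        object.__setattr__(self, "templates", tmpl)
        object.__setattr__(self, "channel_ids", tuple(self.channel_ids))

    # -- condition dynamics -------------------------------------------------

    def control_weight(self, schedule: ConditionSchedule, step: int) -> float:
        """Weight of control-like dynamics at a step (1 control, 0 capsaicin)."""
        cond, pos, length = schedule.phase_position(step)
        if cond == "control":
            return 1.0
        if cond in ("capsaicin", "spinal", "lidocaine2"):
            return 0.0
        # lidocaine1: transient restoration of control dynamics, then relapse
        n_restored = int(round(self.restore_fraction * length))
        return 1.0 if pos < n_restored else 0.0

    def step_transition_matrix(self, schedule: ConditionSchedule, step: int) -> np.ndarray:
        """Effective transition matrix of a step.

        Control and capsaicin steps use their presets.  During lidocaine1
        the first ``restore_fraction`` of the phase restores the control
        matrix and the tail relapses to the capsaicin matrix, emulating the
        transient antinociceptive effect.  Spinal steps use the spinal
        matrix; lidocaine2 (after spinalization) keeps the spinal matrix,
        since systemic lidocaine has only marginal effects once descending
        influences are removed.
        """
        cond, _, _ = schedule.phase_position(step)
        if cond in ("spinal", "lidocaine2"):
            return self.transition_matrices["spinal"]
        w = self.control_weight(schedule, step)
        Pc = self.transition_matrices["control"]
        Pk = self.transition_matrices["capsaicin"]
        return validate_stochastic(w * Pc + (1.0 - w) * Pk)

    def regime_of_step(self, schedule: ConditionSchedule, step: int) -> str:
        """Ground-truth dynamical regime ('control', 'capsaicin' or 'spinal')."""
        cond, _, _ = schedule.phase_position(step)
        if cond in ("spinal", "lidocaine2"):
            return "spinal"
        return "control" if self.control_weight(schedule, step) >= 0.5 else "capsaicin"


# ---------------------------------------------------------------------------
# Event-stream and recording synthesis
# ---------------------------------------------------------------------------

def _renewal_times(rate: float, dead: float, t0: float, t1: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Renewal process on [t0, t1): intervals = dead time + exponential tail."""
    if rate <= 0:
        return np.empty(0)
    mean_tail = 1.0 / rate - dead
    span = t1 - t0
    n_guess = int(rate * span * 1.5 + 20)
    times: list[float] = []
    t = t0 + rng.exponential(1.0 / rate)  # equilibrium-ish start offset
    while t < t1:
        times.append(t)
        t += dead + rng.exponential(mean_tail)
        if len(times) > 4 * n_guess:  # pragma: no cover - safety valve
            raise RuntimeError("runaway event generation")
    return np.asarray(times)


def synthesize_events(schedule: ConditionSchedule, state: GenerativeState,
                      seed: int) -> pd.DataFrame:
    """Generate the ground-truth event table (no waveform rendering).

    Event times are drawn per step.  A shared renewal process at rate
    ``sync_rho * event_rate`` contributes simultaneous events on every
    channel; independent per-channel processes at rate
    ``(1 - sync_rho) * event_rate`` contribute the rest, so each channel
    sees ``event_rate`` events/s of which a fraction ``sync_rho`` is
    synchronized.  Labels follow the step's Markov chain per channel
    (shared times do not imply shared labels).

    Returns
    -------
    pandas.DataFrame with columns ``time_s, channel, class, condition, step``
    (1-based step indices), sorted by channel then time.
    """
    rng = np.random.default_rng(seed)
    rows: list[pd.DataFrame] = []
    dead = state.dead_time_s
    for step in range(schedule.n_steps):
        cond, _, _ = schedule.phase_position(step)
        P = state.step_transition_matrix(schedule, step)
        t0, t1 = step * schedule.step_length_s, (step + 1) * schedule.step_length_s
        shared = _renewal_times(state.sync_rho * state.event_rate, dead, t0, t1, rng)
        for ch in state.channel_ids:
            own = _renewal_times((1.0 - state.sync_rho) * state.event_rate,
                                 dead, t0, t1, rng)
            times = np.sort(np.concatenate([shared, own]))
            # enforce the per-channel dead time after superposition
            keep: list[float] = []
            last = -np.inf
            for t in times:
                if t - last >= dead:
                    keep.append(t)
                    last = t
            times = np.asarray(keep)
            if times.size == 0:
                continue
            labels = sample_class_sequence(P, times.size, rng)
            rows.append(pd.DataFrame({
                "time_s": times, "channel": ch, "class": labels,
                "condition": cond, "step": step + 1,
            }))
    if not rows:
        return pd.DataFrame(columns=["time_s", "channel", "class", "condition", "step"])
    df = pd.concat(rows, ignore_index=True)
    return df.sort_values(["channel", "time_s"], kind="stable").reset_index(drop=True)


@dataclass
class RawRecording:
    """Multichannel continuous recording in µV.

    ``signal`` has shape (n_channels, n_samples); ``channel_ids`` are
    segment/side labels such as ``"L5rL"``; ``t0`` is the absolute time of
    the first sample in seconds.
    """

    signal: np.ndarray
    fs: float
    channel_ids: tuple[str, ...]
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channels x samples)")
        if len(self.channel_ids) != self.signal.shape[0]:
            raise ValueError("channel_ids length must match signal rows")
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ValueError("channel_ids must be unique")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.channel_ids = tuple(self.channel_ids)

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs


def synthesize_recording(schedule: ConditionSchedule, state: GenerativeState,
                         fs: float = DEFAULT_FS, seed: int = 0,
                         ) -> tuple[RawRecording, pd.DataFrame]:
    """Synthesize a continuous multichannel recording plus ground truth.

    Event streams come from :func:`synthesize_events`; each event adds its
    class template to the trace, aligned so the template's negative extremum
    sits at the event time, on top of white Gaussian noise of standard
    deviation ``noise_sigma``.

    Returns
    -------
    (RawRecording, ground-truth DataFrame as in :func:`synthesize_events`).
    """
    if fs < 2000:
        raise ValueError("fs must be >= 2 kHz")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x7EC0]))
    events = synthesize_events(schedule, state, seed)

    waveforms = [render_waveform(p, fs) for p in state.templates]
    peak_offsets = [int(np.argmin(w)) for w in waveforms]
    max_len = max(len(w) for w in waveforms)
    if state.dead_time_s * fs < 1:
        raise ValueError("dead time shorter than one sample")
    if max_len > int(30 * fs):  # pragma: no cover - sanity bound
        raise ValueError("template length incompatible with event spacing")

    n_samples = int(round(schedule.total_s * fs))
    n_ch = len(state.channel_ids)
    if state.noise_sigma > 0:
        signal = rng.normal(0.0, state.noise_sigma, size=(n_ch, n_samples))
    else:
        signal = np.zeros((n_ch, n_samples))
    signal = signal.astype(np.float64)

    ch_index = {ch: i for i, ch in enumerate(state.channel_ids)}
    for row in events.itertuples(index=False):
        c = int(row[events.columns.get_loc("class")]) - 1
        w = waveforms[c]
        start = int(round(row.time_s * fs)) - peak_offsets[c]
        lo, hi = max(start, 0), min(start + len(w), n_samples)
        if hi <= lo:
            continue
        signal[ch_index[row.channel], lo:hi] += w[lo - start:hi - start]

    rec = RawRecording(signal=signal.astype(np.float32), fs=fs,
                       channel_ids=state.channel_ids, t0=0.0)
    return rec, events


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_recording_h5(path, recording: RawRecording) -> None:
    """Write a recording to HDF5 (/signal in µV, fs/channel/t0 attrs)."""
    with h5py.File(path, "w") as f:
        d = f.create_dataset("signal", data=recording.signal.astype(np.float32))
        d.attrs["units"] = "uV"
        f.attrs["fs_hz"] = float(recording.fs)
        f.attrs["channel_ids"] = [str(c) for c in recording.channel_ids]
        f.attrs["t0_s"] = float(recording.t0)


def read_recording_h5(path) -> RawRecording:
    """Read a recording written by :func:`write_recording_h5`."""
    with h5py.File(path, "r") as f:
        sig = f["signal"][...]
        fs = float(f.attrs["fs_hz"])
        chans = tuple(str(c) for c in f.attrs["channel_ids"])
        t0 = float(f.attrs.get("t0_s", 0.0))
    return RawRecording(signal=sig, fs=fs, channel_ids=chans, t0=t0)


def write_events_csv(path, events: pd.DataFrame) -> None:
    """Write a ground-truth / labeled event table to CSV."""
    events.to_csv(path, index=False)


def read_events_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
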