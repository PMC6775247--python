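"""CDP event detection, shape dictionaries, and event classification.

The raw cord dorsum signal is band-limited (the acquisition chain passes
0.3 Hz - 1 kHz), negative-going deflections exceeding a robust noise
threshold are extracted as fixed-length snippets aligned to their negative
peak, and snippets recorded under control conditions are clustered into C
shape classes whose mean waveforms form the channel's dictionary.  All
events — control and maneuver alike — are then labeled with the class of
the nearest template.

CDP classes differ by shape *and* amplitude, so both clustering and
classification use a combined distance: one minus the Pearson correlation
of the waveforms plus a weighted normalized difference of their negative
peak amplitudes.  Dictionaries are built per channel; class 1 is the most
frequent control class (classes are renumbered by descending control
frequency).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .synthetic_data import ConditionSchedule, RawRecording

logger = logging.getLogger("cdpstates")

#: Snippet window around the negative peak, seconds.
SNIPPET_PRE_S = 0.05
SNIPPET_POST_S = 0.15

#: Weight of the normalized amplitude difference in the waveform distance.
AMPLITUDE_WEIGHT = 0.5


@dataclass(frozen=True)
class CDPSnippet:
    """One detected CDP: fixed-length waveform aligned to its negative peak."""

    waveform: np.ndarray          # µV, length fixed per run
    peak_time_s: float
    channel_id: str


@dataclass(frozen=True)
class Dictionary:
    """Per-channel ordered set of C class templates.

    ``templates`` has shape (C, L); row order is descending control-step
    frequency, so class 1 (row 0) is the most frequent control class.
    ``control_counts`` records the size of each class's control cluster.
    """

    channel_id: str
    templates: np.ndarray
    control_counts: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.templates, dtype=float)
        if t.ndim != 2:
            raise ValueError("templates must be a 2-D (C x L) array")
        object.__setattr__(self, "templates", t)
        object.__setattr__(self, "control_counts",
                           np.asarray(self.control_counts, dtype=np.int64))

    @property
    def n_classes(self) -> int:
        return self.templates.shape[0]


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def bandpass_filter(recording: RawRecording, low: float = 0.3,
                    high: float = 1000.0, order: int = 4) -> RawRecording:
    """Zero-phase Butterworth band-pass of every channel.

    Defaults match the acquisition chain's analog band (0.3 Hz - 1 kHz).
    Forward-backward filtering (``sosfiltfilt``) preserves peak latencies.
    """
    nyq = recording.fs / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(f"band ({low}, {high}) Hz must satisfy 0 < low < high < "
                         f"Nyquist ({nyq} Hz)")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=recording.fs,
                     output="sos")
    # pad on the scale of the low-cutoff time constant, or the edge
    # transient of the 0.3 Hz corner contaminates the first seconds
    padlen = min(recording.n_samples - 1, int(3 * recording.fs / low))
    filtered = sps.sosfiltfilt(sos, recording.signal.astype(np.float64), axis=1,
                               padlen=padlen)
    return RawRecording(signal=filtered, fs=recording.fs,
                        channel_ids=recording.channel_ids, t0=recording.t0)


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def robust_noise_sigma(x: np.ndarray) -> float:
    """Noise scale from the median absolute deviation (consistent for a Gaussian)."""
    return float(1.4826 * np.median(np.abs(x - np.median(x))))


def detect_events(recording: RawRecording, threshold_k: float = 4.0,
                  dead_time_s: float = 0.05) -> list[CDPSnippet]:
    """Detect negative CDP deflections and cut peak-aligned snippets.

    A sample qualifies when the signal drops below ``-threshold_k`` times
    the channel's MAD-based noise scale; each detection is a local minimum,
    detections on one channel are at least ``dead_time_s`` apart (the
    deeper peak wins), and the snippet spans 50 ms before to 150 ms after
    the negative peak.  Detections whose window exceeds the signal bounds
    are dropped with a log notice.
    """
    if threshold_k <= 0:
        raise ValueError("threshold_k must be positive")
    fs = recording.fs
    pre = int(round(SNIPPET_PRE_S * fs))
    post = int(round(SNIPPET_POST_S * fs))
    out: list[CDPSnippet] = []
    for ci, ch in enumerate(recording.channel_ids):
        x = recording.signal[ci].astype(np.float64)
        sigma = robust_noise_sigma(x)
        if sigma == 0.0:
            sigma = 1e-12  # noiseless synthetic traces: any deflection counts
        peaks, _ = sps.find_peaks(-x, height=threshold_k * sigma,
                                  distance=max(int(round(dead_time_s * fs)), 1))
        dropped = 0
        for p in peaks:
            if p - pre < 0 or p + post > x.size:
                dropped += 1
                continue
            out.append(CDPSnippet(waveform=x[p - pre:p + post].copy(),
                                  peak_time_s=recording.t0 + p / fs,
                                  channel_id=ch))
        if dropped:
            logger.info("channel %s: dropped %d detections at signal bounds", ch, dropped)
    return out


# ---------------------------------------------------------------------------
# Waveform distance, clustering, classification
# ---------------------------------------------------------------------------

def _peak_amplitude(w: np.ndarray) -> float:
    """Magnitude of the negative peak, µV."""
    return float(-w.min()) if w.size else 0.0


#: Gaussian smoothing width used before waveform comparison, as a fraction
#: of the snippet length (1% of a 200 ms snippet = 2 ms: well below CDP
#: time scales, strongly suppressing wide-band noise).
SMOOTHING_FRACTION = 0.01


def _smooth(W: np.ndarray) -> np.ndarray:
    from scipy.ndimage import gaussian_filter1d
    sigma = max(W.shape[-1] * SMOOTHING_FRACTION, 1.0)
    return gaussian_filter1d(W, sigma=sigma, axis=-1, mode="nearest")


def waveform_distance_matrix(waves: np.ndarray) -> np.ndarray:
    """Pairwise correlation-plus-amplitude distance between waveforms.

    d(i, j) = (1 - pearson(w_i, w_j))
              + AMPLITUDE_WEIGHT * |a_i - a_j| / max(a_i, a_j)

    with a the negative-peak magnitude.  Waveforms are lightly smoothed
    first (a CDP is slow relative to the noise band, so smoothing raises
    the effective SNR of the comparison without distorting shape).
    Constant waveforms get correlation 0 against everything (shape
    uninformative).
    """
    W = _smooth(np.asarray(waves, dtype=float))
    n = W.shape[0]
    centered = W - W.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    unit = centered / safe[:, None]
    corr = unit @ unit.T
    corr[norms == 0, :] = 0.0
    corr[:, norms == 0] = 0.0
    np.fill_diagonal(corr, 1.0)

    amps = np.array([_peak_amplitude(w) for w in W])
    denom = np.maximum(np.maximum.outer(amps, amps), 1e-12)
    amp_term = np.abs(np.subtract.outer(amps, amps)) / denom
    d = (1.0 - corr) + AMPLITUDE_WEIGHT * amp_term
    np.fill_diagonal(d, 0.0)
    return np.maximum(d, 0.0)


def build_dictionary(control_snippets: list[CDPSnippet], n_classes: int,
                     min_per_class: int = 10, min_cluster_size: int = 4) -> Dictionary:
    """Cluster control snippets into C classes and average each cluster.

    Average-linkage agglomerative clustering under the correlation-plus-
    amplitude distance, cut at C clusters.  Detection at a few noise sigmas
    inevitably admits occasional noise snippets; these land in tiny
    clusters, so clusters below ``min_cluster_size`` are discarded as
    outliers and the remaining snippets re-cut until C clusters of
    sufficient size remain.  Templates are the cluster mean waveforms
    (amplitude-preserving — no renormalization), renumbered by descending
    cluster size so class 1 is the most frequent control class.  Ties in
    size break toward the larger negative peak.  Deterministic for a fixed
    snippet set.
    """
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    if len(control_snippets) < min_per_class * n_classes:
        raise ValueError(f"need >= {min_per_class * n_classes} control snippets "
                         f"for C={n_classes}, got {len(control_snippets)}")
    lengths = {s.waveform.size for s in control_snippets}
    if len(lengths) != 1:
        raise ValueError("snippets must share a fixed length")
    channels = {s.channel_id for s in control_snippets}
    if len(channels) != 1:
        raise ValueError("dictionaries are per channel; got snippets from "
                         f"{sorted(channels)}")

    W = np.stack([s.waveform for s in control_snippets])
    D = waveform_distance_matrix(W)
    keep = np.arange(W.shape[0])
    assign = None
    for _ in range(50):
        if keep.size < min_per_class * n_classes // 2 or keep.size <= n_classes:
            raise ValueError("too many outlier snippets discarded; clustering failed")
        Z = linkage(squareform(D[np.ix_(keep, keep)], checks=False), method="average")
        assign = fcluster(Z, t=n_classes, criterion="maxclust")
        ids, sizes = np.unique(assign, return_counts=True)
        small = ids[sizes < min(min_cluster_size, keep.size // (2 * n_classes) + 1)]
        if small.size == 0:
            break
        logger.debug("discarding %d outlier snippets in %d small clusters",
                     int(np.isin(assign, small).sum()), small.size)
        keep = keep[~np.isin(assign, small)]
    ids = np.unique(assign)
    if ids.size < n_classes:
        raise ValueError(f"clustering produced {ids.size} < C={n_classes} clusters; "
                         "snippets may be degenerate")

    templates = np.stack([W[keep[assign == c]].mean(axis=0) for c in ids])
    sizes = np.array([(assign == c).sum() for c in ids])
    amps = np.array([_peak_amplitude(t) for t in templates])
    order = np.lexsort((-amps, -sizes))  # descending size, then amplitude
    return Dictionary(channel_id=control_snippets[0].channel_id,
                      templates=templates[order], control_counts=sizes[order])


def classify_snippet(waveform: np.ndarray, dictionary: Dictionary) -> int:
    """1-based class of the nearest template; ties break to the lower class."""
    if waveform.size != dictionary.templates.shape[1]:
        raise ValueError("snippet length does not match template length")
    stack = np.vstack([waveform, dictionary.templates])
    d = waveform_distance_matrix(stack)[0, 1:]
    return int(np.argmin(d)) + 1


def classify_events(snippets: list[CDPSnippet], dictionary: Dictionary,
                    schedule: ConditionSchedule | None = None) -> pd.DataFrame:
    """Label every snippet with its nearest-template class.

    Returns a labeled-event table (``time_s, channel, class`` and, when a
    schedule is given, ``step`` — 1-based — and ``condition``).
    """
    if not snippets:
        cols = ["time_s", "channel", "class"]
        if schedule is not None:
            cols += ["condition", "step"]
        return pd.DataFrame(columns=cols)
    L = dictionary.templates.shape[1]
    waves = np.stack([s.waveform for s in snippets])
    if waves.shape[1] != L:
        raise ValueError("snippet length does not match template length")

    # one distance evaluation over the joint stack, then slice the
    # snippet-vs-template block
    stack = np.vstack([waves, dictionary.templates])
    D = waveform_distance_matrix(stack)[:len(snippets), len(snippets):]
    labels = np.argmin(D, axis=1) + 1   # argmin ties -> lower class index

    df = pd.DataFrame({
        "time_s": [s.peak_time_s for s in snippets],
        "channel": [s.channel_id for s in snippets],
        "class": labels.astype(np.int64),
    })
    if schedule is not None:
        df = assign_steps(df, schedule)
    return df.sort_values(["channel", "time_s"], kind="stable").reset_index(drop=True)


def assign_steps(events: pd.DataFrame, schedule: ConditionSchedule) -> pd.DataFrame:
    """Attach 1-based step indices and condition tags to an event table."""
    df = events.copy()
    steps = (df["time_s"] // schedule.step_length_s).astype(int)
    in_range = (steps >= 0) & (steps < schedule.n_steps)
    if not in_range.all():
        logger.warning("dropping %d events outside the schedule", int((~in_range).sum()))
        df, steps = df[in_range], steps[in_range]
    conds = schedule.step_conditions
    df["condition"] = [conds[s] for s in steps]
    df["step"] = steps + 1
    return df


def align_template(waveform: np.ndarray, fs: float,
                   pre_s: float = SNIPPET_PRE_S, post_s: float = SNIPPET_POST_S,
                   ) -> np.ndarray:
    """Embed a rendered waveform in a snippet-length window, peak-aligned.

    Utility for validation studies: places the waveform's negative extremum
    at the detection alignment point so it can be compared directly with
    extracted snippets or dictionary templates.
    """
    pre = int(round(pre_s * fs))
    post = int(round(post_s * fs))
    peak = int(np.argmin(waveform))
    out = np.zeros(pre + post)
    lo = max(0, peak - pre)
    seg = waveform[lo:peak + post]
    start = pre - (peak - lo)
    out[start:start + min(len(seg), len(out) - start)] = seg[:len(out) - start]
    return out


def match_templates(dictionary: Dictionary, reference: np.ndarray) -> dict[int, int]:
    """Optimal 1-1 assignment of dictionary classes to reference templates.

    Dictionary classes are numbered by control frequency, which generally
    differs from any external numbering (e.g. the class ids of a synthetic
    ground truth).  This resolves the correspondence by minimizing the
    total waveform distance over all bijections (Hungarian algorithm).

    Returns a mapping ``{dictionary_class: reference_index + 1}`` (both
    1-based).
    """
    from scipy.optimize import linear_sum_assignment

    ref = np.asarray(reference, dtype=float)
    if ref.shape[0] != dictionary.n_classes:
        raise ValueError("reference must contain one template per class")
    D = waveform_distance_matrix(np.vstack([dictionary.templates, ref]))
    D = D[:dictionary.n_classes, dictionary.n_classes:]
    rows, cols = linear_sum_assignment(D)
    return {int(r) + 1: int(c) + 1 for r, c in zip(rows, cols)}


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_dictionary(path, dictionary: Dictionary) -> None:
    """Serialize a dictionary as JSON (metadata + template arrays)."""
    payload = {
        "channel_id": dictionary.channel_id,
        "n_classes": dictionary.n_classes,
        "control_counts": dictionary.control_counts.tolist(),
        "templates": dictionary.templates.tolist(),
    }
    with open(path, "w") as f:
        json.dump(payload, f)


def read_dictionary(path) -> Dictionary:
    with open(path) as f:
        payload = json.load(f)
    return Dictionary(channel_id=payload["channel_id"],
                      templates=np.asarray(payload["templates"], dtype=float),
                      control_counts=np.asarray(payload["control_counts"]))
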