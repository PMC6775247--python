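"""Windowed cross-segment correlation and the coefficient-set similarity index.

Complementary to the Markov state analysis, the raw (band-passed) traces of
every channel pair are correlated over successive non-overlapping windows.
The vector of pairwise Pearson coefficients per window — displayed with the
pair order locked to the descending coefficients of the first (control)
window — tracks how segmental synchronization reorganizes across maneuvers,
and a bounded 0-1 index compares coefficient sets between windows: 0 means
the two sets are identical, 1 maximally opposed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .synthetic_data import RawRecording

logger = logging.getLogger("cdpstates")


@dataclass(frozen=True)
class CorrelationSet:
    """Pairwise Pearson coefficients of one window, in the locked pair order."""

    window_index: int
    r: np.ndarray                  # coefficients, one per channel pair
    pairs: tuple[tuple[str, str], ...]


def windowed_correlation(recording: RawRecording, window_s: float = 600.0,
                         ) -> list[CorrelationSet]:
    """Pearson correlation of every channel pair per non-overlapping window.

    The pair ordering of every window is fixed by the descending
    coefficients of the first window (the control reference), so successive
    windows can be compared element-by-element.  A window longer than the
    recording yields a single truncated window with a warning.
    """
    if recording.signal.shape[0] < 2:
        raise ValueError("need at least 2 channels")
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    n = recording.n_samples
    win = int(round(window_s * recording.fs))
    if win > n:
        logger.warning("window (%g s) exceeds recording (%g s); using one truncated window",
                       window_s, recording.duration_s)
        win = n
    n_windows = n // win
    pair_idx = list(combinations(range(len(recording.channel_ids)), 2))

    all_r = np.empty((n_windows, len(pair_idx)))
    for w in range(n_windows):
        seg = recording.signal[:, w * win:(w + 1) * win].astype(np.float64)
        C = np.corrcoef(seg)
        all_r[w] = [C[i, j] for i, j in pair_idx]

    order = np.argsort(-all_r[0], kind="stable")
    pairs = tuple((recording.channel_ids[pair_idx[o][0]],
                   recording.channel_ids[pair_idx[o][1]]) for o in order)
    return [CorrelationSet(window_index=w, r=all_r[w, order], pairs=pairs)
            for w in range(n_windows)]


def coefficient_set_similarity(v1: np.ndarray, v2: np.ndarray) -> float:
    """Scaled mean absolute difference between two coefficient sets.

    ``mean(|v1 - v2|) / 2``: coefficients span [-1, 1], so the index lies
    in [0, 1], is 0 exactly when the sets are identical and 1 when every
    pair sits at opposite extremes.  Symmetric, and a pseudo-metric up to
    the constant scale.
    """
    a = np.asarray(v1, dtype=float)
    b = np.asarray(v2, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"coefficient sets must have equal length ({a.shape} vs {b.shape})")
    if a.ndim != 1:
        raise ValueError("coefficient sets must be 1-D")
    return float(np.mean(np.abs(a - b)) / 2.0)


def correlation_table(sets: list[CorrelationSet]) -> pd.DataFrame:
    """Windows x pairs table of coefficients in the locked pair order."""
    if not sets:
        return pd.DataFrame()
    cols = [f"{a}-{b}" for a, b in sets[0].pairs]
    return pd.DataFrame([s.r for s in sets], columns=cols,
                        index=[s.window_index for s in sets])
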