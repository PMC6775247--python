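"""Per-step class histograms, the RMS histogram-significance statistic, and t-tests.

Each analysis time step yields a histogram of CDP class counts per channel.
Two histograms are compared bin-by-bin under a Poisson counting model
approximated by a normal: the per-bin significance is the standardized
count difference

    S_i = (n_i1 - K * n_i2) / sqrt(n_i1 + K^2 * n_i2),   K = N1 / N2,

with K rescaling histogram 2 when the totals differ (K = 1 recovers the
equal-total form).  The root-mean-square of the significances around their
mean summarizes the comparison: RMS ~ 0 means identical histograms, RMS ~ 1
two draws from the same parent distribution, RMS >> 1 different parents.
The identity RMS^2 = chi^2 / M - Sbar^2 (chi^2 = sum S_i^2) holds on the
bins actually used.

Significances operate on raw counts (the Poisson model needs them);
fractional probabilities are used for display and for the per-class
Student's t-tests against control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("cdpstates")

#: Star thresholds for per-class t-tests.
STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass(frozen=True)
class StepHistogram:
    """Class counts of one channel in one time step."""

    counts: np.ndarray            # length M, non-negative integers
    step_index: int = 0           # 1-based
    channel_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 1:
            raise ValueError("counts must be a 1-D vector")
        if np.any(c < 0) or not np.allclose(c, np.round(c)):
            raise ValueError("counts must be non-negative integers")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def fractions(self) -> np.ndarray:
        """Fractional probabilities of occurrence; NaN vector when the step is empty."""
        N = self.total
        if N == 0:
            logger.warning("empty histogram (step %s, channel %s): fractions undefined",
                           self.step_index, self.channel_id)
            return np.full(self.n_bins, np.nan)
        return self.counts / N


@dataclass(frozen=True)
class SignificanceVector:
    """Per-bin significances between two histograms (used bins only)."""

    values: np.ndarray            # S_i on the bins in `used`
    used: np.ndarray              # boolean mask over the original M bins
    K: float                      # N1 / N2

    @property
    def m_effective(self) -> int:
        return int(self.used.sum())


@dataclass(frozen=True)
class RMSResult:
    """RMS-of-significances summary of a histogram pair."""

    rms: float
    s_bar: float
    chi2: float
    m_effective: int


@dataclass(frozen=True)
class TTestResult:
    """Welch t-test of one class's per-step fractions, condition vs control."""

    class_label: int
    t: float
    p: float
    n_control: int
    n_condition: int
    stars: str
    degenerate: bool = False      # zero-variance groups handled by rule


def fractional_probabilities(events: pd.DataFrame, step: int, n_classes: int,
                             channel: str | None = None) -> StepHistogram:
    """Build the class histogram of one step (optionally one channel).

    Parameters
    ----------
    events
        Labeled-event table with columns ``step``, ``class`` and optionally
        ``channel`` / ``condition``.
    step
        1-based step index.
    n_classes
        Number of classes C (histogram bins).
    """
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    sel = events[events["step"] == step]
    if channel is not None:
        sel = sel[sel["channel"] == channel]
    counts = np.bincount(sel["class"].to_numpy(dtype=np.int64), minlength=n_classes + 1)[1:]
    if counts.size != n_classes:
        raise ValueError("event labels exceed n_classes")
    cond = str(sel["condition"].iloc[0]) if ("condition" in sel and len(sel)) else ""
    return StepHistogram(counts=counts, step_index=int(step),
                         channel_id="" if channel is None else str(channel),
                         condition=cond)


def significance_per_bin(h1: StepHistogram, h2: StepHistogram) -> SignificanceVector:
    """Per-bin normalized significances S_i(K) between two histograms.

    Bins empty in both histograms are excluded (the statistic is 0/0 there
    and an unobserved Poisson bin carries no variance information); the
    remaining bins define M_effective.
    """
    if h1.n_bins != h2.n_bins:
        raise ValueError(f"histograms must share M (got {h1.n_bins} vs {h2.n_bins})")
    N1, N2 = h1.total, h2.total
    if N1 == 0 or N2 == 0:
        raise ValueError("cannot compare a histogram with zero total events")
    K = N1 / N2
    n1 = h1.counts.astype(float)
    n2 = h2.counts.astype(float)
    used = (h1.counts > 0) | (h2.counts > 0)
    var = n1[used] + K * K * n2[used]
    values = (n1[used] - K * n2[used]) / np.sqrt(var)
    return SignificanceVector(values=values, used=used, K=K)


def rms_distance(h1: StepHistogram, h2: StepHistogram) -> RMSResult:
    """RMS of the per-bin significances between two histograms."""
    sig = significance_per_bin(h1, h2)
    M = sig.m_effective
    if M == 0:
        raise ValueError("no usable bins: RMS undefined")
    s = sig.values
    s_bar = float(s.mean())
    chi2 = float((s ** 2).sum())
    rms = float(np.sqrt(np.mean((s - s_bar) ** 2)))
    return RMSResult(rms=rms, s_bar=s_bar, chi2=chi2, m_effective=M)


def rms_matrix(histograms: list[StepHistogram]) -> np.ndarray:
    """Symmetric step-by-step matrix of RMS distances (zero diagonal)."""
    n = len(histograms)
    ms = {h.n_bins for h in histograms}
    if len(ms) > 1:
        raise ValueError("all histograms must share the number of bins")
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = rms_distance(histograms[i], histograms[j]).rms
    return out


def class_probability_ttest(control_fracs: np.ndarray,
                            condition_fracs: np.ndarray) -> list[TTestResult]:
    """Welch t-test per class of condition-step vs control-step fractions.

    Parameters
    ----------
    control_fracs, condition_fracs
        Arrays of shape (n_steps, C): per-step fractional probabilities.

    Notes
    -----
    Two-sided Welch (unequal-variance) test per class.  Degenerate rule for
    zero variance in both groups: equal means give t = 0, p = 1; unequal
    means are reported as p < 1e-12 and flagged.  No multiple-testing
    correction is applied by default; apply Benjamini-Hochberg downstream
    if desired.
    """
    a = np.atleast_2d(np.asarray(control_fracs, dtype=float))
    b = np.atleast_2d(np.asarray(condition_fracs, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups must share the number of classes")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need >= 2 steps per group; pool adjacent steps if necessary")
    results: list[TTestResult] = []
    for c in range(a.shape[1]):
        x, y = a[:, c], b[:, c]
        if np.var(x) == 0.0 and np.var(y) == 0.0:
            if np.isclose(x.mean(), y.mean()):
                t, p, degen = 0.0, 1.0, False
            else:
                t = np.inf if x.mean() > y.mean() else -np.inf
                p, degen = 1e-13, True
        else:
            t, p = stats.ttest_ind(x, y, equal_var=False)
            t, p, degen = float(t), float(p), False
        stars = next((s for thr, s in STAR_LEVELS if p < thr), "")
        results.append(TTestResult(class_label=c + 1, t=t, p=p,
                                   n_control=a.shape[0], n_condition=b.shape[0],
                                   stars=stars, degenerate=degen))
    return results


def ttest_table(results: list[TTestResult]) -> pd.DataFrame:
    """Tabulate t-test results for reporting."""
    return pd.DataFrame([{
        "class": r.class_label, "t": r.t, "p": r.p,
        "n_control": r.n_control, "n_condition": r.n_condition,
        "stars": r.stars, "degenerate": r.degenerate,
    } for r in results])


def benjamini_hochberg(pvalues: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg rejection mask (optional, off by default upstream)."""
    from statsmodels.stats.multitest import multipletests
    reject, _, _, _ = multipletests(np.asarray(pvalues, dtype=float),
                                    alpha=alpha, method="fdr_bh")
    return reject
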