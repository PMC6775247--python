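"""Order-1 Markov models of CDP class sequences and the likelihood similarity index.

Within one recording channel, the class label of each CDP is modeled as
depending only on the class of the preceding CDP (an order-1 Markov chain):
the transition-probability matrix fitted to one time step is taken as a
compact description of the functional connectivity state of the generating
network during that step.

Two steps are compared by evaluating how well the model fitted to one step
(the *source*) explains the label sequence of another (the *target*).  The
mean per-transition log-likelihood of the target under the source model,
referenced to the source's own mean log-likelihood and exponentiated, gives
an index in [0, 1]: exactly 1 when the target is the source sequence itself,
exactly 0 when the target uses a transition the source model assigns zero
probability, and asymmetric in general.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger("cdpstates")


@dataclass(frozen=True)
class MarkovModel:
    """Maximum-likelihood order-1 chain over class labels 1..C.

    ``transition_probs`` rows are normalized bigram counts; rows whose label
    never occurs as a transition source are left uniform-free (all zero) and
    flagged in ``observed_rows``.
    """

    transition_counts: np.ndarray
    transition_probs: np.ndarray
    source_length: int            # number of transitions the fit used
    n_states: int

    @property
    def observed_rows(self) -> np.ndarray:
        """Boolean mask of states observed at least once as a transition source."""
        return self.transition_counts.sum(axis=1) > 0


def _as_labels(labels, C: int) -> np.ndarray:
    x = np.asarray(labels, dtype=np.int64)
    if x.ndim != 1:
        raise ValueError("label sequence must be 1-D")
    if x.size and (x.min() < 1 or x.max() > C):
        raise ValueError(f"labels must lie in 1..{C}, got range "
                         f"[{x.min()}, {x.max()}]")
    return x


def fit_markov(labels, n_states: int) -> MarkovModel:
    """Fit the ML transition matrix from bigram counts of a label sequence.

    Parameters
    ----------
    labels
        Sequence of integer class labels in 1..n_states, length >= 2.
    n_states
        Number of classes C.
    """
    x = _as_labels(labels, n_states)
    if x.size < 2:
        raise ValueError("need at least 2 labels to fit transitions")
    counts = np.zeros((n_states, n_states), dtype=np.int64)
    np.add.at(counts, (x[:-1] - 1, x[1:] - 1), 1)
    row_sums = counts.sum(axis=1)
    probs = np.zeros((n_states, n_states), dtype=float)
    observed = row_sums > 0
    probs[observed] = counts[observed] / row_sums[observed, None]
    if not observed.all():
        missing = np.flatnonzero(~observed) + 1
        logger.debug("states never observed as transition source: %s", missing.tolist())
    return MarkovModel(transition_counts=counts, transition_probs=probs,
                       source_length=int(x.size - 1), n_states=n_states)


def sequence_log_likelihood(model: MarkovModel, labels) -> tuple[float, float]:
    """Log-likelihood of a label sequence under a fitted chain.

    Only transitions enter the likelihood (the initial state is not
    modeled).  No smoothing is applied: if the sequence uses a transition of
    zero estimated probability — including any transition out of a state the
    model never observed as a source — both values are ``-inf``.

    Returns
    -------
    (total, mean) log-likelihood, the mean taken per transition.
    """
    x = _as_labels(labels, model.n_states)
    if x.size < 2:
        raise ValueError("sequence must contain at least one transition")
    p = model.transition_probs[x[:-1] - 1, x[1:] - 1]
    if np.any(p == 0.0):
        return -np.inf, -np.inf
    ll = float(np.log(p).sum())
    return ll, ll / (x.size - 1)


def similarity_index(model: MarkovModel, source_labels, target_labels) -> float:
    """Normalized likelihood similarity of a target step to a source step.

    With ``lbar(seq)`` the mean per-transition log-likelihood under the
    source model, the index is ``exp(lbar(target) - lbar(source))`` clipped
    to [0, 1].  Per-transition normalization makes the index robust to
    unequal step lengths; the exponential-difference form pins the stated
    anchors: 1 when target == source, 0 when the model cannot generate the
    target.  The measure is not symmetric.
    """
    _, mean_src = sequence_log_likelihood(model, source_labels)
    _, mean_tgt = sequence_log_likelihood(model, target_labels)
    if not np.isfinite(mean_tgt):
        return 0.0
    if not np.isfinite(mean_src):  # cannot happen when model was fit on source
        raise ValueError("source sequence impossible under its own model")
    return float(np.clip(np.exp(mean_tgt - mean_src), 0.0, 1.0))


def similarity_matrix(step_sequences: dict[int, np.ndarray] | list,
                      n_states: int) -> tuple[np.ndarray, list[int]]:
    """All-pairs similarity between the per-step label sequences of a channel.

    Entry ``[s, s']`` is the similarity of step s' under the model fitted to
    step s; the diagonal is exactly 1.  Steps with fewer than 2 events carry
    no transition information and are excluded with a log notice.

    Parameters
    ----------
    step_sequences
        Either a mapping ``{step_key: labels}`` or a plain list of label
        sequences (keys then being positions).
    n_states
        Number of classes C.

    Returns
    -------
    (matrix, kept_keys) — the matrix covers only the retained steps, in the
    order given by ``kept_keys``.
    """
    if isinstance(step_sequences, dict):
        items = list(step_sequences.items())
    else:
        items = list(enumerate(step_sequences))
    kept = [(k, np.asarray(seq)) for k, seq in items if np.asarray(seq).size >= 2]
    dropped = [k for k, seq in items if np.asarray(seq).size < 2]
    if dropped:
        logger.warning("excluding steps with <2 events from similarity matrix: %s", dropped)
    if len(kept) < 2:
        raise ValueError("need at least 2 usable steps for a similarity matrix")

    keys = [k for k, _ in kept]
    seqs = [s for _, s in kept]
    models = [fit_markov(s, n_states) for s in seqs]
    n = len(kept)
    S = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            S[i, j] = 1.0 if i == j else similarity_index(models[i], seqs[i], seqs[j])
    return S, keys
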