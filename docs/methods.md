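# Methods

This note documents the models, the numerical choices, and what the
synthetic data does and does not emulate.

## Statistical model of a recording

A recording is a set of channels (segment/side electrode sites over L4–L7)
carrying continuous µV traces at 5 kHz (default; any rate ≥ 2 kHz is
accepted), band-limited to 0.3 Hz–1 kHz by the acquisition chain. The
experiment is a sequence of *conditions* (control, capsaicin, lidocaine,
spinalization, lidocaine again) divided into fixed-length *time steps*
(default 600 s, the middle of the 5–10 min convention). All analyses treat
steps as the unit of replication.

Event-level data are triples (time, channel, class) with classes 1..C
(default C = 12). Classes are defined per channel by clustering
control-condition snippets; class 1 is the most frequent control class.

## Event extraction

Detection thresholds at k·σ̂ (default k = 4) on the negative-going filtered
signal, with σ̂ = 1.4826·MAD — robust to the events themselves. Detections
are local minima at least one dead time (default 50 ms) apart; the deeper
peak wins a conflict. Snippets span 50 ms before to 150 ms after the
negative extremum, which is the alignment point.

Zero-phase filtering uses a 4th-order Butterworth band-pass applied
forward-backward. The reflect padding is sized to the low-cutoff time
constant (3/f_low seconds); with the default 0.3 Hz corner the edge
transient of an unpadded filter would otherwise depress the first seconds
of the trace by several µV and generate spurious detections there.

Snippet comparison uses d(i,j) = (1 − Pearson) + 0.5·|aᵢ − aⱼ|/max(aᵢ, aⱼ),
where a is the negative-peak magnitude — classes differ by shape *and*
amplitude, so both terms are needed. Waveforms are Gaussian-smoothed
(σ = 1% of the snippet, i.e. 2 ms) before comparison: a CDP is slow
relative to the noise band, and without smoothing the correlation term is
dominated by wide-band noise over the ~90% of the snippet that carries no
signal. Dictionary building is average-linkage agglomerative clustering cut
at C clusters; clusters smaller than 4 snippets are discarded as outliers
(threshold-crossing noise events land there) and the remainder re-cut until
C adequately sized clusters remain. Templates are amplitude-preserving
cluster means, renumbered by descending cluster size (ties toward the
larger peak). Classification assigns each snippet the nearest template
under the same distance, ties toward the lower class index. Everything is
deterministic for a fixed input.

Because dictionary classes are numbered by control frequency, validation
against an external numbering (e.g. the generator's ground truth) requires
the optimal class bijection; `match_templates` computes it by Hungarian
assignment on template distances.

## Histogram comparison

Per-bin significances and their RMS operate on raw counts under the
Poisson-approximated-by-normal model, never on fractions (fractions are for
display and t-tests). Bins empty in *both* histograms are excluded
(M_effective): the statistic is 0/0 there and an unobserved bin carries no
variance information. When totals differ, histogram 2 is rescaled by
K = N₁/N₂ inside the significance; K = 1 recovers the plain form. The
radical in the RMS is resolved as RMS = √(Σ(S&#770;ᵢ−S̄)²/M_effective), the
form consistent with the identity RMS² = χ²/M − S̄², which the
implementation maintains to 1e-9.

The per-class test against control is a two-sided Welch t-test with steps
as replicates (the available alternative — events as replicates — inflates
n by orders of magnitude and ignores step-level autocorrelation). Zero
variance in both groups with equal means yields t = 0, p = 1; with unequal
means the difference is certain at the resolution of the data, reported as
p < 1e-12 and flagged. No multiple-testing correction is applied by
default; a Benjamini–Hochberg helper is provided.

## Markov similarity

Each step's label sequence is modeled as an order-1 chain fitted by
maximum likelihood (row-normalized bigram counts). The likelihood covers
transitions only — the model conditions each CDP on its predecessor, so the
initial state is not scored. No smoothing is applied: rows never observed
as a source stay zero, and any target transition with zero estimated
probability makes the sequence impossible under the model.

The similarity of target step s′ under source step s is

    index(s → s′) = exp( ℓ̄(s′ | model_s) − ℓ̄(s | model_s) ) clipped to [0, 1]

with ℓ̄ the mean per-transition log-likelihood. The per-transition
normalization makes the index robust to unequal step lengths; the
exponential difference pins the endpoints (exactly 1 on the source itself,
exactly 0 on an impossible target) and preserves asymmetry. An optional
Laplace-α smoothing flag exists in spirit through the model container but
defaults to off, because the 0 endpoint requires exact zeros.

Finite-sample behavior: with C = 12 there are 132 free parameters, and for
a step of n transitions the source model overfits its own step by about
d/2n nats per transition, so two independent samples of the same chain
score ≈ exp(−d/n). At n = 2,000 this is ≈ 0.94, which is why same-regime
steps clear the 0.9 graph threshold while the default event rate
(4 events/s × 600 s ≈ 2,400 events per step) keeps them there. Steps with
fewer than 2 events carry no transition information and are dropped from
similarity matrices with a log notice.

## Graphs, communities, consensus

Per-segment graphs connect each step to its k = 3 most similar steps with
index ≥ S = 0.9 (fewer if fewer qualify); the directed selections are
symmetrized by union because the community method operates on undirected
graphs, with edge weight the larger directed similarity. Communities come
from the WalkTrap random-walk agglomerative method (walk length 4, cut at
best modularity) as implemented in python-igraph; isolated nodes form
singleton communities, and the result is deterministic for a fixed graph.

For the consensus, each segment's per-step top-k lists (k = 4, threshold
mst = 0.9) are pooled as directed votes. Each step then joins the k2 = 3
most-voted partners *among the steps it voted for in at least one segment*,
ranked by total votes on the pair (both directions), ties toward the
smaller step index. Restricting candidates to a node's own vote lists keeps
every consensus edge grounded in that step's similarity judgments and makes
the consensus of identical segments reduce exactly to the single-segment
topology at matched k. The graph parameters (k, S, mst, k2) are the
defaults used throughout; all are configurable.

## Segment correlation

Windowed correlograms compute Pearson r for every channel pair on the
band-passed continuous signals over non-overlapping windows (default one
step), with the pair ordering locked to the descending coefficients of the
first (control) window. The 0–1 index between two coefficient sets is the
mean absolute difference divided by 2 (coefficients span [−1, 1]). This
particular formula is a design choice — bounded, symmetric, zero iff
identical, one iff maximally opposed — the quantity it reproduces is
reported in the source experiments without a stated formula, so printed
values from real recordings cannot be compared against it numerically. An
event-train correlation option is deliberately not provided; the continuous
signal carries the synchronization structure the generator models.

## The synthetic generator

The generator emulates the *structure* the analysis assumes, not dorsal-horn
biophysics:

* **Event times** — per channel, a renewal process with intervals
  = 50 ms dead time + exponential tail, at `event_rate` (default
  4 events/s). A shared process at rate ρ·rate (copied to all channels)
  plus independent processes at (1−ρ)·rate give each channel the nominal
  rate with fraction ρ of synchronized event times (`sync_rho`,
  default 0.3). Raising ρ provably raises mean pairwise correlation.
* **Labels** — condition-specific order-1 chains. Each preset matrix is
  0.25·uniform + 0.35·class-preference + 0.40·cyclic persistence kernel.
  The preference profile encodes the pharmacology (control favors the
  small, low-index classes geometrically with ratio 0.93; capsaicin the
  reverse — suppressing small-CDP classes and boosting the largest;
  spinal a mid-class hump), while the wrapped Gaussian kernel (σ = 1.5
  classes, centered 0/+4/−4 classes away for control/capsaicin/spinal)
  makes the *sequencing* itself condition-specific. The uniform floor
  keeps every transition probability above ~2%, which the unsmoothed
  similarity index requires at realistic step lengths; the resulting
  regimes score ≈ 0.93 within and ≲ 0.82 across, giving the 0.9 graph
  threshold a real margin on both sides.
* **Lidocaine** — the first 80% of a `lidocaine1` phase restores the
  control matrix, the tail relapses to capsaicin (matching the observed
  transient restoration and fade); lidocaine after spinalization keeps the
  spinal matrix (its effects there are marginal). Each step's first label
  is drawn from its chain's stationary distribution, since steps are
  analyzed independently.
* **Waveforms** — raised-cosine compositions: a negative lobe (nCDP), an
  optional positive lobe after it (npCDP), and an optional slow pre-
  component of either sign. Class amplitudes are geometrically spaced
  20–100 µV (constant relative gap, since amplitude discrimination is
  relative); widths 18–32 ms; pre-components 40 ms wide at 35% of the
  class amplitude, so a noise-shifted pre-peak stays within the detection
  dead time of the main peak. Default background noise is 4 µV, putting
  the smallest class at SNR 5.

What the generator does *not* emulate: the slow synchronized oscillations
seen under capsaicin (beyond what the class mix induces), overlapping-event
superposition effects at high rates, nonstationarity within a step,
electrode drift, or any biophysical coupling between segments. Passing
tests therefore demonstrate that the pipeline recovers the structures it
models — not that real cord recordings satisfy those models.

## Problem sizes and determinism

Tests and the demonstration configuration run at reduced scale: signal-level
checks use 2 channels × 4–6 one-minute steps, label-level state-transition
checks use the full 25-step schedule at 4 segments × ~2,400 events/step,
and the consensus-recovery study uses 20 seeded runs at 6 segments. All
randomness flows through `numpy.random.Generator` objects seeded from a
single integer; fixed seeds reproduce recordings bit-for-bit, and graph
construction, clustering and community detection are deterministic given
their inputs.

## Known limitations

* The extraction stage assumes separable events; it does not decompose
  overlaps, so very high event rates degrade classification.
* Dictionary class numbering is frequency-based and therefore not stable
  across channels or datasets; cross-channel class identity is not claimed.
* The no-smoothing likelihood makes the similarity index exactly zero on
  any unseen transition, which is the intended endpoint behavior but means
  short steps (≲ 1,000 events at C = 12) read as dissimilar even within a
  regime.
* WalkTrap at best-modularity can split large homogeneous step groups into
  sub-communities on occasion; the state-transition narrative is robust to
  this (sub-communities stay within a regime) but exact community counts
  are not guaranteed.
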