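# cdpstates

Functional-connectivity state transitions in dorsal-horn neuronal
populations, inferred from spontaneous cord dorsum potentials (CDPs).

Spontaneous CDPs are brief field potentials recorded from the dorsal surface
of the lumbar spinal cord (channels labeled by segment and side, e.g.
`L5rL`). They come in distinct shape classes — purely negative (nCDP),
negative-positive (npCDP), and waveforms preceded by slow negative or
positive components — and the *sequencing* of those classes reflects the
functional connectivity of the neuronal ensembles that generate them.
Nociceptive (intradermal capsaicin) and antinociceptive (systemic lidocaine)
maneuvers, and spinalization, reorganize that sequencing. `cdpstates`
implements the complete analysis chain for such experiments, plus a
ground-truthed synthetic-data generator so every stage can be validated
without animal data.

## The analysis

1. **Extraction & classification** (`waveform_dictionary`). Band-pass the
   raw signal (0.3 Hz–1 kHz), detect negative deflections beyond
   *k*·MAD of the noise (default *k* = 4), cut 200 ms peak-aligned snippets,
   cluster control-condition snippets into *C* = 12 classes under a
   correlation-plus-amplitude distance, and label every event with its
   nearest template. Class 1 is the most frequent control class.

2. **Step histograms and the RMS statistic** (`step_histograms`). Per time
   step (a fixed 5–10 min window), count events per class and form
   fractional probabilities of occurrence. Two steps are compared on raw
   counts under a Poisson model: per-bin significances

   S&#770;ᵢ = (n&#770;ᵢ₁ − K·n&#770;ᵢ₂) / √(σ&#770;²ᵢ₁ + K²σ&#770;²ᵢ₂),  σ&#770;²ᵢₖ = n&#770;ᵢₖ,  K = N₁/N₂,

   and RMS = √(Σᵢ(S&#770;ᵢ − S̄)²/M). RMS ≈ 0 means identical histograms,
   ≈ 1 two draws from the same parent distribution, ≫ 1 different parents;
   RMS² = χ²/M − S̄² holds exactly. Per-class Welch t-tests against the
   control steps star significant changes at 0.05 / 0.01 / 0.001.

3. **Markov similarity** (`markov_similarity`). Each step's label sequence
   is fitted as an order-1 Markov chain. The similarity of step *s′* to
   step *s* is exp(ℓ̄(s′|model_s) − ℓ̄(s|model_s)) clipped to [0, 1], with
   ℓ̄ the mean per-transition log-likelihood: exactly 1 on the source
   itself, exactly 0 if the target uses a transition of zero estimated
   probability (no smoothing), asymmetric in general.

4. **State graphs and consensus** (`state_graphs`). Per segment, each step
   connects to its *k* = 3 most similar steps above *S* = 0.9; WalkTrap
   (random-walk) communities define per-segment connectivity states. For
   the whole cord, each segment's top-*k* lists (*k* = 4, threshold
   *mst* = 0.9) are pooled as votes and a consensus graph joins each step
   to its *k2* = 3 most-voted partners; its WalkTrap communities are the
   global functional states, and the step-ordered community sequence is
   the state-transition narrative.

5. **Segment correlation** (`segment_correlation`). Windowed Pearson
   correlation of every channel pair (pair order locked to the first
   control window) and a bounded 0–1 index comparing coefficient sets.

6. **Synthesis** (`synthetic_data`). Multi-channel recordings in which
   per-channel event streams follow condition-specific order-1 chains over
   12 classes (control / capsaicin / spinal presets; lidocaine phases
   restore control dynamics then relapse), with tunable cross-segment
   synchronization, a dead-time renewal process for event times, and
   Gaussian background noise. Every event is returned as ground truth.

## Worked example

A label-level run of the demonstration schedule (3 control, 9 capsaicin,
11 lidocaine, 2 spinalization steps of 600 s; 4 segments; 4 events/s):

```bash
cat > demo.yaml <<EOF
schedule:
  - [control, 3]
  - [capsaicin, 9]
  - [lidocaine1, 11]
  - [spinal, 2]
step_length_s: 600
seed: 1
channels: [L4rL, L5rL, L6rL, L7rL]
event_rate: 4.0
use_raw: false
outdir: demo_run
EOF
cdpstates run --config demo.yaml
```

prints

```
run complete: 23 artifacts in demo_run
  n_labeled_events: 221663
  n_consensus_communities: 3
```

and `demo_run/state_transitions.csv` holds the consensus narrative. For
this seed the three communities partition the 25 steps as

* community 0 — control steps 1–3 **and** lidocaine steps 13–21,
* community 1 — capsaicin steps 4–12 **and** late-lidocaine steps 22–23,
* community 2 — spinalization steps 24–25.

That is the expected physiology: lidocaine transiently returns the cord to
its control connectivity state, the effect fades (the last lidocaine steps
rejoin the capsaicin state), and spinalization creates a third state. The
run directory also contains per-channel RMS matrices, t-test tables,
similarity matrices (CSV), per-segment and consensus graphs (GraphML with
step/condition/community attributes), and vote tables. With
`use_raw: true` the pipeline additionally synthesizes the continuous
traces, detects and classifies the CDPs from scratch, and computes windowed
segment-pair correlograms.

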