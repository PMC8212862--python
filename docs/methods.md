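# Methods

This note documents the models implemented in `afqc`, the assumptions of the
synthetic-data generator, the numerical choices, and the known limitations.
It states no empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Problem setting

Intermittent 30-s single-lead (lead I) ECGs from handheld screening devices
are analyzed for atrial fibrillation (AF) by rhythm only: atrial activity is
not reliably measurable in lead I, so detection rests on RR-interval
irregularity.  Transient noise creates false QRS detections that mimic that
irregularity.  The package therefore couples two models: an event-level
signal-quality classifier, and a windowed RR-irregularity detector whose
input is pruned by the classifier's decisions.

## 2. The quality-control CNN

### Architecture

Input: 400 samples (400 ms at 1 kHz), min-max normalized to [0, 1].
Layers (valid convolutions, no padding):

| stage | definition | output length | parameters |
|---|---|---|---|
| conv-1 | 16 filters, kernel 10, stride 2, ReLU, L2 0.01 | 196 | 176 |
| conv-2 | 32 filters, kernel 10, stride 2, ReLU | 94 | 5,152 |
| pool | average, kernel 5, stride 2 | 45 | 0 |
| conv-3 | 64 filters, kernel 10, stride 2, ReLU | 18 | 20,544 |
| pool | average, kernel 5, stride 2 | 7 | 0 |
| fc-1 | 448 → 40, ReLU, dropout 0.5 | — | 17,960 |
| fc-2 | 40 → 40, ReLU, dropout 0.25 | — | 1,640 |
| fc-3 | 40 → 1, sigmoid | — | 41 |

The output is the probability that the event is a false detection (the
positive class throughout the event-level evaluation).

### Loss, weights, training

Weighted binary cross entropy with inverse-frequency weights
w_j = M/(2·M_j) computed from the *training split*; predictions are clipped
to [1e-7, 1 − 1e-7] so the loss stays finite.  Optimization: Adam
(lr 0.001, β₁ 0.9, β₂ 0.999), batch size 256, at most 200 epochs.  At the
end of each epoch the validation loss is computed; when it exceeds its best
value for more than `patience` consecutive epochs (default 0, i.e. stop on
any increase) training stops and the best-epoch parameters are restored.
Weight initialization is uniform fan-in scaling,
U(−√(6/fan_in), +√(6/fan_in)); initialization, batch shuffling and dropout
masks are all driven by generators spawned from one seed, so training is a
pure function of (data, configs, seed).

The L2 penalty (0.01 · Σw²) applies to the first convolutional layer only —
the layer closest to the raw waveform and hence most prone to memorizing
noise shapes.

### Decision threshold

The operating threshold sweeps {0.01, 0.02, …, 0.99} and takes the smallest
value maximizing F1 on the validation split.  Classification is strict:
an event is a false detection iff its probability exceeds the threshold.
The threshold is data-dependent by construction; on the synthetic corpora it
typically lands far from 0.5 because of the class imbalance.

### Implementation note

The network (strided 1-D convolution via im2col, average pooling, dense
layers, dropout, backprop, Adam) is implemented directly in numpy
(`afqc/_nn.py`).  A finite-difference gradient check of the full stack is
part of the test suite.

## 3. The RR-irregularity AF detector

For each sliding window of N intervals (stride 1; a series of M intervals
has M − N + 1 windows):

- γ = α · median(window); α is dimensionless, so the statistic is invariant
  to a common rescaling of all intervals.
- Λ = (number of pairs j < k with |r(j) − r(k)| > γ) / ((N−1)(N−2)).
  The normalizer is kept as (N−1)(N−2) although the pair count is
  N(N−1)/2 — the window threshold η was tuned jointly with this
  normalization, and Λ's maximum N/(2(N−2)) equals 1 only at N = 4.
  A *concordance* variant counting pairs below γ is exposed as
  `convention="printed"`; the two satisfy
  Λ_exceed + Λ_printed = N/(2(N−2)) whenever no pair difference ties γ.
- Tie-breaks: a pair difference exactly equal to γ counts as concordant
  (regular); Λ exactly equal to η flags the window irregular (O = 1).
- Recording decision: AF iff (ΣO over qualifying windows)/I ≥ η_d with
  η_d = 1/3, the value implied by the rule that ≥ 10 s of AF inside a 30-s
  recording labels the whole recording AF.  I = 0 (no qualifying window, or
  series shorter than one window) yields non-AF with a quality flag — never
  a silent 0/0.

### Quality-control pruning

Given per-event labels from the CNN:

1. The recording's median RR is the median of intervals between
   *consecutive true-labeled* detections (per recording, not per window).
2. A maximal run of exactly **one** false detection flanked by true
   detections whose spanning interval deviates < 15% from that median is
   merged away: the two sub-intervals fuse and nothing is disqualified.
   Runs of two or more false detections never merge.
3. Every other false detection is deleted, and each sliding window whose
   time span strictly contains a deleted event is marked non-qualifying.

The merge exception matters: without it, every isolated noise spike between
normal beats would disqualify N windows and shorten the usable recording.

### Parameter tuning

Exhaustive constrained grid search: N ∈ {4,…,8}, α ∈ {0.03,…,0.12} in steps
of 0.01, η ∈ {0.05,…,0.95} in steps of 0.05 — 950 combinations, each
evaluated exactly once.  The α and η step sizes are chosen to match the
precision at which the shipped presets are stated.  Among combinations with
recording-level training sensitivity ≥ 99%, the lowest-FPR one wins; ties
break toward smaller N, then α, then η (smaller N means less context needed;
smaller α and η are the more sensitive settings).  If nothing is feasible
the best-sensitivity combination is returned flagged infeasible.  The
sensitivity constraint is applied at recording level on the training split.
Evaluation repeats the split/tune/test cycle over random subject-level
splits (default 10) and reports mean ± sd, since a single split biases the
estimate; AF subjects are divided as evenly as possible between train and
test, the odd extra subject alternating with seed parity.

### Metrics

Se, Sp, Acc, FPR = 1 − Sp, PPV, and F1 = 2·Se·PPV/(Se+PPV) from the 2×2
table.  Positive class: false detection (event level) or AF (recording
level).  Patient-level sensitivity counts a patient as detected when at
least one of their recordings is labeled AF.  Metrics with zero denominators
are reported as not-available (None), never silently as 0.  The
expert-review load is TP + FP (detector-positive recordings), and the
expected number of recordings reviewed per AF found is round(1/PPV).

## 4. The synthetic corpus generator

The generator emulates the statistical regime of an elderly screening
population; all waveform and noise parameters are package choices, pinned in
`MorphologyConfig` / `NoiseSpec` so tests can rely on them.

- **RR structure.**  Sinus intervals: truncated normal
  (mean 700–1000 ms per subject, sd 10–30 ms — resting short-recording
  variability; truncation [0.5, 1.5]×mean).  AF intervals: truncated normal
  with sd = 0.3×mean (coefficient of variation typical of AF at rest),
  truncation [300, 1800] ms; the generator floor is sd ≥ 0.15×mean.
  Ectopy replaces a beat with a premature one (0.6×) plus compensatory
  pause (1.4×).  AF recordings are either fully AF or carry one embedded
  episode of 14–25 s; multi-episode recordings are out of scope.  A
  recording is labeled AF iff its summed AF-interval duration reaches 10 s,
  and the label-consistency invariant is enforced on construction.
- **Waveforms.**  Each beat is a sum of Gaussians (P, Q, R, S, T; R = 1 mV).
  During AF the P wave is suppressed and a small 4–12 Hz fibrillatory
  baseline is added.  Baseline wander (≤ 0.15 Hz, 0.05 mV) and white noise
  (sd 0.01 mV) are always present.
- **Transient noise.**  Counts per recording are Poisson (memoryless
  arrivals).  Spikes: 10–50 ms biphasic deflections, 1.5–3× R amplitude,
  support hard-limited to ±50 ms.  Steps: 0.5–2× R offsets with exponential
  recovery (τ = 0.2–1 s).  Bursts: 20–100 Hz band-limited noise, 1–2× R
  peak, 0.5–2 s.  Recording quality is bimodal, as in handheld screening:
  by default 30% of recordings carry pervasive noise
  (spike/step/burst means 12/1/2 per recording) and the rest only mild
  artifacts (0.5/0.2/0.2).
- **Corpus structure.**  round(n_subjects × prevalence) subjects are AF;
  each receives at least `min_af_recordings` AF recordings.  Defaults echo
  the screening regime: 26 recordings per subject, prevalence 0.024.
- **Event labeling.**  Detections are matched to true beats greedily
  nearest-first within a 75-ms tolerance (half a conservative refractory
  period); each beat matches at most one detection; everything unmatched is
  a false detection.

### The reference QRS detector

Deliberately naive — band-pass 5–25 Hz, squaring, threshold at an adaptive
multiple (3×) of the blockwise running median absolute amplitude, 250-ms
refractory period — so that transient noise produces false detections, the
failure mode the quality-control stage exists to fix.  It is not a
production detector and is not meant to compete with one.

### What the generator does and does not show

Passing tests on this corpus demonstrate that the pipeline's mechanics are
correct and that the quality-control stage removes noise-induced false
alarms *when noise events are morphologically distinct from QRS complexes*.
Real screening ECGs contain noise that mimics QRS morphology, inverted
leads, drifting electrode contact, and rhythms (flutter, bigeminy) the
generator does not model; absolute performance numbers on synthetic corpora
therefore do not transfer to clinical data, and synthetic noise realism is
validated only through the separability property (the CNN must exceed 95%
held-out accuracy under the default regime).

## 5. Problem sizes

The standing training problem used by the test suite and the acceptance
script: an event corpus of 24 subjects × 5 recordings with elevated
artifact rates, yielding ≥ 5,000 events at ≈ 3:1 true-beat:false-detection
imbalance; CNN training for up to 20 epochs with patience 3.  The screening
evaluation uses 200 subjects × 5 recordings at 5% prevalence with every AF
subject holding ≥ 3 AF recordings.  The grid search is exercised on planted
RR statistics (irregular AF, regular sinus, noise-fragmented sinus) and
verified combination-by-combination against an independent brute-force
table.  These sizes keep a full run to minutes on one CPU while leaving
every statistical margin comfortable.

## 6. Design choices where the design was open

- **Direction of the irregularity count.**  The concordance-style step
  function H(γ − |Δ|) and the rule "Λ above η ⇒ irregular" cannot both hold;
  a discordance fraction (pairs *exceeding* γ) is the only reading
  consistent with the tuned α range and the irregularity semantics, so that
  is what `irregularity_fraction` computes, with the concordance form kept
  behind a flag and tested via the complement identity.
- **Dropout placement.**  Dropout lives after the first two fully connected
  layers (following the complete layer listing rather than the prose
  mention of the convolutional stage).
- **Second fully connected layer width 40**, consistent with its parameter
  count (1,640 = 40×40 + 40) and output shape.
- **Boundary events.**  Segments crossing a recording edge are
  edge-replicated to 400 samples and flagged `padded`, so either inclusion
  policy can be audited downstream; constant segments normalize to 0.5.
- **Early stopping** restores best-epoch weights; patience is configurable
  with the literal stop-on-any-increase rule as default 0.
- **Merge-rule scope.**  "Normally spaced" is judged against the
  recording-level median true-true RR; only single false detections merge.
- **Window containment** for disqualification is strict interior of the
  window's time span.
- **Split balancing** is at subject level; exact 60/20/20 event fractions
  are therefore only approximate, which is the price of subject
  disjointness.

## 7. Limitations

- The CNN is trained per lead; segments from other leads require retraining.
- Episode boundaries within a recording are not localized; the decision is
  per recording.
- The detector analyzes rhythm only; no f-wave/atrial-activity features.
- The numpy training loop is single-threaded; it is sized for the corpora
  above, not for million-event datasets.
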