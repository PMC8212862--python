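# afqc — quality-controlled AF screening on single-lead handheld ECGs

Mass screening for atrial fibrillation (AF) with thumb-contact handheld
devices produces huge numbers of short (30 s) lead-I ECGs of very mixed
quality.  Transient noise — spikes, baseline steps, muscle bursts — makes
QRS detectors emit *false detections*, which turn a regular rhythm into an
apparently irregular one, which in turn triggers false AF alarms and an
expensive expert-review load.

`afqc` implements an event-level quality-control stage, inserted between the
QRS detector and a low-complexity RR-irregularity AF detector, for exactly
this setting.  It is aimed at biomedical-signal-processing researchers and
engineers who want a complete, reproducible, dependency-light reference
pipeline: every stage runs on seeded synthetic screening corpora, so no
clinical data is required to exercise or extend it.

## The method

**Quality-control CNN.**  Every detector event is a 400-ms segment (150 ms
before to 250 ms after the occurrence time, at 1 kHz) min-max normalized to
[0, 1].  A small 1-D CNN — convolutions of 16/32/64 filters (kernel 10,
stride 2, no padding), average pooling (kernel 5, stride 2) after the second
and third convolutions, then fully connected layers of 40, 40 and 1 neurons
with dropout 0.5/0.25 — maps each segment to the probability that the event
is a false detection.  Class imbalance between the M₀ true beats and M₁
false detections is handled by a weighted binary cross entropy

```
L = -(1/M) Σᵢ [ w₁ yᵢ log(ŷᵢ) + w₀ (1-yᵢ) log(1-ŷᵢ) ],   w_j = M / (2 M_j),
```

and the decision threshold is chosen to maximize F1 on a subject-disjoint
validation split.  The network is implemented from scratch in numpy
(forward, backprop, Adam, seeded initialization), so training is exactly
reproducible and the package has no deep-learning dependency.

**AF detector.**  For a sliding window of N consecutive RR intervals
r(0..N-1), the irregularity fraction is

```
Λᵢ = #{ j<k : |r(j) - r(k)| > γᵢ } / ((N-1)(N-2)),    γᵢ = α · median(window).
```

A window is irregular when Λᵢ ≥ η, and a recording is called AF when the
fraction of irregular windows among the I qualifying windows reaches
η_d = 1/3 (the threshold that encodes "10 s of AF in a 30-s recording is
AF").  With quality control, CNN-flagged false detections are removed first:
an isolated false detection between two normally spaced true beats (spanning
interval within 15% of the median RR) is silently merged away, and every
other removal disqualifies the sliding windows containing it.  (N, α, η) are
tuned by exhaustive grid search (N ∈ {4..8}, α ∈ {0.03..0.12},
η ∈ {0.05..0.95}) minimizing the recording-level false positive rate subject
to sensitivity ≥ 99%; the shipped presets are (8, 0.07, 0.55) without and
(4, 0.04, 0.65) with quality control.

## Worked example

```python
import numpy as np
from afqc import (RhythmSpec, gen_rr_series, render_ecg, detect_qrs,
                  rr_intervals, detect_af, PRESET_WITHOUT_QC)

spec = RhythmSpec(kind="af", mean_rr=700.0, rr_sd=180.0)
beats = gen_rr_series(spec, duration=30.0, seed=1)       # ground-truth beats
rec, truth = render_ecg(beats, spec, seed=1)             # 30 s of synthetic ECG
times = detect_qrs(rec)                                  # reference detector
decision = detect_af(rr_intervals(times), PRESET_WITHOUT_QC)
print(f"true beats: {len(beats)}, detections: {len(times)}")
print(f"decision: {decision.label}  "
      f"(irregular-window fraction {decision.fraction:.2f} over "
      f"{decision.n_qualifying} windows)")
```

prints

```
true beats: 42, detections: 42
decision: AF  (irregular-window fraction 0.62 over 34 windows)
```

i.e. all 42 fibrillatory beats are found, 62% of the 34 sliding windows are
irregular, and since 0.62 ≥ η_d = 1/3 the recording is labeled AF.

For the model-fitting surfaces, `QcClassifier(dataset).fit()` returns a
results object with the trained CNN, the F1-optimal threshold and per-split
metrics (`.summary()` prints a table), and `DetectorTuner(train).fit()` runs
the constrained grid search.  The `afqc` command-line tool exposes the
stages individually (`simulate`, `detect-qrs`, `extract-events`, `train-qc`,
`classify`, `detect-af`, `optimize`, `evaluate`, `run-all`).

## Layout

- `afqc.corpus` — seeded synthetic corpus generator (rhythms, PQRST
  rendering, transient-noise injection, beat-level ground truth)
- `afqc.events` — reference QRS detector, 400-ms event segments, subject-
  disjoint 60/20/20 splits
- `afqc.qc` — the quality-control CNN (architecture, weighted loss,
  training, threshold selection) and its Model/Results surface
- `afqc.detector` — Λ statistic, window flags, QC pruning, recording decision
- `afqc.evaluation` — metrics at event/recording/patient level, subject
  splits, constrained grid search, repeated evaluation
- `afqc.pipeline`, `afqc.io`, `afqc.cli` — orchestration, file formats, CLI

`docs/methods.md` documents the models, the synthetic-data assumptions, and
the numerical choices in detail.
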