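"""Shared fixtures: synthetic corpora and a trained quality-control CNN.

The heavyweight objects (the event corpus and the CNN trained on it) are
session-scoped so the model is trained once and reused by every test that
needs a classifier.
"""

from __future__ import annotations

import numpy as np
import pytest

from afqc.corpus import EVENT_CORPUS_NOISE, RhythmSpec, build_corpus, gen_rr_series, render_ecg
from afqc.events import build_event_dataset
from afqc.qc import TrainConfig, select_threshold, train_qc

# sizes of the standing training problem; chosen so the dataset clears
# 5,000 events at roughly 3:1 class imbalance
EVENT_CORPUS_KW = dict(
    n_subjects=24,
    recordings_per_subject=5,
    af_prevalence=0.08,
    seed=11,
    noise=EVENT_CORPUS_NOISE,
    noisy_fraction=0.0,
)
TRAIN_KW = dict(epochs=20, patience=3)


@pytest.fixture(scope="session")
def event_corpus():
    return build_corpus(**EVENT_CORPUS_KW)


@pytest.fixture(scope="session")
def event_dataset(event_corpus):
    return build_event_dataset(event_corpus, seed=11)


@pytest.fixture(scope="session")
def trained_qc(event_dataset):
    """(model, threshold, history) of the CNN trained with seed 0."""
    model, history = train_qc(event_dataset,
                              tconfig=TrainConfig(seed=0, **TRAIN_KW))
    X_val, y_val = event_dataset.subset("validation")
    theta, _ = select_threshold(model.predict_proba(X_val), y_val)
    return model, theta, history


@pytest.fixture()
def sinus_recording():
    """One clean 30-s sinus recording with its ground truth."""
    spec = RhythmSpec(kind="sinus", mean_rr=800.0, rr_sd=30.0)
    beats = gen_rr_series(spec, 30.0, seed=1)
    return render_ecg(beats, spec, seed=3)
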