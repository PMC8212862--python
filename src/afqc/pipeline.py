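"""End-to-end orchestration: simulate -> detect -> quality control -> AF detection.

The pipeline mirrors the screening workflow: a QRS detector runs on every
recording; each detector event is classified by the quality-control CNN;
CNN-flagged false detections are pruned (with window disqualification) before
the RR-irregularity AF detector decides each recording; performance is
reported at recording and patient level, with and without quality control.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .corpus import (
    Corpus,
    DEFAULT_NOISE,
    EVENT_CORPUS_NOISE,
    NoiseSpec,
    build_corpus,
)
from .detector import (
    DetectorParams,
    PRESET_WITH_QC,
    PRESET_WITHOUT_QC,
    qc_prune,
)
from .events import build_event_dataset, detect_qrs, extract_segment, minmax_normalize
from .evaluation import (
    RecordingSeries,
    decide_recordings,
    metrics,
    patient_sensitivity,
    recording_confusion,
    review_load,
)
from .qc import QcModel, QcModelConfig, TrainConfig, classify_events, train_qc, select_threshold

__all__ = [
    "PipelineConfig",
    "extract_series",
    "evaluate_series",
    "train_quality_model",
    "run_pipeline",
]


@dataclass
class PipelineConfig:
    """Everything needed for a deterministic end-to-end run."""

    # screening corpus
    n_subjects: int = 50
    recordings_per_subject: int = 5
    af_prevalence: float = 0.05
    min_af_recordings: int = 3
    corpus_seed: int = 100
    noise: NoiseSpec = field(default_factory=lambda: DEFAULT_NOISE)
    # CNN training corpus (event-level)
    train_subjects: int = 24
    train_recordings_per_subject: int = 5
    train_corpus_seed: int = 11
    train_noise: NoiseSpec = field(default_factory=lambda: EVENT_CORPUS_NOISE)
    split_seed: int = 11
    # CNN training
    epochs: int = 30
    patience: int = 3
    train_seed: int = 0
    # detector
    params_without_qc: DetectorParams = field(
        default_factory=lambda: PRESET_WITHOUT_QC)
    params_with_qc: DetectorParams = field(default_factory=lambda: PRESET_WITH_QC)
    tolerance: float = 75.0


def train_quality_model(config: PipelineConfig) -> tuple[QcModel, float, dict]:
    """Build the event corpus, train the CNN, pick the F1-optimal threshold."""
    corpus = build_corpus(
        config.train_subjects,
        recordings_per_subject=config.train_recordings_per_subject,
        af_prevalence=0.08,
        seed=config.train_corpus_seed,
        noise=config.train_noise,
        noisy_fraction=0.0,
    )
    dataset = build_event_dataset(corpus, seed=config.split_seed,
                                  tolerance=config.tolerance)
    model, history = train_qc(
        dataset, QcModelConfig(),
        TrainConfig(epochs=config.epochs, patience=config.patience,
                    seed=config.train_seed))
    X_val, y_val = dataset.subset("validation")
    theta, f1 = select_threshold(model.predict_proba(X_val), y_val)
    info = {"events": dataset.M, "true_beats": dataset.M0,
            "false_detections": dataset.M1, "epochs_run": len(history),
            "threshold": theta, "validation_f1": f1}
    return model, theta, info


def extract_series(
    corpus: Corpus,
    model: QcModel | None = None,
    threshold: float | None = None,
    tolerance: float = 75.0,
) -> tuple[list[RecordingSeries], list[RecordingSeries] | None]:
    """Detector series for every recording, without and (optionally) with QC.

    Without QC every detection is accepted.  With QC, the CNN labels each
    event and `qc_prune` removes the false detections, marking disqualified
    window spans via `excluded_times`.
    """
    plain: list[RecordingSeries] = []
    pruned: list[RecordingSeries] | None = [] if model is not None else None
    for rec, truth in corpus.recordings:
        det = detect_qrs(rec)
        plain.append(RecordingSeries(
            recording_id=rec.recording_id, subject_id=rec.subject_id,
            truth_label=truth.rhythm_label, times=det))
        if model is None:
            continue
        if det.size:
            segs = np.stack([minmax_normalize(extract_segment(rec, t)[0])
                             for t in det])
            labels, _ = classify_events(model, segs, threshold)
        else:
            labels = np.empty(0, dtype=np.int8)
        res = qc_prune(det, labels)
        pruned.append(RecordingSeries(
            recording_id=rec.recording_id, subject_id=rec.subject_id,
            truth_label=truth.rhythm_label, times=res.accepted_times,
            excluded_times=res.excluded_times))
    return plain, pruned


def evaluate_series(series, corpus: Corpus, params: DetectorParams) -> dict:
    """Recording-level metrics, patient-level sensitivity, and review load."""
    decisions = decide_recordings(series, params)
    truth = {s.recording_id: s.truth_label for s in series}
    counts = recording_confusion(decisions, truth)
    m = metrics(counts)
    rec_subject = {s.recording_id: s.subject_id for s in series}
    p_se = patient_sensitivity(
        {rid: d.is_af for rid, d in decisions.items()},
        rec_subject, corpus.af_subjects)
    return {
        "counts": {"TP": counts.tp, "FP": counts.fp,
                   "TN": counts.tn, "FN": counts.fn},
        "metrics": {k: v for k, v in m.as_dict().items()},
        "patient_sensitivity": p_se,
        "review_load": review_load(counts),
        "params": {"N": params.N, "alpha": params.alpha,
                   "eta": params.eta, "eta_d": params.eta_d},
    }


def run_pipeline(config: PipelineConfig = PipelineConfig()) -> dict:
    """Full run; returns a deterministic report dictionary.

    Stages: simulate training corpus -> train CNN -> simulate screening
    corpus -> QRS detection -> event classification + pruning -> AF detection
    with and without quality control -> metrics.
    """
    model, theta, train_info = train_quality_model(config)
    corpus = build_corpus(
        config.n_subjects,
        recordings_per_subject=config.recordings_per_subject,
        af_prevalence=config.af_prevalence,
        seed=config.corpus_seed,
        noise=config.noise,
        min_af_recordings=config.min_af_recordings,
    )
    plain, pruned = extract_series(corpus, model, theta,
                                   tolerance=config.tolerance)
    report = {
        "training": train_info,
        "corpus": {
            "subjects": len(corpus.subjects),
            "recordings": len(corpus),
            "af_subjects": len(corpus.af_subjects),
            "af_recordings": sum(t.is_af for _, t in corpus.recordings),
        },
        "without_qc": evaluate_series(plain, corpus, config.params_without_qc),
        "with_qc": evaluate_series(pruned, corpus, config.params_with_qc),
    }
    return report
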