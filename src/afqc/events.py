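"""Event extraction: QRS detection and fixed-length normalized segments.

An *event* is a 400-ms window around a QRS-detector occurrence time — 150 ms
before and 250 ms after — min-max normalized to [0, 1].  These are the inputs
the signal-quality CNN classifies into true beat detections and false
(noise-induced) detections.

The reference QRS detector here is deliberately simple (band-pass, square,
adaptive threshold, refractory period) so that transient noise produces false
detections — exactly the failure mode the quality-control stage removes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .corpus import (
    Corpus,
    EcgRecording,
    FALSE_DETECTION,
    TRUE_BEAT,
    label_events,
)

__all__ = [
    "Detection",
    "EventDataset",
    "SEGMENT_PRE_MS",
    "SEGMENT_POST_MS",
    "SEGMENT_LEN",
    "detect_qrs",
    "extract_segment",
    "minmax_normalize",
    "resample_to_1khz",
    "assign_subject_splits",
    "build_event_dataset",
]

SEGMENT_PRE_MS = 150
SEGMENT_POST_MS = 250
SEGMENT_LEN = SEGMENT_PRE_MS + SEGMENT_POST_MS  # samples at 1,000 Hz
TARGET_FS = 1000.0

SPLITS = ("train", "validation", "test")


@dataclass
class Detection:
    """One detector event: occurrence time (ms) plus its normalized segment."""

    time: float
    segment: np.ndarray
    padded: bool = False
    probability: float | None = None


# ---------------------------------------------------------------------------
# Reference QRS detector
# ---------------------------------------------------------------------------

def _running_median_abs(x: np.ndarray, fs: float, block_s: float = 2.0) -> np.ndarray:
    """Blockwise running median of |x|, linearly interpolated to sample grid."""
    n = len(x)
    block = max(int(round(block_s * fs)), 1)
    starts = np.arange(0, n, block)
    meds = np.array([np.median(np.abs(x[s:s + block])) for s in starts])
    centers = np.minimum(starts + block / 2.0, n - 1)
    if len(meds) == 1:
        return np.full(n, meds[0])
    return np.interp(np.arange(n), centers, meds)


def detect_qrs(rec: EcgRecording, threshold_factor: float = 3.0) -> np.ndarray:
    """Naive reference QRS detector; returns sorted detection times in ms.

    Band-passes the signal to 5-25 Hz, squares it, thresholds at an adaptive
    multiple of the running median absolute amplitude, and enforces a 250-ms
    refractory period.  Deterministic.
    """
    if rec.fs < 250:
        raise ValueError("detect_qrs requires fs >= 250 Hz")
    if rec.duration < 1.0:
        warnings.warn("recording shorter than 1 s; no detections emitted")
        return np.empty(0)
    sos = sps.butter(3, [5.0, 25.0], btype="bandpass", fs=rec.fs, output="sos")
    bp = sps.sosfiltfilt(sos, rec.samples)
    env = bp ** 2
    thr = (threshold_factor * _running_median_abs(bp, rec.fs)) ** 2
    # floor guards against near-flat stretches where the median is ~0
    thr = np.maximum(thr, 1e-6)
    peaks, _ = sps.find_peaks(env, height=thr, distance=int(round(0.25 * rec.fs)))
    return peaks * 1000.0 / rec.fs


# ---------------------------------------------------------------------------
# Segments
# ---------------------------------------------------------------------------

def resample_to_1khz(rec: EcgRecording) -> EcgRecording:
    """Polyphase-resample a recording to 1,000 Hz (no-op if already there)."""
    if rec.fs == TARGET_FS:
        return rec
    from fractions import Fraction

    frac = Fraction(TARGET_FS / rec.fs).limit_denominator(1000)
    out = sps.resample_poly(rec.samples, frac.numerator, frac.denominator)
    return EcgRecording(subject_id=rec.subject_id, recording_id=rec.recording_id,
                        fs=TARGET_FS, samples=out)


def extract_segment(rec: EcgRecording, t: float) -> tuple[np.ndarray, bool]:
    """Raw 400-ms window [t-150, t+250) ms as 400 samples at 1,000 Hz.

    Windows crossing a recording boundary are edge-replicated to full length
    and flagged ``padded``.
    """
    if not 0 <= t < rec.duration_ms:
        raise ValueError(f"t={t} ms outside recording of {rec.duration_ms} ms")
    rec = resample_to_1khz(rec)
    n = len(rec.samples)
    start = int(round(t)) - SEGMENT_PRE_MS
    stop = start + SEGMENT_LEN
    lo, hi = max(start, 0), min(stop, n)
    seg = rec.samples[lo:hi]
    pad_left, pad_right = lo - start, stop - hi
    padded = pad_left > 0 or pad_right > 0
    if padded:
        seg = np.pad(seg, (pad_left, pad_right), mode="edge")
    return seg, padded


def minmax_normalize(segment: np.ndarray) -> np.ndarray:
    """Scale a segment to [0, 1]; a constant segment maps to all 0.5."""
    segment = np.asarray(segment, dtype=float)
    if segment.size == 0:
        raise ValueError("segment must be non-empty")
    lo, hi = segment.min(), segment.max()
    if hi == lo:
        return np.full_like(segment, 0.5)
    return (segment - lo) / (hi - lo)


def extract_event(rec: EcgRecording, t: float) -> Detection:
    """Convenience: extract + normalize one event."""
    seg, padded = extract_segment(rec, t)
    return Detection(time=float(t), segment=minmax_normalize(seg), padded=padded)


# ---------------------------------------------------------------------------
# Event dataset with subject-disjoint splits
# ---------------------------------------------------------------------------

@dataclass
class EventDataset:
    """Labeled event segments with subject-disjoint train/validation/test splits.

    y follows the convention 0 = true beat, 1 = false detection (the positive
    class of the quality-control task).
    """

    X: np.ndarray                 # (M, 400) float32, values in [0, 1]
    y: np.ndarray                 # (M,) int8
    split: np.ndarray             # (M,) of {"train","validation","test"}
    subject_ids: np.ndarray       # (M,) str
    recording_ids: np.ndarray     # (M,) str
    times: np.ndarray             # (M,) float, ms
    padded: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.padded is None:
            self.padded = np.zeros(len(self.y), dtype=bool)
        lengths = {len(a) for a in (self.X, self.y, self.split,
                                    self.subject_ids, self.recording_ids,
                                    self.times, self.padded)}
        if len(lengths) != 1:
            raise ValueError("all event arrays must have equal length")
        for name in SPLITS:
            subs = set(self.subject_ids[self.split == name])
            others = set(self.subject_ids[self.split != name])
            if subs & others:
                raise ValueError("a subject appears in more than one split")

    @property
    def M(self) -> int:
        return len(self.y)

    @property
    def M0(self) -> int:
        """Number of true beat detections."""
        return int(np.sum(self.y == 0))

    @property
    def M1(self) -> int:
        """Number of false detections."""
        return int(np.sum(self.y == 1))

    def subset(self, split: str) -> tuple[np.ndarray, np.ndarray]:
        if split not in SPLITS:
            raise ValueError(f"unknown split {split!r}")
        m = self.split == split
        return self.X[m], self.y[m]


def assign_subject_splits(
    events_per_subject: dict[str, int],
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> dict[str, str]:
    """Assign whole subjects to splits so event fractions approximate targets.

    Subjects are shuffled, then filled greedily into train, validation, and
    test in that order until each split's event budget is reached.  Every
    split with a positive target fraction receives at least one subject when
    enough subjects exist.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    subjects = sorted(events_per_subject)
    rng.shuffle(subjects)
    total = sum(events_per_subject.values())
    targets = [f * total for f in fractions]

    assignment: dict[str, str] = {}
    filled = [0.0, 0.0, 0.0]
    n_assigned = [0, 0, 0]
    pending = [i for i, f in enumerate(fractions) if f > 0]
    for j, sid in enumerate(subjects):
        # reserve one subject for each not-yet-populated positive split
        remaining_subjects = len(subjects) - j
        needed = [i for i in pending if n_assigned[i] == 0]
        if remaining_subjects <= len(needed):
            idx = needed[0]
        else:
            idx = next((i for i in pending if filled[i] < targets[i]), pending[-1])
        assignment[sid] = SPLITS[idx]
        filled[idx] += events_per_subject[sid]
        n_assigned[idx] += 1
    return assignment


def build_event_dataset(
    corpus: Corpus,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
    tolerance: float = 75.0,
    threshold_factor: float = 3.0,
) -> EventDataset:
    """Run the reference detector on every recording and assemble labeled events.

    Splits are assigned at the subject level (no subject contributes events
    to more than one split), so the 60/20/20 event fractions are approximate.
    Deterministic given the seed.
    """
    if len(corpus.subjects) < 3:
        raise ValueError("need at least 3 subjects to form disjoint splits")

    per_rec: list[tuple[str, str, np.ndarray, np.ndarray, EcgRecording]] = []
    events_per_subject: dict[str, int] = {}
    for rec, truth in corpus.recordings:
        det = detect_qrs(rec, threshold_factor=threshold_factor)
        labels = label_events(det, truth, tolerance=tolerance)
        per_rec.append((rec.subject_id, rec.recording_id, det, labels, rec))
        events_per_subject[rec.subject_id] = (
            events_per_subject.get(rec.subject_id, 0) + det.size)
    for sid in corpus.subjects:
        events_per_subject.setdefault(sid, 0)

    assignment = assign_subject_splits(events_per_subject, fractions, seed)

    X, y, split, subs, recs, times, padded = [], [], [], [], [], [], []
    for sid, rid, det, labels, rec in per_rec:
        for t, lab in zip(det, labels):
            seg, pad = extract_segment(rec, t)
            X.append(minmax_normalize(seg).astype(np.float32))
            y.append(0 if lab == TRUE_BEAT else 1)
            split.append(assignment[sid])
            subs.append(sid)
            recs.append(rid)
            times.append(t)
            padded.append(pad)
    return EventDataset(
        X=np.asarray(X, dtype=np.float32).reshape(len(y), SEGMENT_LEN),
        y=np.asarray(y, dtype=np.int8),
        split=np.asarray(split, dtype=object),
        subject_ids=np.asarray(subs, dtype=object),
        recording_ids=np.asarray(recs, dtype=object),
        times=np.asarray(times, dtype=float),
        padded=np.asarray(padded, dtype=bool),
    )
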