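"""File formats: recordings, ground truth, events, reports, configuration.

Recordings travel as two-column CSV (time_ms, amplitude_mV); ground truth
as JSON (beat_times, noise_times, af_intervals, rhythm_label); a corpus is a
directory of those plus a manifest CSV.  All writers round-trip bit-exactly
for integer fields and to better than 1e-9 relative error for floats.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .corpus import BeatTruth, Corpus, EcgRecording, corpus_manifest
from .events import TARGET_FS, resample_to_1khz

__all__ = [
    "write_recording_csv",
    "read_recording",
    "write_truth_json",
    "read_truth_json",
    "write_corpus",
    "read_corpus",
    "write_events_csv",
    "write_json_report",
]


class ParseError(ValueError):
    """Malformed input file; message carries file and location context."""


def write_recording_csv(rec: EcgRecording, path: str | Path) -> None:
    path = Path(path)
    t_ms = np.arange(len(rec.samples)) * 1000.0 / rec.fs
    with path.open("w") as fh:
        fh.write("time_ms,amplitude_mV\n")
        for t, v in zip(t_ms, rec.samples):
            fh.write(f"{float(t)!r},{float(v)!r}\n")


def read_recording(path: str | Path, subject_id: str = "",
                   recording_id: str = "",
                   resample: bool = True) -> EcgRecording:
    """Read a two-column CSV recording; resamples to 1,000 Hz by default."""
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message varies
        raise ParseError(f"{path}: not parseable as CSV ({exc})") from exc
    for col in ("time_ms", "amplitude_mV"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    t = df["time_ms"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ParseError(f"{path}: need at least two samples")
    dt = np.diff(t)
    bad = np.flatnonzero(dt <= 0)
    if bad.size:
        raise ParseError(
            f"{path}: time_ms not strictly increasing at line {bad[0] + 2}")
    if np.max(np.abs(dt - dt[0])) > 1e-6 * dt[0]:
        raise ParseError(f"{path}: time_ms not uniformly sampled")
    fs = 1000.0 / dt[0]
    rec = EcgRecording(subject_id=subject_id or path.stem,
                       recording_id=recording_id or path.stem,
                       fs=fs, samples=df["amplitude_mV"].to_numpy(dtype=float))
    if resample and fs != TARGET_FS:
        rec = resample_to_1khz(rec)
    return rec


def write_truth_json(truth: BeatTruth, path: str | Path) -> None:
    payload = {
        "beat_times": [float(t) for t in truth.beat_times],
        "noise_times": [float(t) for t in truth.noise_times],
        "af_intervals": [[float(a), float(b)] for a, b in truth.af_intervals],
        "rhythm_label": truth.rhythm_label,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth_json(path: str | Path) -> BeatTruth:
    raw = json.loads(Path(path).read_text())
    return BeatTruth(
        beat_times=np.asarray(raw["beat_times"], dtype=float),
        rhythm_label=raw["rhythm_label"],
        noise_times=np.asarray(raw["noise_times"], dtype=float),
        af_intervals=tuple((a, b) for a, b in raw["af_intervals"]),
    )


def write_corpus(corpus: Corpus, out_dir: str | Path,
                 splits: dict[str, str] | None = None) -> None:
    """Write a corpus directory: per-recording CSV + truth JSON + manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for rec, truth in corpus.recordings:
        write_recording_csv(rec, out / f"{rec.recording_id}.csv")
        write_truth_json(truth, out / f"{rec.recording_id}.truth.json")
    corpus_manifest(corpus, splits).to_csv(out / "manifest.csv", index=False)
    meta = {"seed": corpus.seed,
            "subjects": {k: list(v) for k, v in sorted(corpus.subjects.items())},
            "af_subjects": sorted(corpus.af_subjects)}
    (out / "corpus.json").write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_corpus(in_dir: str | Path) -> Corpus:
    src = Path(in_dir)
    meta = json.loads((src / "corpus.json").read_text())
    subjects = {k: tuple(v) for k, v in meta["subjects"].items()}
    recordings = []
    for sid, rec_ids in sorted(subjects.items()):
        for rid in rec_ids:
            rec = read_recording(src / f"{rid}.csv", subject_id=sid,
                                 recording_id=rid)
            truth = read_truth_json(src / f"{rid}.truth.json")
            recordings.append((rec, truth))
    return Corpus(recordings=tuple(recordings), subjects=subjects,
                  af_subjects=frozenset(meta["af_subjects"]),
                  seed=int(meta["seed"]))


def write_events_csv(dataset, path: str | Path) -> None:
    """One row per event: recording_id, time_ms, label, padded, then the
    400 normalized samples."""
    path = Path(path)
    with path.open("w") as fh:
        header = ",".join(["recording_id", "time_ms", "label", "split",
                           "padded"] + [f"s{i}" for i in range(dataset.X.shape[1])])
        fh.write(header + "\n")
        for i in range(dataset.M):
            vals = ",".join(f"{v:.6f}" for v in dataset.X[i])
            fh.write(f"{dataset.recording_ids[i]},{float(dataset.times[i])!r},"
                     f"{int(dataset.y[i])},{dataset.split[i]},"
                     f"{int(dataset.padded[i])},{vals}\n")


def write_json_report(report: dict, path: str | Path) -> None:
    """Deterministic JSON report (sorted keys, fixed float handling)."""
    Path(path).write_text(json.dumps(report, indent=1, sort_keys=True))
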