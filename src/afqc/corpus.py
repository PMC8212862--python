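"""Synthetic handheld-ECG screening corpora.

Screening databases recorded with thumb-contact handheld devices are dominated
by short (30 s) lead-I recordings of highly variable quality.  This module
generates seeded corpora that emulate that regime end to end: multi-recording
subjects, sinus / atrial-fibrillation (AF) / ectopy RR-interval structure, the
rule that a recording counts as AF when it contains at least 10 s of AF, and
the transient artifacts (spikes, baseline steps, muscle-noise bursts) that
make naive QRS detectors emit false detections.

Everything is a pure function of its arguments including the seed, so corpora
are bit-reproducible and every downstream stage of the pipeline can be tested
without access to clinical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal as sps
from scipy.stats import truncnorm

__all__ = [
    "RhythmSpec",
    "NoiseSpec",
    "MorphologyConfig",
    "EcgRecording",
    "BeatTruth",
    "Corpus",
    "TRUE_BEAT",
    "FALSE_DETECTION",
    "AF_LABEL",
    "NON_AF_LABEL",
    "AF_EPISODE_MIN_S",
    "gen_rr_series",
    "render_ecg",
    "inject_transients",
    "build_corpus",
    "label_events",
    "corpus_manifest",
    "DEFAULT_NOISE",
    "HEAVY_NOISE",
    "DEFAULT_MORPHOLOGY",
    "EVENT_CORPUS_NOISE",
]

TRUE_BEAT = "true_beat"
FALSE_DETECTION = "false_detection"
AF_LABEL = "AF"
NON_AF_LABEL = "non-AF"

#: Minimum total AF-episode duration (s) for a recording to be labeled AF.
AF_EPISODE_MIN_S = 10.0


# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RhythmSpec:
    """Rhythm model for one recording.

    Parameters
    ----------
    kind:
        ``"sinus"`` (regular), ``"af"`` (the whole recording is AF) or
        ``"ectopic-sinus"`` (sinus with premature beats).
    mean_rr, rr_sd:
        Mean and standard deviation of the RR interval in ms.  Sinus
        intervals are drawn from a normal truncated to [0.5, 1.5] x mean;
        AF intervals from a normal with sd >= 0.15 x mean truncated to
        [300, 1800] ms.
    af_episode:
        Optional (onset, offset) in seconds embedding a single AF episode in
        an otherwise sinus recording.  Must last at least 10 s so that the
        recording-labeling rule applies.
    ectopy_rate:
        Per-beat probability that a beat is replaced by a premature beat
        (interval x 0.6) followed by a compensatory pause (x 1.4).
    af_rr_sd:
        Standard deviation of RR intervals during AF; defaults to
        max(rr_sd, 0.15 x mean_rr) when not given.  AF at rest typically
        shows a coefficient of variation around 0.2-0.3.
    """

    kind: str = "sinus"
    mean_rr: float = 800.0
    rr_sd: float = 25.0
    af_episode: tuple[float, float] | None = None
    ectopy_rate: float = 0.0
    af_rr_sd: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("sinus", "af", "ectopic-sinus"):
            raise ValueError(f"unknown rhythm kind {self.kind!r}")
        if self.mean_rr <= 0:
            raise ValueError("mean_rr must be positive")
        if self.rr_sd < 0:
            raise ValueError("rr_sd must be non-negative")
        if not 0.0 <= self.ectopy_rate <= 1.0:
            raise ValueError("ectopy_rate must be in [0, 1]")
        if self.af_rr_sd is not None and self.af_rr_sd < 0:
            raise ValueError("af_rr_sd must be non-negative")
        if self.af_episode is not None:
            onset, offset = self.af_episode
            if offset - onset < AF_EPISODE_MIN_S:
                raise ValueError(
                    "an embedded AF episode must last at least "
                    f"{AF_EPISODE_MIN_S:g} s"
                )

    def af_intervals(self, duration: float) -> list[tuple[float, float]]:
        """AF intervals (s) implied by this spec for a recording of `duration` s."""
        if self.kind == "af":
            return [(0.0, duration)]
        if self.af_episode is not None:
            onset, offset = self.af_episode
            return [(max(onset, 0.0), min(offset, duration))]
        return []


@dataclass(frozen=True)
class NoiseSpec:
    """Transient-artifact model for one recording.

    Artifact counts per recording are Poisson with the given means.  Spikes
    are 10-50 ms biphasic deflections; steps are baseline offsets with
    exponential recovery (time constant 0.2-1 s); bursts are band-limited
    20-100 Hz noise lasting `burst_duration_range` seconds.  Amplitudes are
    expressed as multiples of the R-wave amplitude.
    """

    spike_rate: float = 0.5
    step_rate: float = 0.2
    burst_rate: float = 0.2
    spike_amp_range: tuple[float, float] = (1.5, 3.0)
    step_amp_range: tuple[float, float] = (0.5, 2.0)
    burst_amp_range: tuple[float, float] = (1.0, 2.0)
    burst_duration_range: tuple[float, float] = (0.5, 2.0)

    def __post_init__(self) -> None:
        for name in ("spike_rate", "step_rate", "burst_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("spike_amp_range", "step_amp_range", "burst_amp_range",
                     "burst_duration_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be a positive (lo, hi) range")


@dataclass(frozen=True)
class MorphologyConfig:
    """Waveform-morphology defaults, pinned in one place so tests can rely on them.

    Each wave is (name, offset from R in ms, Gaussian width in ms, amplitude
    in mV); a beat is rendered as the sum of these Gaussians.  During AF the
    P wave is suppressed and a small 4-12 Hz fibrillatory baseline is added.
    """

    waves: tuple[tuple[str, float, float, float], ...] = (
        ("P", -180.0, 25.0, 0.12),
        ("Q", -22.0, 9.0, -0.08),
        ("R", 0.0, 11.0, 1.0),
        ("S", 25.0, 9.0, -0.18),
        ("T", 160.0, 60.0, 0.35),
    )
    fibrillatory_amp: float = 0.035
    fibrillatory_band: tuple[float, float] = (4.0, 12.0)
    wander_amp: float = 0.05
    wander_freq_range: tuple[float, float] = (0.05, 0.15)
    noise_sd: float = 0.01  # white measurement noise, mV (contract: <= 0.02)

    @property
    def r_amplitude(self) -> float:
        return next(a for (n, _, _, a) in self.waves if n == "R")


DEFAULT_MORPHOLOGY = MorphologyConfig()

#: Mild artifact rates of a good-quality recording.
DEFAULT_NOISE = NoiseSpec()

#: Pervasive artifact rates of a poor-quality recording (bad electrode
#: contact, motion): transient noise throughout the 30 s.
HEAVY_NOISE = NoiseSpec(spike_rate=12.0, step_rate=1.0, burst_rate=2.0)

#: Elevated artifact rates used when compiling CNN training events, emulating
#: the practice of harvesting false detections from noise-heavy recordings;
#: yields roughly a 3:1 true-beat : false-detection imbalance.
EVENT_CORPUS_NOISE = NoiseSpec(spike_rate=14.0, step_rate=1.0, burst_rate=1.5)


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EcgRecording:
    """One 30-s single-lead ECG: amplitude samples (mV) at sampling rate fs (Hz)."""

    subject_id: str
    recording_id: str
    fs: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))

    @property
    def duration(self) -> float:
        """Recording duration in seconds."""
        return len(self.samples) / self.fs

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.duration


@dataclass(frozen=True)
class BeatTruth:
    """Ground truth for one synthetic recording.

    beat_times and noise_times are in ms; af_intervals in seconds.  The
    rhythm label is AF exactly when the summed AF-interval duration reaches
    10 s, mirroring the screening annotation rule.
    """

    beat_times: np.ndarray
    rhythm_label: str
    noise_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    af_intervals: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        beats = np.asarray(self.beat_times, dtype=float)
        noise = np.asarray(self.noise_times, dtype=float)
        if beats.size and np.any(np.diff(beats) <= 0):
            raise ValueError("beat_times must be strictly increasing")
        object.__setattr__(self, "beat_times", beats)
        object.__setattr__(self, "noise_times", np.sort(noise))
        total_af = sum(off - on for on, off in self.af_intervals)
        expected = AF_LABEL if total_af >= AF_EPISODE_MIN_S else NON_AF_LABEL
        if self.rhythm_label != expected:
            raise ValueError(
                f"rhythm_label {self.rhythm_label!r} inconsistent with "
                f"{total_af:g} s of AF"
            )

    @property
    def is_af(self) -> bool:
        return self.rhythm_label == AF_LABEL


@dataclass(frozen=True)
class Corpus:
    """A synthetic screening corpus: recordings grouped by subject."""

    recordings: tuple[tuple[EcgRecording, BeatTruth], ...]
    subjects: dict[str, tuple[str, ...]]
    af_subjects: frozenset[str]
    seed: int

    def __post_init__(self) -> None:
        owner: dict[str, str] = {}
        for sid, rec_ids in self.subjects.items():
            for rid in rec_ids:
                if rid in owner:
                    raise ValueError(f"recording {rid} assigned to two subjects")
                owner[rid] = sid
        af_truth = {
            sid for sid, rec_ids in self.subjects.items()
            if any(t.is_af for r, t in self.recordings if r.recording_id in rec_ids)
        }
        if af_truth != set(self.af_subjects):
            raise ValueError("af_subjects inconsistent with recording labels")

    def __len__(self) -> int:
        return len(self.recordings)

    def subject_of(self, recording_id: str) -> str:
        for sid, rec_ids in self.subjects.items():
            if recording_id in rec_ids:
                return sid
        raise KeyError(recording_id)


# ---------------------------------------------------------------------------
# RR-interval generation
# ---------------------------------------------------------------------------

def _draw_truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                           lo: float, hi: float) -> float:
    if sd == 0:
        return float(mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _in_af(t_ms: float, af_intervals_ms: Sequence[tuple[float, float]]) -> bool:
    return any(on <= t_ms < off for on, off in af_intervals_ms)


def gen_rr_series(spec: RhythmSpec, duration: float, seed: int) -> np.ndarray:
    """Generate strictly increasing beat times (ms) covering [0, duration) s.

    Sinus intervals ~ N(mean_rr, rr_sd) truncated to [0.5, 1.5] x mean_rr;
    AF intervals ~ N(mean_rr, max(rr_sd, 0.15 x mean_rr)) truncated to
    [300, 1800] ms; ectopic beats substitute a premature beat (x0.6) plus a
    compensatory pause (x1.4) with probability ``ectopy_rate``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    dur_ms = 1000.0 * duration
    af_ms = [(1000.0 * on, 1000.0 * off) for on, off in spec.af_intervals(duration)]

    times = [float(rng.uniform(40.0, min(spec.mean_rr, dur_ms)))]
    while True:
        t = times[-1]
        if _in_af(t, af_ms):
            af_sd = (spec.af_rr_sd if spec.af_rr_sd is not None
                     else max(spec.rr_sd, 0.15 * spec.mean_rr))
            iv = _draw_truncated_normal(rng, spec.mean_rr, af_sd, 300.0, 1800.0)
            ectopic = False
        else:
            iv = _draw_truncated_normal(
                rng, spec.mean_rr, spec.rr_sd,
                0.5 * spec.mean_rr, 1.5 * spec.mean_rr)
            ectopic = (spec.ectopy_rate > 0
                       and rng.uniform() < spec.ectopy_rate)
        if ectopic:
            premature = t + 0.6 * iv
            if premature >= dur_ms:
                break
            times.append(premature)
            pause_end = premature + 1.4 * iv
            if pause_end >= dur_ms:
                break
            times.append(pause_end)
        else:
            nxt = t + iv
            if nxt >= dur_ms:
                break
            times.append(nxt)
    return np.asarray(times)


# ---------------------------------------------------------------------------
# Waveform rendering
# ---------------------------------------------------------------------------

def _add_gaussian(x: np.ndarray, fs: float, center_ms: float, width_ms: float,
                  amp: float) -> None:
    """Add amp * exp(-(t-c)^2 / (2 w^2)) in place, evaluated on +-4 widths."""
    n = len(x)
    c = center_ms * fs / 1000.0
    w = width_ms * fs / 1000.0
    i0 = max(int(np.floor(c - 4 * w)), 0)
    i1 = min(int(np.ceil(c + 4 * w)) + 1, n)
    if i0 >= i1:
        return
    idx = np.arange(i0, i1)
    x[i0:i1] += amp * np.exp(-0.5 * ((idx - c) / w) ** 2)


def render_ecg(
    beat_times: np.ndarray,
    spec: RhythmSpec,
    fs: float = 1000.0,
    seed: int = 0,
    duration: float = 30.0,
    morphology: MorphologyConfig = DEFAULT_MORPHOLOGY,
    subject_id: str = "S0",
    recording_id: str = "R0",
) -> tuple[EcgRecording, BeatTruth]:
    """Render beat times into a PQRST waveform plus baseline wander and noise.

    Each beat is a sum of Gaussians (P, Q, R, S, T).  Within AF intervals the
    P wave is suppressed and a small 4-12 Hz fibrillatory baseline is added.
    A <= 0.15 Hz sinusoidal baseline wander and white measurement noise
    (sd <= 0.02 mV) are always present.
    """
    beat_times = np.asarray(beat_times, dtype=float)
    if beat_times.size and np.any(np.diff(beat_times) <= 0):
        raise ValueError("beat_times must be strictly increasing")
    if fs <= 0:
        raise ValueError("fs must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(fs * duration))
    x = np.zeros(n)
    af_iv = spec.af_intervals(duration)
    af_ms = [(1000.0 * on, 1000.0 * off) for on, off in af_iv]

    for b in beat_times:
        suppress_p = _in_af(b, af_ms)
        for name, off, width, amp in morphology.waves:
            if suppress_p and name == "P":
                continue
            _add_gaussian(x, fs, b + off, width, amp)

    # fibrillatory baseline during AF: a few incoherent sinusoids in 4-12 Hz
    t_s = np.arange(n) / fs
    for on, off in af_iv:
        mask = (t_s >= on) & (t_s < off)
        for _ in range(3):
            f = rng.uniform(*morphology.fibrillatory_band)
            phase = rng.uniform(0, 2 * np.pi)
            amp = morphology.fibrillatory_amp * rng.uniform(0.6, 1.4)
            x[mask] += amp * np.sin(2 * np.pi * f * t_s[mask] + phase)

    f_w = rng.uniform(*morphology.wander_freq_range)
    x += morphology.wander_amp * np.sin(2 * np.pi * f_w * t_s
                                        + rng.uniform(0, 2 * np.pi))
    x += rng.normal(0.0, morphology.noise_sd, n)

    total_af = sum(off - on for on, off in af_iv)
    label = AF_LABEL if total_af >= AF_EPISODE_MIN_S else NON_AF_LABEL
    rec = EcgRecording(subject_id=subject_id, recording_id=recording_id,
                       fs=fs, samples=x)
    truth = BeatTruth(beat_times=beat_times, rhythm_label=label,
                      af_intervals=tuple(af_iv))
    return rec, truth


# ---------------------------------------------------------------------------
# Transient-noise injection
# ---------------------------------------------------------------------------

def _estimate_r_amplitude(rec: EcgRecording, truth: BeatTruth,
                          morphology: MorphologyConfig) -> float:
    if truth.beat_times.size == 0:
        return morphology.r_amplitude
    half = int(round(0.02 * rec.fs))
    peaks = []
    for b in truth.beat_times:
        i = int(round(b * rec.fs / 1000.0))
        lo, hi = max(i - half, 0), min(i + half + 1, len(rec.samples))
        if lo < hi:
            peaks.append(np.max(np.abs(rec.samples[lo:hi])))
    return float(np.median(peaks)) if peaks else morphology.r_amplitude


def inject_transients(
    rec: EcgRecording,
    truth: BeatTruth,
    noise: NoiseSpec,
    seed: int,
    morphology: MorphologyConfig = DEFAULT_MORPHOLOGY,
) -> tuple[EcgRecording, BeatTruth]:
    """Superimpose spikes, baseline steps, and noise bursts on a recording.

    Counts per artifact type are Poisson with the spec's means.  True beat
    times are never moved or removed; `noise_times` records artifact centers.
    """
    rng = np.random.default_rng(seed)
    x = rec.samples.copy()
    fs = rec.fs
    n = len(x)
    dur_ms = rec.duration_ms
    r_amp = _estimate_r_amplitude(rec, truth, morphology)

    n_spikes = int(rng.poisson(noise.spike_rate))
    n_steps = int(rng.poisson(noise.step_rate))
    n_bursts = int(rng.poisson(noise.burst_rate))
    centers: list[float] = []

    for _ in range(n_spikes):
        c_ms = float(rng.uniform(0, dur_ms))
        width = rng.uniform(10.0, 50.0)  # total biphasic width, ms
        amp = rng.uniform(*noise.spike_amp_range) * r_amp * rng.choice([-1.0, 1.0])
        c = c_ms * fs / 1000.0
        w = width * fs / 1000.0
        support = 0.05 * fs  # hard-limit support to +-50 ms of the center
        i0 = max(int(np.ceil(c - support)), 0)
        i1 = min(int(np.floor(c + support)) + 1, n)
        if i0 >= i1:
            continue
        idx = np.arange(i0, i1)
        lobe = w / 4.0
        shape = (np.exp(-0.5 * ((idx - (c - lobe)) / (w / 6.0)) ** 2)
                 - np.exp(-0.5 * ((idx - (c + lobe)) / (w / 6.0)) ** 2))
        x[i0:i1] += amp * shape
        centers.append(c_ms)

    for _ in range(n_steps):
        c_ms = float(rng.uniform(0, dur_ms))
        amp = rng.uniform(*noise.step_amp_range) * r_amp * rng.choice([-1.0, 1.0])
        tau_s = rng.uniform(0.2, 1.0)
        i0 = int(round(c_ms * fs / 1000.0))
        if i0 >= n:
            continue
        t_rel = np.arange(n - i0) / fs
        x[i0:] += amp * np.exp(-t_rel / tau_s)
        centers.append(c_ms)

    for _ in range(n_bursts):
        d_s = rng.uniform(*noise.burst_duration_range)
        c_ms = float(rng.uniform(0, dur_ms))
        amp = rng.uniform(*noise.burst_amp_range) * r_amp
        half = int(round(d_s * fs / 2.0))
        i_c = int(round(c_ms * fs / 1000.0))
        i0, i1 = max(i_c - half, 0), min(i_c + half, n)
        if i1 - i0 < int(0.05 * fs):
            continue
        white = rng.normal(0.0, 1.0, i1 - i0)
        hi = min(100.0, 0.45 * fs)
        sos = sps.butter(4, [20.0, hi], btype="bandpass", fs=fs, output="sos")
        band = sps.sosfiltfilt(sos, white)
        peak = np.max(np.abs(band))
        if peak > 0:
            band *= amp / peak
        band *= sps.windows.tukey(i1 - i0, alpha=0.25)
        x[i0:i1] += band
        centers.append(c_ms)

    new_rec = replace(rec, samples=x)
    new_truth = BeatTruth(
        beat_times=truth.beat_times,
        rhythm_label=truth.rhythm_label,
        noise_times=np.sort(np.concatenate([truth.noise_times,
                                            np.asarray(centers)])),
        af_intervals=truth.af_intervals,
    )
    return new_rec, new_truth


# ---------------------------------------------------------------------------
# Corpus assembly
# ---------------------------------------------------------------------------

def build_corpus(
    n_subjects: int,
    recordings_per_subject: int = 26,
    af_prevalence: float = 0.024,
    seed: int = 0,
    *,
    duration: float = 30.0,
    fs: float = 1000.0,
    noise: NoiseSpec = DEFAULT_NOISE,
    heavy_noise: NoiseSpec = HEAVY_NOISE,
    noisy_fraction: float = 0.3,
    morphology: MorphologyConfig = DEFAULT_MORPHOLOGY,
    min_af_recordings: int = 1,
    af_recording_rate: float = 0.5,
    ectopic_fraction: float = 0.08,
) -> Corpus:
    """Build a seeded screening corpus.

    ``round(n_subjects * af_prevalence)`` subjects are designated AF; each
    receives at least ``min_af_recordings`` AF-labeled recordings (a fully-AF
    recording or one with a single embedded episode >= 10 s).  Recording
    quality is bimodal, as in handheld screening: a fraction
    ``noisy_fraction`` of recordings suffers pervasive transient noise
    (``heavy_noise``), the rest only mild artifacts (``noise``).  The default
    prevalence (0.024) and recordings-per-subject (26) echo the screening
    regime the generator emulates.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be at least 1")
    if not 0.0 <= af_prevalence <= 1.0:
        raise ValueError("af_prevalence must be in [0, 1]")
    if not 1 <= min_af_recordings <= recordings_per_subject:
        raise ValueError("min_af_recordings must be in [1, recordings_per_subject]")

    rng = np.random.default_rng(seed)
    n_af = int(round(n_subjects * af_prevalence))
    subject_ids = [f"S{i:04d}" for i in range(n_subjects)]
    af_ids = frozenset(
        subject_ids[i] for i in rng.choice(n_subjects, size=n_af, replace=False)
    ) if n_af else frozenset()

    recordings: list[tuple[EcgRecording, BeatTruth]] = []
    subjects: dict[str, tuple[str, ...]] = {}
    for sid in subject_ids:
        mean_rr = float(rng.uniform(700.0, 1000.0))
        rr_sd = float(rng.uniform(10.0, 25.0))
        is_af_subject = sid in af_ids
        if is_af_subject:
            af_flags = rng.uniform(size=recordings_per_subject) < af_recording_rate
            deficit = min_af_recordings - int(af_flags.sum())
            if deficit > 0:
                af_flags[np.flatnonzero(~af_flags)[:deficit]] = True
        else:
            af_flags = np.zeros(recordings_per_subject, dtype=bool)

        rec_ids = []
        for k in range(recordings_per_subject):
            rid = f"{sid}-{k:03d}"
            rec_ids.append(rid)
            if af_flags[k]:
                af_mean = 0.85 * mean_rr
                if rng.uniform() < 0.6:
                    spec = RhythmSpec(kind="af", mean_rr=af_mean,
                                      rr_sd=0.3 * af_mean)
                else:
                    ep_dur = float(rng.uniform(14.0, min(25.0, duration)))
                    onset = float(rng.uniform(0.0, duration - ep_dur))
                    spec = RhythmSpec(kind="sinus", mean_rr=mean_rr, rr_sd=rr_sd,
                                      af_episode=(onset, onset + ep_dur),
                                      af_rr_sd=0.3 * mean_rr)
            elif rng.uniform() < ectopic_fraction:
                spec = RhythmSpec(kind="ectopic-sinus", mean_rr=mean_rr,
                                  rr_sd=rr_sd, ectopy_rate=0.04)
            else:
                spec = RhythmSpec(kind="sinus", mean_rr=mean_rr, rr_sd=rr_sd)

            s_rr, s_render, s_noise = (int(rng.integers(2**31)) for _ in range(3))
            rec_noise = heavy_noise if rng.uniform() < noisy_fraction else noise
            beats = gen_rr_series(spec, duration, s_rr)
            rec, truth = render_ecg(beats, spec, fs=fs, seed=s_render,
                                    duration=duration, morphology=morphology,
                                    subject_id=sid, recording_id=rid)
            rec, truth = inject_transients(rec, truth, rec_noise, s_noise,
                                           morphology=morphology)
            recordings.append((rec, truth))
        subjects[sid] = tuple(rec_ids)

    return Corpus(recordings=tuple(recordings), subjects=subjects,
                  af_subjects=af_ids, seed=seed)


# ---------------------------------------------------------------------------
# Event labeling
# ---------------------------------------------------------------------------

def label_events(
    detection_times: np.ndarray,
    truth: BeatTruth,
    tolerance: float = 75.0,
) -> np.ndarray:
    """Label each detection as a true beat or a false detection.

    Each true beat is matched to at most one detection — the nearest within
    `tolerance` ms; matched detections are labeled ``true_beat`` and all
    others ``false_detection``.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    det = np.asarray(detection_times, dtype=float)
    if det.size and np.any(np.diff(det) < 0):
        raise ValueError("detection_times must be sorted")
    labels = np.full(det.size, FALSE_DETECTION, dtype=object)
    beats = truth.beat_times
    if det.size == 0 or beats.size == 0:
        return labels

    # candidate (distance, beat, detection) pairs within tolerance,
    # greedily matched nearest-first
    pairs: list[tuple[float, int, int]] = []
    for bi, b in enumerate(beats):
        lo = np.searchsorted(det, b - tolerance, side="left")
        hi = np.searchsorted(det, b + tolerance, side="right")
        for di in range(lo, hi):
            pairs.append((abs(det[di] - b), bi, di))
    pairs.sort()
    beat_used = np.zeros(beats.size, dtype=bool)
    det_used = np.zeros(det.size, dtype=bool)
    for dist, bi, di in pairs:
        if beat_used[bi] or det_used[di]:
            continue
        beat_used[bi] = True
        det_used[di] = True
        labels[di] = TRUE_BEAT
    return labels


def corpus_manifest(corpus: Corpus, splits: dict[str, str] | None = None):
    """Corpus summary table: one row per recording.

    Columns: subject_id, recording_id, rhythm_label, n_beats, n_noise_events,
    split (empty when no split assignment is given).
    """
    import pandas as pd

    rows = []
    for rec, truth in corpus.recordings:
        rows.append({
            "subject_id": rec.subject_id,
            "recording_id": rec.recording_id,
            "rhythm_label": truth.rhythm_label,
            "n_beats": int(truth.beat_times.size),
            "n_noise_events": int(truth.noise_times.size),
            "split": (splits or {}).get(rec.subject_id, ""),
        })
    return pd.DataFrame(rows)
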