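"""Screening-style performance evaluation and detector-parameter optimization.

Metrics (Se, Sp, Acc, FPR, PPV, F1) are computed from 2x2 confusion counts
at three levels: event level (positive class = false detection), recording
level (positive class = AF), and patient level (an AF patient counts as
detected when at least one of their recordings is labeled AF; only
sensitivity is meaningful there).

The detector's (N, alpha, eta) are tuned by exhaustive grid search over
N in {4..8}, alpha in {0.03..0.12} (step 0.01) and eta in {0.05..0.95}
(step 0.05) — 950 combinations — minimizing the recording-level false
positive rate subject to sensitivity >= 99% on the training subjects.
Because a single subject-level split biases the estimate, the whole
split / tune / test cycle is repeated over random subject splits and
summarized as mean +- standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detector import (
    AfDecision,
    DetectorParams,
    detect_af,
    rr_intervals,
    window_qualifies,
)

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "SplitPlan",
    "GridSearchResult",
    "RecordingSeries",
    "confusion",
    "metrics",
    "review_load",
    "recordings_per_af_found",
    "patient_sensitivity",
    "split_subjects",
    "decide_recordings",
    "recording_confusion",
    "grid_search",
    "default_grid",
    "repeated_eval",
    "DetectorTuner",
    "TuningResults",
]


# ---------------------------------------------------------------------------
# Confusion counts and metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    """Fractions in [0, 1]; a metric with a zero denominator is None."""

    Se: float | None
    Sp: float | None
    Acc: float | None
    FPR: float | None
    PPV: float | None
    F1: float | None

    def as_dict(self) -> dict[str, float | None]:
        return {"Se": self.Se, "Sp": self.Sp, "Acc": self.Acc,
                "FPR": self.FPR, "PPV": self.PPV, "F1": self.F1}


def confusion(predicted, truth, positive) -> ConfusionCounts:
    """Standard 2x2 tally with the declared positive class."""
    pred = np.asarray(predicted)
    true = np.asarray(truth)
    if pred.shape != true.shape:
        raise ValueError("predicted and true labels must have equal length")
    p_pos = pred == positive
    t_pos = true == positive
    return ConfusionCounts(
        tp=int(np.sum(p_pos & t_pos)),
        fp=int(np.sum(p_pos & ~t_pos)),
        tn=int(np.sum(~p_pos & ~t_pos)),
        fn=int(np.sum(~p_pos & t_pos)),
    )


def _ratio(num: int, denom: int) -> float | None:
    return num / denom if denom > 0 else None


def metrics(counts: ConfusionCounts) -> MetricSet:
    """Se, Sp, Acc, FPR, PPV and F1 from confusion counts.

    FPR = 1 - Sp = FP / (TN + FP); F1 = 2 Se PPV / (Se + PPV).  Metrics whose
    denominator is zero are reported as None (not available), never as 0.
    """
    se = _ratio(counts.tp, counts.tp + counts.fn)
    sp = _ratio(counts.tn, counts.tn + counts.fp)
    acc = _ratio(counts.tp + counts.tn, counts.total)
    fpr = None if sp is None else 1.0 - sp
    ppv = _ratio(counts.tp, counts.tp + counts.fp)
    if se is None or ppv is None or (se + ppv) == 0:
        f1 = None
    else:
        f1 = 2.0 * se * ppv / (se + ppv)
    return MetricSet(Se=se, Sp=sp, Acc=acc, FPR=fpr, PPV=ppv, F1=f1)


def review_load(counts: ConfusionCounts) -> int:
    """Number of detector-positive recordings an expert must review (TP + FP)."""
    return counts.tp + counts.fp


def recordings_per_af_found(ppv: float) -> int:
    """Expected recordings reviewed per AF recording found, round(1 / PPV)."""
    if ppv <= 0:
        raise ValueError("PPV must be positive")
    return int(round(1.0 / ppv))


def patient_sensitivity(recording_decisions: dict[str, bool],
                        recording_subject: dict[str, str],
                        af_subjects: set[str] | frozenset[str]) -> float | None:
    """Fraction of AF patients with at least one AF-labeled recording."""
    if not af_subjects:
        return None
    detected = {recording_subject[rid]
                for rid, is_af in recording_decisions.items() if is_af}
    for rid in recording_decisions:
        if rid not in recording_subject:
            raise ValueError(f"recording {rid} has no subject mapping")
    hits = sum(1 for sid in af_subjects if sid in detected)
    return hits / len(af_subjects)


# ---------------------------------------------------------------------------
# Subject-level splitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitPlan:
    assignment: dict[str, str]   # subject_id -> "train" | "test"
    seed: int

    def subjects(self, part: str) -> list[str]:
        return sorted(s for s, p in self.assignment.items() if p == part)


def split_subjects(subject_ids, af_subjects, fraction: float = 0.5,
                   seed: int = 0) -> SplitPlan:
    """Assign subjects to train/test; AF subjects are divided as evenly as possible.

    With an odd AF count, the extra AF subject alternates between train and
    test across seeds (seed parity), so no side is systematically favored.
    """
    subject_ids = sorted(subject_ids)
    af = sorted(set(af_subjects) & set(subject_ids))
    non_af = [s for s in subject_ids if s not in set(af)]
    if len(subject_ids) < 2:
        raise ValueError("need at least 2 subjects to split")
    rng = np.random.default_rng(seed)
    rng.shuffle(af)
    rng.shuffle(non_af)

    n_af_train = len(af) // 2
    if len(af) % 2 == 1 and seed % 2 == 0:
        n_af_train += 1
    n_non_train = int(round(fraction * len(non_af)))
    assignment = {}
    for i, s in enumerate(af):
        assignment[s] = "train" if i < n_af_train else "test"
    for i, s in enumerate(non_af):
        assignment[s] = "train" if i < n_non_train else "test"
    return SplitPlan(assignment=assignment, seed=seed)


# ---------------------------------------------------------------------------
# Recording-level evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecordingSeries:
    """Detector input for one recording: accepted times after (optional) QC."""

    recording_id: str
    subject_id: str
    truth_label: str                       # "AF" | "non-AF"
    times: np.ndarray                      # accepted detection times, ms
    excluded_times: np.ndarray = field(default_factory=lambda: np.empty(0))


def decide_recordings(series_list, params: DetectorParams) -> dict[str, AfDecision]:
    """Run the AF detector over every recording; returns id -> decision."""
    out: dict[str, AfDecision] = {}
    for s in series_list:
        if s.times.size < 2:
            out[s.recording_id] = AfDecision(label="non-AF", fraction=0.0,
                                             n_qualifying=0, quality_flag=True)
            continue
        rr = rr_intervals(s.times)
        mask = None
        if s.excluded_times.size:
            mask = window_qualifies(s.times, s.excluded_times, params.N)
        out[s.recording_id] = detect_af(rr, params, qualifies=mask)
    return out


def recording_confusion(decisions: dict[str, AfDecision],
                        truth_labels: dict[str, str]) -> ConfusionCounts:
    ids = sorted(decisions)
    pred = np.array(["AF" if decisions[r].is_af else "non-AF" for r in ids])
    true = np.array([truth_labels[r] for r in ids])
    return confusion(pred, true, positive="AF")


# ---------------------------------------------------------------------------
# Constrained grid search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSearchResult:
    params: DetectorParams
    se: float
    fpr: float
    feasible: bool
    table: pd.DataFrame | None = None

    def summary(self) -> str:
        p = self.params
        status = "feasible" if self.feasible else "INFEASIBLE (best-Se fallback)"
        return (
            "Detector parameter search\n"
            "=========================\n"
            f"status : {status}\n"
            f"N      : {p.N}\n"
            f"alpha  : {p.alpha:.2f}\n"
            f"eta    : {p.eta:.2f}\n"
            f"train Se  : {self.se * 100:.1f}%\n"
            f"train FPR : {self.fpr * 100:.1f}%"
        )


def default_grid() -> tuple[list[int], list[float], list[float]]:
    """N in {4..8}; alpha 0.03..0.12 step 0.01; eta 0.05..0.95 step 0.05."""
    ns = list(range(4, 9))
    alphas = [round(0.03 + 0.01 * i, 2) for i in range(10)]
    etas = [round(0.05 * i, 2) for i in range(1, 20)]
    return ns, alphas, etas


def _precompute(series_list, ns):
    """Per recording and N: sorted pair |differences| per window, window medians,
    qualifying masks — everything grid evaluation needs."""
    pre = []
    for s in series_list:
        entry = {"is_af": s.truth_label == "AF", "per_n": {}}
        m = s.times.size - 1
        if m >= 1:
            intervals = np.diff(s.times)
        for n in ns:
            n_windows = m - n + 1 if m >= 1 else 0
            if n_windows <= 0:
                entry["per_n"][n] = None
                continue
            win = np.lib.stride_tricks.sliding_window_view(intervals, n)
            iu = np.triu_indices(n, k=1)
            pair_abs = np.abs(win[:, :, None] - win[:, None, :])[:, iu[0], iu[1]]
            med = np.median(win, axis=1)
            if s.excluded_times.size:
                mask = window_qualifies(s.times, s.excluded_times, n)
            else:
                mask = np.ones(n_windows, dtype=bool)
            entry["per_n"][n] = (pair_abs, med, mask)
        pre.append(entry)
    return pre


def grid_search(
    series_list,
    se_min: float = 0.99,
    grid: tuple[list[int], list[float], list[float]] | None = None,
    eta_d: float = 1.0 / 3.0,
    keep_table: bool = False,
) -> GridSearchResult:
    """Exhaustive constrained search for the detector operating point.

    Every (N, alpha, eta) combination is evaluated exactly once on the
    training recordings.  Among combinations meeting the recording-level
    sensitivity constraint the one with the lowest FPR wins; ties break
    toward smaller N, then alpha, then eta.  If no combination is feasible,
    the one with the highest Se (then lowest FPR) is returned with
    ``feasible=False``.
    """
    series_list = list(series_list)
    if not series_list:
        raise ValueError("training set must not be empty")
    ns, alphas, etas = grid if grid is not None else default_grid()
    pre = _precompute(series_list, ns)

    rows = []
    for n in ns:
        norm = (n - 1) * (n - 2)
        for alpha in alphas:
            # Lambda for every window of every recording at this (N, alpha)
            lam_cache = []
            for entry in pre:
                data = entry["per_n"][n]
                if data is None:
                    lam_cache.append(None)
                    continue
                pair_abs, med, mask = data
                gamma = alpha * med
                lam = (pair_abs > gamma[:, None]).sum(axis=1) / norm
                lam_cache.append((lam, mask))
            for eta in etas:
                tp = fp = tn = fn = 0
                for entry, cached in zip(pre, lam_cache):
                    if cached is None:
                        is_af_pred = False
                    else:
                        lam, mask = cached
                        if mask.any():
                            frac = (lam[mask] >= eta).mean()
                            is_af_pred = frac >= eta_d
                        else:
                            is_af_pred = False
                    if entry["is_af"]:
                        tp += is_af_pred
                        fn += not is_af_pred
                    else:
                        fp += is_af_pred
                        tn += not is_af_pred
                se = tp / (tp + fn) if (tp + fn) else 0.0
                fpr = fp / (fp + tn) if (fp + tn) else 0.0
                rows.append((n, alpha, eta, se, fpr))

    table = pd.DataFrame(rows, columns=["N", "alpha", "eta", "Se", "FPR"])
    feasible = table[table.Se >= se_min]
    if len(feasible):
        # lowest FPR; ties toward smaller N, alpha, eta (row order is sorted)
        best = feasible.loc[feasible.FPR.idxmin()]
        ok = True
    else:
        best = table.sort_values(["Se", "FPR"], ascending=[False, True],
                                 kind="stable").iloc[0]
        ok = False
    params = DetectorParams(N=int(best.N), alpha=float(best.alpha),
                            eta=float(best.eta), eta_d=eta_d)
    return GridSearchResult(params=params, se=float(best.Se),
                            fpr=float(best.FPR), feasible=ok,
                            table=table if keep_table else None)


# ---------------------------------------------------------------------------
# Repeated subject-level evaluation
# ---------------------------------------------------------------------------

def repeated_eval(
    series_list,
    af_subjects,
    n_repeats: int = 10,
    base_seed: int = 0,
    se_min: float = 0.99,
    grid=None,
    params: DetectorParams | None = None,
) -> pd.DataFrame:
    """Split subjects, tune (or reuse) detector parameters, evaluate on test.

    Returns one row per repeat (seed, N, alpha, eta, Se, FPR, PPV) followed by
    ``mean`` and ``sd`` summary rows.  When ``params`` is given the tuning
    step is skipped and the fixed operating point is evaluated on every test
    split.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    series_list = list(series_list)
    subject_ids = sorted({s.subject_id for s in series_list})
    rows = []
    for r in range(n_repeats):
        seed = base_seed + r
        plan = split_subjects(subject_ids, af_subjects, seed=seed)
        train = [s for s in series_list if plan.assignment[s.subject_id] == "train"]
        test = [s for s in series_list if plan.assignment[s.subject_id] == "test"]
        if params is None:
            res = grid_search(train, se_min=se_min, grid=grid)
            p = res.params
        else:
            p = params
        decisions = decide_recordings(test, p)
        truth = {s.recording_id: s.truth_label for s in test}
        m = metrics(recording_confusion(decisions, truth))
        rows.append({"seed": seed, "N": p.N, "alpha": p.alpha, "eta": p.eta,
                     "Se": m.Se, "FPR": m.FPR, "PPV": m.PPV})
    df = pd.DataFrame(rows)
    summary = df[["Se", "FPR", "PPV"]].astype(float)
    mean = {"seed": "mean", **summary.mean().to_dict()}
    sd = {"seed": "sd", **summary.std(ddof=1).to_dict()} if n_repeats > 1 else None
    out = pd.concat([df, pd.DataFrame([mean] + ([sd] if sd else []))],
                    ignore_index=True)
    return out


# ---------------------------------------------------------------------------
# Model / Results surface for the tuning step
# ---------------------------------------------------------------------------

@dataclass
class TuningResults:
    result: GridSearchResult
    test_metrics: MetricSet | None

    def summary(self) -> str:
        text = self.result.summary()
        if self.test_metrics is not None:
            m = self.test_metrics
            text += ("\n-- held-out test --\n"
                     f"Se  : {m.Se * 100:.1f}%\n"
                     f"FPR : {m.FPR * 100:.1f}%\n"
                     f"PPV : {(m.PPV * 100):.1f}%" if m.PPV is not None else "")
        return text


class DetectorTuner:
    """Constrained grid-search tuner with a Model/Results interface."""

    def __init__(self, train_series, test_series=None, se_min: float = 0.99,
                 grid=None):
        self.train_series = list(train_series)
        self.test_series = list(test_series) if test_series is not None else None
        self.se_min = se_min
        self.grid = grid

    def fit(self) -> TuningResults:
        res = grid_search(self.train_series, se_min=self.se_min, grid=self.grid)
        tm = None
        if self.test_series:
            decisions = decide_recordings(self.test_series, res.params)
            truth = {s.recording_id: s.truth_label for s in self.test_series}
            tm = metrics(recording_confusion(decisions, truth))
        return TuningResults(result=res, test_metrics=tm)
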