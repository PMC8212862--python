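"""Low-complexity RR-irregularity AF detector with quality-control pruning.

AF is characterized by irregular RR intervals.  For a sliding window of N
consecutive intervals r(0..N-1) the irregularity fraction is

    Lambda_i = (1 / ((N-1)(N-2))) * #{ j < k : |r(j) - r(k)| > gamma_i },

where gamma_i = alpha * median of the window.  Note the normalizer is
(N-1)(N-2) rather than the pair count N(N-1)/2, so Lambda's maximum is
N / (2(N-2)) — equal to 1 only at N = 4; the window threshold eta was tuned
jointly with this normalizer, so it is kept.  A window is flagged irregular
(O_i = 1) when Lambda_i >= eta; the recording is called AF when the fraction
of flagged windows among the I qualifying windows reaches eta_d.  The default
eta_d = 1/3 encodes the rule that 10 s of AF within a 30-s recording already
labels the whole recording AF.

The complementary "printed" convention (counting pairs *below* gamma) is kept
behind ``convention="printed"`` for auditability; the two satisfy
Lambda_exceed + Lambda_printed = N / (2(N-2)) whenever no pair difference
ties with gamma.

With quality control, detections the CNN labels as false are removed before
interval formation.  An isolated false detection lying between two normally
spaced true detections — their spanning interval deviating < 15% from the
recording's median true-to-true RR interval — is silently merged away; every
other removal disqualifies the sliding windows whose time span contains it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus import FALSE_DETECTION

__all__ = [
    "RrSeries",
    "DetectorParams",
    "WindowStat",
    "AfDecision",
    "PruneResult",
    "PRESET_WITHOUT_QC",
    "PRESET_WITH_QC",
    "rr_intervals",
    "gamma_threshold",
    "irregularity_fraction",
    "window_flag",
    "qc_prune",
    "window_qualifies",
    "detect_af",
]


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RrSeries:
    """Accepted detection times (ms) and their successive differences."""

    times: np.ndarray
    intervals: np.ndarray
    median_rr: float


@dataclass(frozen=True)
class DetectorParams:
    """(N, alpha, eta, eta_d) of the RR-irregularity detector."""

    N: int = 8
    alpha: float = 0.07
    eta: float = 0.55
    eta_d: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not 0 < self.eta < 1:
            raise ValueError("eta must be in (0, 1)")
        if not 0 < self.eta_d <= 1:
            raise ValueError("eta_d must be in (0, 1]")


#: Operating points tuned without and with CNN quality control.
PRESET_WITHOUT_QC = DetectorParams(N=8, alpha=0.07, eta=0.55)
PRESET_WITH_QC = DetectorParams(N=4, alpha=0.04, eta=0.65)


@dataclass(frozen=True)
class WindowStat:
    index: int
    gamma: float
    lam: float
    flag: int
    qualifies: bool


@dataclass(frozen=True)
class AfDecision:
    """Recording-level decision: AF iff fraction >= eta_d and I > 0."""

    label: str                      # "AF" | "non-AF"
    fraction: float
    n_qualifying: int
    quality_flag: bool
    windows: tuple[WindowStat, ...] = ()

    @property
    def is_af(self) -> bool:
        return self.label == "AF"


@dataclass(frozen=True)
class PruneResult:
    """Outcome of quality-control pruning of a detection series."""

    accepted_times: np.ndarray    # true-labeled detection times, ms
    excluded_times: np.ndarray    # removed false detections that disqualify windows
    merged_times: np.ndarray      # false detections silently merged away
    quality_flag: bool            # no true detections at all


# ---------------------------------------------------------------------------
# Primitives
# ---------------------------------------------------------------------------

def rr_intervals(times: np.ndarray) -> RrSeries:
    """Successive differences of sorted detection times."""
    times = np.asarray(times, dtype=float)
    if times.size < 2:
        raise ValueError("need at least 2 detection times")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    intervals = np.diff(times)
    return RrSeries(times=times, intervals=intervals,
                    median_rr=float(np.median(intervals)))


def gamma_threshold(window: np.ndarray, alpha: float) -> float:
    """gamma = alpha * median of the window's intervals."""
    return float(alpha * np.median(np.asarray(window, dtype=float)))


def irregularity_fraction(window: np.ndarray, gamma: float,
                          convention: str = "exceed") -> float:
    """Fraction of interval pairs discordant relative to gamma.

    ``"exceed"`` counts pairs with |r(j) - r(k)| > gamma (irregularity; the
    operational form), ``"printed"`` counts pairs with |r(j) - r(k)| < gamma
    together with ties (the complementary concordance form).  Both use the
    (N-1)(N-2) normalizer; ties |difference| == gamma count as concordant.
    """
    w = np.asarray(window, dtype=float)
    n = w.size
    if n < 3:
        raise ValueError("window must contain at least 3 intervals")
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    diffs = np.abs(w[:, None] - w[None, :])
    iu = np.triu_indices(n, k=1)
    pair_diffs = diffs[iu]
    if convention == "exceed":
        count = int(np.sum(pair_diffs > gamma))
    elif convention == "printed":
        count = int(np.sum(pair_diffs <= gamma))
    else:
        raise ValueError("convention must be 'exceed' or 'printed'")
    return count / ((n - 1) * (n - 2))


def window_flag(lam: float, eta: float) -> int:
    """O = 1 iff Lambda >= eta (equality counts as irregular)."""
    return 1 if lam >= eta else 0


# ---------------------------------------------------------------------------
# Quality-control pruning
# ---------------------------------------------------------------------------

def _is_false(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "iub":
        return arr.astype(bool)
    return arr == FALSE_DETECTION


def qc_prune(detection_times: np.ndarray, labels,
             deviation_limit: float = 0.15) -> PruneResult:
    """Remove CNN-flagged false detections ahead of AF detection.

    The recording's median RR interval is taken over intervals between
    *consecutive true-labeled* detections.  A maximal run of exactly one
    false detection whose flanking true detections span an interval deviating
    less than ``deviation_limit`` (15%) from that median is merged away: the
    two sub-intervals fuse into one normal RR interval and nothing is
    disqualified.  Every other false detection is deleted and recorded in
    ``excluded_times`` so the sliding windows containing it can be skipped.
    """
    times = np.asarray(detection_times, dtype=float)
    is_false = _is_false(labels)
    if times.shape != is_false.shape:
        raise ValueError("labels must align with detection times")

    true_times = times[~is_false]
    if true_times.size == 0:
        return PruneResult(accepted_times=np.empty(0),
                           excluded_times=times.copy(),
                           merged_times=np.empty(0),
                           quality_flag=True)
    median_rr = (float(np.median(np.diff(true_times)))
                 if true_times.size >= 2 else None)

    merged: list[float] = []
    excluded: list[float] = []
    i = 0
    n = times.size
    while i < n:
        if not is_false[i]:
            i += 1
            continue
        j = i
        while j < n and is_false[j]:
            j += 1
        run = times[i:j]
        flanked = i > 0 and j < n and not is_false[i - 1] and not is_false[j]
        if run.size == 1 and flanked and median_rr:
            span = times[j] - times[i - 1]
            if abs(span - median_rr) < deviation_limit * median_rr:
                merged.append(float(run[0]))
                i = j
                continue
        excluded.extend(float(t) for t in run)
        i = j

    return PruneResult(accepted_times=true_times,
                       excluded_times=np.asarray(excluded),
                       merged_times=np.asarray(merged),
                       quality_flag=False)


def window_qualifies(times: np.ndarray, excluded_times: np.ndarray,
                     n_intervals: int) -> np.ndarray:
    """Qualifying mask over the sliding windows of an accepted time series.

    Window i spans (times[i], times[i + N]); it is disqualified when an
    excluded event time lies strictly inside that span.
    """
    times = np.asarray(times, dtype=float)
    excluded = np.asarray(excluded_times, dtype=float)
    n_windows = times.size - n_intervals
    if n_windows <= 0:
        return np.zeros(0, dtype=bool)
    mask = np.ones(n_windows, dtype=bool)
    for e in excluded:
        lo = np.searchsorted(times, e, side="right") - 1  # times[lo] < e <= times[lo+1]
        if lo < 0 or lo >= times.size - 1 or times[lo] == e:
            continue
        first = max(lo - n_intervals + 1, 0)
        mask[first:min(lo + 1, n_windows)] = False
    return mask


# ---------------------------------------------------------------------------
# Recording decision
# ---------------------------------------------------------------------------

def detect_af(series: RrSeries, params: DetectorParams,
              qualifies: np.ndarray | None = None,
              keep_windows: bool = False) -> AfDecision:
    """Slide the N-interval window over a series and decide AF for the recording.

    Windows are every contiguous run of N intervals (stride 1); I counts the
    qualifying ones.  The recording is AF when the mean window flag over
    qualifying windows reaches eta_d.  Series shorter than one window, or
    with no qualifying window, yield non-AF with the quality flag set.
    """
    m = series.intervals.size
    n_windows = m - params.N + 1
    if n_windows <= 0:
        return AfDecision(label="non-AF", fraction=0.0, n_qualifying=0,
                          quality_flag=True)
    if qualifies is None:
        qualifies = np.ones(n_windows, dtype=bool)
    qualifies = np.asarray(qualifies, dtype=bool)
    if qualifies.size != n_windows:
        raise ValueError("qualifies mask length must equal the window count")

    stats: list[WindowStat] = []
    flags = np.zeros(n_windows, dtype=int)
    for i in range(n_windows):
        w = series.intervals[i:i + params.N]
        gamma = gamma_threshold(w, params.alpha)
        lam = irregularity_fraction(w, gamma)
        flags[i] = window_flag(lam, params.eta)
        if keep_windows:
            stats.append(WindowStat(index=i, gamma=gamma, lam=lam,
                                    flag=flags[i], qualifies=bool(qualifies[i])))

    n_qual = int(qualifies.sum())
    if n_qual == 0:
        return AfDecision(label="non-AF", fraction=0.0, n_qualifying=0,
                          quality_flag=True, windows=tuple(stats))
    fraction = float(flags[qualifies].mean())
    label = "AF" if fraction >= params.eta_d else "non-AF"
    return AfDecision(label=label, fraction=fraction, n_qualifying=n_qual,
                      quality_flag=False, windows=tuple(stats))
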