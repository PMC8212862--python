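"""Metrics, subject splits, constrained grid search, repeated evaluation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from afqc.detector import DetectorParams, detect_af, rr_intervals
from afqc.evaluation import (
    ConfusionCounts,
    RecordingSeries,
    confusion,
    decide_recordings,
    default_grid,
    grid_search,
    metrics,
    patient_sensitivity,
    recording_confusion,
    recordings_per_af_found,
    repeated_eval,
    review_load,
    split_subjects,
)


class TestConfusionAndMetrics:
    def test_perfect_predictions(self):
        c = confusion(np.array([1, 0, 1]), np.array([1, 0, 1]), positive=1)
        assert (c.fp, c.fn) == (0, 0) and c.tp + c.tn == 3
        m = metrics(ConfusionCounts(tp=1, fp=0, tn=1, fn=0))
        assert m.Se == m.Sp == m.Acc == m.PPV == m.F1 == 1.0 and m.FPR == 0.0

    def test_all_positive_on_all_negative(self):
        c = confusion(np.ones(5), np.zeros(5), positive=1)
        assert c.fp == 5 and c.tp == c.tn == c.fn == 0

    def test_screening_confusion_with_quality_control(self):
        m = metrics(ConfusionCounts(tp=106, fp=1807, tn=916, fn=1))
        assert m.Se == pytest.approx(106 / 107)
        assert m.FPR == pytest.approx(1807 / 2723)
        assert m.PPV == pytest.approx(106 / 1913)

    def test_screening_confusion_without_quality_control(self):
        m = metrics(ConfusionCounts(tp=106, fp=2405, tn=318, fn=1))
        assert m.PPV == pytest.approx(106 / 2511)

    def test_review_load_arithmetic(self):
        without = ConfusionCounts(tp=106, fp=2405, tn=318, fn=1)
        with_qc = ConfusionCounts(tp=106, fp=1807, tn=916, fn=1)
        assert review_load(without) == 2511
        assert review_load(with_qc) == 1913
        assert review_load(without) - review_load(with_qc) == 598

    def test_recordings_reviewed_per_af_found(self):
        assert recordings_per_af_found(0.046) == 22
        assert recordings_per_af_found(0.062) == 16

    @given(tp=st.integers(0, 1000), fp=st.integers(0, 1000),
           tn=st.integers(0, 1000), fn=st.integers(0, 1000))
    def test_fpr_complements_specificity(self, tp, fp, tn, fn):
        m = metrics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
        if m.Sp is not None:
            assert m.FPR + m.Sp == pytest.approx(1.0)
        if m.Se is not None and m.PPV is not None and m.Se + m.PPV > 0:
            assert m.F1 == pytest.approx(
                2 * m.Se * m.PPV / (m.Se + m.PPV))

    def test_undefined_metrics_are_none_not_zero(self):
        m = metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=0))
        assert m.Se is None and m.PPV is None
        assert m.Sp == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion(np.ones(3), np.ones(4), positive=1)


class TestPatientSensitivity:
    def test_every_af_patient_detected(self):
        decisions = {"r1": True, "r2": False, "r3": True}
        subj = {"r1": "a", "r2": "a", "r3": "b"}
        assert patient_sensitivity(decisions, subj, {"a", "b"}) == 1.0

    def test_one_missed_patient(self):
        decisions = {"r1": True, "r2": False}
        subj = {"r1": "a", "r2": "b"}
        assert patient_sensitivity(decisions, subj, {"a", "b"}) == 0.5

    def test_false_positives_do_not_affect_sensitivity(self):
        decisions = {"r1": True, "r2": True}
        subj = {"r1": "a", "r2": "c"}   # c is non-AF
        assert patient_sensitivity(decisions, subj, {"a"}) == 1.0

    def test_no_af_patients_is_not_available(self):
        assert patient_sensitivity({"r": True}, {"r": "a"}, set()) is None


class TestSplitSubjects:
    def test_af_subjects_divided_evenly(self):
        subjects = [f"s{i}" for i in range(200)]
        af = subjects[:77]
        plan = split_subjects(subjects, af, seed=0)
        n_train = sum(1 for s in af if plan.assignment[s] == "train")
        assert n_train in (38, 39)

    def test_odd_extra_alternates_with_seed_parity(self):
        subjects = [f"s{i}" for i in range(10)]
        af = subjects[:3]
        n_even = sum(1 for s in af
                     if split_subjects(subjects, af, seed=2).assignment[s]
                     == "train")
        n_odd = sum(1 for s in af
                    if split_subjects(subjects, af, seed=3).assignment[s]
                    == "train")
        assert {n_even, n_odd} == {1, 2}

    def test_even_half_split(self):
        subjects = [f"s{i}" for i in range(100)]
        plan = split_subjects(subjects, [], fraction=0.5, seed=1)
        assert sum(1 for v in plan.assignment.values() if v == "train") == 50

    def test_deterministic(self):
        subjects = [f"s{i}" for i in range(30)]
        a = split_subjects(subjects, subjects[:5], seed=9)
        b = split_subjects(subjects, subjects[:5], seed=9)
        assert a.assignment == b.assignment


def _planted_series(n_af=12, n_regular=36, n_noisy=12, seed=0):
    """RR series with separable statistics: irregular AF, regular sinus,
    and noisy-but-regular recordings that create false positives."""
    rng = np.random.default_rng(seed)
    series = []
    for i in range(n_af):
        iv = rng.uniform(400, 1200, 36)
        series.append(RecordingSeries(
            recording_id=f"af{i}", subject_id=f"A{i}", truth_label="AF",
            times=np.concatenate([[0.0], np.cumsum(iv)])))
    for i in range(n_regular):
        iv = rng.normal(820, 18, 36)
        series.append(RecordingSeries(
            recording_id=f"nr{i}", subject_id=f"N{i}", truth_label="non-AF",
            times=np.concatenate([[0.0], np.cumsum(iv)])))
    for i in range(n_noisy):
        iv = rng.normal(820, 18, 36)
        # transient noise splits a few intervals into short fragments
        for k in rng.choice(34, size=6, replace=False):
            iv[k] *= rng.uniform(0.25, 0.5)
        series.append(RecordingSeries(
            recording_id=f"nz{i}", subject_id=f"Z{i}", truth_label="non-AF",
            times=np.concatenate([[0.0], np.cumsum(iv)])))
    return series


def brute_force_table(series_list, ns, alphas, etas, eta_d=1 / 3):
    """Independent oracle: run the reference decision routine per combo."""
    rows = []
    rr = [(rr_intervals(s.times), s.truth_label == "AF") for s in series_list]
    for n in ns:
        for alpha in alphas:
            for eta in etas:
                params = DetectorParams(N=n, alpha=alpha, eta=eta, eta_d=eta_d)
                tp = fp = tn = fn = 0
                for series, is_af in rr:
                    pred = detect_af(series, params).is_af
                    tp += pred and is_af
                    fp += pred and not is_af
                    tn += (not pred) and (not is_af)
                    fn += (not pred) and is_af
                se = tp / (tp + fn) if tp + fn else 0.0
                fpr = fp / (fp + tn) if fp + tn else 0.0
                rows.append((n, alpha, eta, se, fpr))
    return pd.DataFrame(rows, columns=["N", "alpha", "eta", "Se", "FPR"])


class TestGridSearch:
    SMALL_GRID = ([4, 6, 8],
                  [0.04, 0.07, 0.10],
                  [0.15, 0.35, 0.55, 0.75])

    def test_grid_cardinality(self):
        ns, alphas, etas = default_grid()
        assert len(ns) * len(alphas) * len(etas) == 950

    def test_matches_brute_force_oracle_on_small_grid(self):
        series = _planted_series(n_af=6, n_regular=12, n_noisy=6)
        res = grid_search(series, se_min=0.99, grid=self.SMALL_GRID)
        oracle = brute_force_table(series, *self.SMALL_GRID)
        feas = oracle[oracle.Se >= 0.99]
        assert len(feas) > 0 and res.feasible
        best = feas.loc[feas.FPR.idxmin()]
        assert (res.params.N, res.params.alpha, res.params.eta) == (
            int(best.N), float(best.alpha), float(best.eta))
        assert res.fpr == pytest.approx(float(best.FPR))

    def test_unconstrained_returns_global_minimum_fpr(self):
        series = _planted_series(n_af=4, n_regular=8, n_noisy=4)
        res = grid_search(series, se_min=0.0, grid=self.SMALL_GRID)
        oracle = brute_force_table(series, *self.SMALL_GRID)
        assert res.fpr == pytest.approx(float(oracle.FPR.min()))

    def test_infeasible_constraint_reports_fallback(self):
        # only regular recordings in truth-label AF: nothing reaches Se=1
        series = [RecordingSeries(
            recording_id=f"r{i}", subject_id=f"s{i}", truth_label="AF",
            times=np.arange(0, 24_000, 800.0)) for i in range(4)]
        series += _planted_series(n_af=0, n_regular=6, n_noisy=0)
        res = grid_search(series, se_min=0.99, grid=self.SMALL_GRID)
        assert not res.feasible

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            grid_search([])


class TestRepeatedEval:
    def test_report_shape_and_summary_rows(self):
        series = _planted_series(n_af=8, n_regular=16, n_noisy=8)
        af_subjects = {s.subject_id for s in series if s.truth_label == "AF"}
        df = repeated_eval(series, af_subjects, n_repeats=3, base_seed=0,
                           grid=TestGridSearch.SMALL_GRID)
        assert len(df) == 5  # 3 repeats + mean + sd
        assert list(df.seed[-2:]) == ["mean", "sd"]

    def test_fixed_params_skip_tuning_and_are_deterministic(self):
        series = _planted_series(n_af=6, n_regular=10, n_noisy=6)
        af_subjects = {s.subject_id for s in series if s.truth_label == "AF"}
        p = DetectorParams(N=4, alpha=0.05, eta=0.45)
        a = repeated_eval(series, af_subjects, n_repeats=2, base_seed=5,
                          params=p)
        b = repeated_eval(series, af_subjects, n_repeats=2, base_seed=5,
                          params=p)
        pd.testing.assert_frame_equal(a, b)
        assert set(a.N[:2]) == {4}


class TestDecideRecordings:
    def test_short_series_get_quality_flag(self):
        s = RecordingSeries(recording_id="r", subject_id="s",
                            truth_label="non-AF", times=np.array([100.0]))
        decisions = decide_recordings([s], DetectorParams(N=4))
        assert decisions["r"].quality_flag and not decisions["r"].is_af

    def test_recording_confusion_counts(self):
        series = _planted_series(n_af=4, n_regular=6, n_noisy=0, seed=3)
        decisions = decide_recordings(series, DetectorParams(N=4, alpha=0.04,
                                                             eta=0.65))
        truth = {s.recording_id: s.truth_label for s in series}
        c = recording_confusion(decisions, truth)
        assert c.total == len(series)
        assert c.tp + c.fn == 4
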