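"""RR-irregularity detector: Lambda statistic, QC pruning, recording decision."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from afqc.detector import (
    DetectorParams,
    PRESET_WITH_QC,
    detect_af,
    gamma_threshold,
    irregularity_fraction,
    qc_prune,
    rr_intervals,
    window_flag,
    window_qualifies,
)


def brute_force_lambda(window, gamma):
    """Independent O(N^2) oracle: explicit double loop over pairs."""
    n = len(window)
    count = 0
    for j in range(n - 1):
        for k in range(j + 1, n):
            if abs(window[j] - window[k]) > gamma:
                count += 1
    return count / ((n - 1) * (n - 2))


class TestRrIntervals:
    def test_uniform_series(self):
        s = rr_intervals([0, 800, 1600])
        np.testing.assert_array_equal(s.intervals, [800, 800])
        assert s.median_rr == 800

    def test_even_count_median(self):
        s = rr_intervals([0, 600, 1500])
        np.testing.assert_array_equal(s.intervals, [600, 900])
        assert s.median_rr == 750

    @pytest.mark.parametrize("times", [[0.0], [0.0, 100.0, 100.0]])
    def test_degenerate_series_rejected(self, times):
        with pytest.raises(ValueError):
            rr_intervals(times)


class TestGammaAndLambda:
    def test_gamma_examples(self):
        assert gamma_threshold([700, 720, 740, 760], 0.07) == pytest.approx(51.1)
        assert gamma_threshold([700, 720, 740, 760], 0.0) == 0.0
        assert gamma_threshold([800] * 6, 0.1) == pytest.approx(80.0)

    def test_constant_window_is_regular(self):
        assert irregularity_fraction([800, 800, 800, 800], 10.0) == 0.0

    def test_alternating_window(self):
        lam = irregularity_fraction([600, 900, 600, 900], 30.0)
        assert lam == pytest.approx(4 / 6)

    def test_eight_interval_worked_example(self):
        w = [700, 710, 1000, 690, 705, 1010, 695, 700]
        gamma = gamma_threshold(w, 0.07)
        assert gamma == pytest.approx(49.175)
        assert irregularity_fraction(w, gamma) == pytest.approx(12 / 42)

    def test_tie_counts_as_concordant(self):
        # |900 - 800| == gamma exactly -> concordant under both conventions
        assert irregularity_fraction([800, 900, 800], 100.0) == 0.0

    def test_small_window_rejected(self):
        with pytest.raises(ValueError):
            irregularity_fraction([1.0, 2.0], 0.5)

    @settings(deadline=None, max_examples=60)
    @given(
        n=st.integers(3, 12),
        seed=st.integers(0, 10_000),
        alpha=st.floats(0.01, 0.2),
    )
    def test_matches_brute_force_oracle(self, n, seed, alpha):
        rng = np.random.default_rng(seed)
        w = rng.uniform(300, 1500, n)
        gamma = gamma_threshold(w, alpha)
        assert irregularity_fraction(w, gamma) == pytest.approx(
            brute_force_lambda(w, gamma))

    @settings(deadline=None, max_examples=40)
    @given(n=st.integers(3, 10), seed=st.integers(0, 10_000))
    def test_conventions_are_complementary(self, n, seed):
        rng = np.random.default_rng(seed)
        w = rng.uniform(300, 1500, n)
        gamma = gamma_threshold(w, 0.07)
        total = (irregularity_fraction(w, gamma, "exceed")
                 + irregularity_fraction(w, gamma, "printed"))
        assert total == pytest.approx(n / (2 * (n - 2)))

    @settings(deadline=None, max_examples=30)
    @given(seed=st.integers(0, 10_000), scale=st.floats(0.1, 10))
    def test_scale_invariance(self, seed, scale):
        rng = np.random.default_rng(seed)
        w = rng.uniform(300, 1500, 8)
        gamma = gamma_threshold(w, 0.07)
        assert irregularity_fraction(w * scale, gamma * scale) == (
            irregularity_fraction(w, gamma))

    def test_window_flag_boundary(self):
        assert window_flag(0.667, 0.65) == 1
        assert window_flag(0.65, 0.65) == 1    # equality is irregular
        assert window_flag(0.0, 0.1) == 0


class TestQcPrune:
    def test_normally_spaced_false_detection_is_merged(self):
        times = np.array([0, 800, 1600, 2000, 2400, 3200], dtype=float)
        labels = np.array([0, 0, 0, 1, 0, 0])
        res = qc_prune(times, labels)
        np.testing.assert_array_equal(res.merged_times, [2000.0])
        assert res.excluded_times.size == 0
        np.testing.assert_array_equal(
            np.diff(res.accepted_times), [800, 800, 800, 800])
        mask = window_qualifies(res.accepted_times, res.excluded_times, 4)
        assert mask.all()

    def test_abnormally_spaced_false_detection_disqualifies_windows(self):
        times = np.array([0, 800, 1600, 2100, 3000], dtype=float)
        labels = np.array([0, 0, 0, 1, 0])
        res = qc_prune(times, labels)
        assert res.merged_times.size == 0
        np.testing.assert_array_equal(res.excluded_times, [2100.0])
        np.testing.assert_array_equal(res.accepted_times, [0, 800, 1600, 3000])
        mask = window_qualifies(res.accepted_times, res.excluded_times, 2)
        # the deleted event at 2100 sits in the (1600, 3000) interval:
        # every 2-interval window spanning it is disqualified
        np.testing.assert_array_equal(mask, [True, False])

    def test_no_false_detections_is_a_noop(self):
        times = np.array([0, 800, 1600], dtype=float)
        res = qc_prune(times, np.zeros(3, dtype=int))
        np.testing.assert_array_equal(res.accepted_times, times)
        assert res.excluded_times.size == 0 and not res.quality_flag

    def test_all_false_sets_quality_flag(self):
        res = qc_prune(np.array([100.0, 400.0]), np.array([1, 1]))
        assert res.quality_flag
        assert res.accepted_times.size == 0

    def test_double_run_never_merges(self):
        # two consecutive false detections inside one normal interval
        times = np.array([0, 800, 1000, 1200, 1600], dtype=float)
        labels = np.array([0, 0, 1, 1, 0])
        res = qc_prune(times, labels)
        assert res.merged_times.size == 0
        assert set(res.excluded_times) == {1000.0, 1200.0}

    def test_string_labels_accepted(self):
        times = np.array([0, 800, 1600, 2000, 2400, 3200], dtype=float)
        labels = np.array(["true_beat"] * 3 + ["false_detection"]
                          + ["true_beat"] * 2, dtype=object)
        res = qc_prune(times, labels)
        np.testing.assert_array_equal(res.merged_times, [2000.0])


class TestDetectAf:
    def _series_with_flags(self, flags, params):
        """Build an interval series whose window flags equal `flags` under
        the given params, verified against a brute-force recomputation."""
        regular = 800.0
        irregular = [500.0, 1100.0]
        n = params.N
        intervals = []
        # windows overlap, so construct greedily and verify afterwards
        intervals = [regular] * (len(flags) + n - 1)
        for i, f in enumerate(flags):
            if f:
                intervals[i:i + n] = (irregular * n)[:n]
        times = np.concatenate([[0.0], np.cumsum(intervals)])
        series = rr_intervals(times)
        got = []
        for i in range(len(series.intervals) - n + 1):
            w = series.intervals[i:i + n]
            lam = brute_force_lambda(w, gamma_threshold(w, params.alpha))
            got.append(window_flag(lam, params.eta))
        return series, got

    def test_boundary_fraction_is_af(self):
        params = DetectorParams(N=4, alpha=0.07, eta=0.5, eta_d=1 / 3)
        series, flags = self._series_with_flags([1, 0, 0], params)
        decision = detect_af(series, params)
        assert decision.fraction == pytest.approx(np.mean(flags))
        if decision.fraction >= 1 / 3:
            assert decision.is_af

    def test_regular_series_is_non_af(self):
        series = rr_intervals(np.arange(0, 24_000, 800.0))
        decision = detect_af(series, DetectorParams(N=8, alpha=0.07, eta=0.55))
        assert not decision.is_af and decision.fraction == 0.0

    def test_af_like_series_is_af(self):
        rng = np.random.default_rng(2)
        iv = rng.uniform(400, 1100, 40)
        series = rr_intervals(np.concatenate([[0.0], np.cumsum(iv)]))
        assert detect_af(series, PRESET_WITH_QC).is_af

    def test_too_short_series_flags_quality(self):
        series = rr_intervals([0.0, 800.0, 1600.0])
        decision = detect_af(series, DetectorParams(N=8))
        assert not decision.is_af and decision.quality_flag

    def test_all_windows_disqualified_flags_quality(self):
        series = rr_intervals(np.arange(0, 8000, 800.0))
        params = DetectorParams(N=4)
        mask = np.zeros(series.intervals.size - 4 + 1, dtype=bool)
        decision = detect_af(series, params, qualifies=mask)
        assert not decision.is_af and decision.quality_flag

    def test_false_detection_never_decreases_lambda(self):
        """Splitting one interval of a regular window raises its Lambda."""
        times = np.arange(0, 9000, 800.0)
        with_noise = np.sort(np.append(times, 4000.0 + 333.0))
        base = rr_intervals(times)
        noisy = rr_intervals(with_noise)
        params = DetectorParams(N=8, alpha=0.07, eta=0.55)
        for i in range(noisy.intervals.size - 8 + 1):
            w_noisy = noisy.intervals[i:i + 8]
            lam_noisy = irregularity_fraction(
                w_noisy, gamma_threshold(w_noisy, params.alpha))
            w_base = base.intervals[min(i, base.intervals.size - 8):][:8]
            lam_base = irregularity_fraction(
                w_base, gamma_threshold(w_base, params.alpha))
            assert lam_noisy >= lam_base

    def test_perfect_qc_restores_clean_decision(self):
        """With QC and an accurate classifier, isolated noise between normal
        beats leaves the decision identical to the clean recording."""
        clean = np.arange(0, 24_000, 800.0)
        noise = np.array([4_400.0, 12_400.0])
        noisy = np.sort(np.concatenate([clean, noise]))
        labels = np.isin(noisy, noise).astype(int)
        res = qc_prune(noisy, labels)
        np.testing.assert_array_equal(res.accepted_times, clean)
        params = DetectorParams(N=4, alpha=0.04, eta=0.65)
        clean_decision = detect_af(rr_intervals(clean), params)
        qc_decision = detect_af(
            rr_intervals(res.accepted_times), params,
            qualifies=window_qualifies(res.accepted_times,
                                       res.excluded_times, 4))
        assert qc_decision == clean_decision

    def test_scale_invariance_of_decision(self):
        rng = np.random.default_rng(7)
        iv = rng.uniform(400, 1100, 30)
        times = np.concatenate([[0.0], np.cumsum(iv)])
        params = PRESET_WITH_QC
        a = detect_af(rr_intervals(times), params)
        b = detect_af(rr_intervals(times * 3.7), params)
        assert a.label == b.label and a.fraction == pytest.approx(b.fraction)
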