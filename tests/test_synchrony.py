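"""Peak detection, stimulus-locked matching, coincidence null, cell-chain model."""

import numpy as np
import pytest
from scipy.stats import binom

import wavegraft as wg
from wavegraft.synchrony_efficiency import OverlappingWindowError, match_events


def synthetic_transient_trace(peak_times_s, dt=1 / 34.6, t_end_s=None, amp=1.0):
    t_end_s = t_end_s if t_end_s is not None else max(peak_times_s) + 1.0
    t = np.arange(0, t_end_s, dt)
    v = np.zeros_like(t)
    for pt in peak_times_s:
        v += amp * np.exp(-0.5 * ((t - pt) / 0.05) ** 2)
    return wg.Trace(v, dt)


def brute_force_peaks(values, min_prominence):
    """Textbook local maxima + prominence-from-definition filter."""
    out = []
    n = len(values)
    for i in range(1, n - 1):
        if not (values[i - 1] < values[i] > values[i + 1]):
            continue
        bases = []
        for step in (-1, 1):
            j = i + step
            lowest = values[i]
            base = values[i]
            while 0 <= j < n:
                lowest = min(lowest, values[j])
                if values[j] > values[i]:
                    break
                j += step
            bases.append(lowest)
        prom = values[i] - max(bases)
        if prom >= min_prominence * (values.max() - values.min()):
            out.append(i)
    return np.array(out)


class TestDetectPeaks:
    def test_clean_1hz_train_yields_42_peaks(self):
        trace = synthetic_transient_trace(np.arange(42) + 0.5, t_end_s=43.0)
        peaks = wg.detect_peaks(wg.normalize_trace(trace))
        assert peaks.peak_times_s.size == 42
        np.testing.assert_allclose(np.diff(peaks.peak_times_s), 1.0, atol=1.5 / 34.6)

    def test_monotone_trace_has_no_peaks(self):
        peaks = wg.detect_peaks(wg.Trace(np.linspace(0, 1, 50), 0.03))
        assert peaks.peak_times_s.size == 0

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            values = rng.normal(0, 1, 200)
            trace = wg.Trace(values, 0.1)
            mine = wg.detect_peaks(trace, min_prominence=0.25).peak_times_s / 0.1
            oracle = brute_force_peaks(values, 0.25)
            np.testing.assert_array_equal(np.round(mine).astype(int), oracle)

    def test_min_separation_keeps_most_prominent(self):
        t = np.arange(0, 3.0, 0.01)
        v = np.exp(-0.5 * ((t - 1.0) / 0.05) ** 2) + 0.6 * np.exp(-0.5 * ((t - 1.2) / 0.05) ** 2)
        peaks = wg.detect_peaks(wg.Trace(v, 0.01), min_prominence=0.2, min_separation_s=0.5)
        assert peaks.peak_times_s.size == 1
        assert peaks.peak_times_s[0] == pytest.approx(1.0, abs=0.02)


class TestClassifySynchronization:
    def test_every_second_wave_transmitted(self):
        ref = wg.build_stimulus_train(1.0, 0.02, 42, 0.0)
        graft_times = ref.onset_times_s[::2] + 0.3
        report = wg.classify_synchronization(ref, graft_times, 0.8)
        assert report.n_transmitted == 21
        assert report.fraction == pytest.approx(0.5)

    def test_20_of_42_reports_exact_fraction(self):
        ref = np.arange(42, dtype=float)
        graft = ref[:20] + 0.25
        report = wg.classify_synchronization(ref, graft, 0.8)
        assert report.n_transmitted == 20
        assert report.fraction == pytest.approx(20 / 42)
        assert round(report.fraction, 3) == 0.476

    def test_empty_graft_series(self):
        report = wg.classify_synchronization(np.arange(10.0), np.empty(0), 0.5)
        assert report.fraction == 0.0
        assert report.coincidence_p == 1.0

    def test_fraction_invariant_under_common_time_shift(self, rng):
        ref = np.sort(rng.uniform(0, 60, 20))
        ref = ref[np.concatenate(([True], np.diff(ref) > 1.0))]
        graft = np.sort(rng.uniform(0, 60, 15))
        r0 = wg.classify_synchronization(ref, graft, 0.9)
        r1 = wg.classify_synchronization(ref + 13.7, graft + 13.7, 0.9)
        assert r0.fraction == r1.fraction

    def test_each_graft_peak_consumes_one_reference(self):
        # one graft peak inside two consecutive windows must count once
        report = wg.classify_synchronization(np.array([0.0, 1.0]), np.array([1.3]), 0.8)
        assert report.n_transmitted == 1

    def test_overlapping_window_rejected(self):
        with pytest.raises(OverlappingWindowError):
            wg.classify_synchronization(np.arange(5.0), np.array([0.5]), 1.0)


class TestCoincidenceProbability:
    def test_closed_form_is_exact_binomial_tail(self):
        report = wg.SyncReport(42, 20, np.full(20, 0.2), 0.3)
        out = wg.coincidence_probability(report, 0.5, "closed-form")
        p1 = 0.3 * 0.5
        assert out.coincidence_p == pytest.approx(float(binom.sf(19, 42, p1)))
        assert out.null_method == "closed-form"

    def test_zero_transmitted_gives_probability_one(self):
        report = wg.SyncReport(42, 0, np.empty(0), 0.3)
        assert wg.coincidence_probability(report, 0.5).coincidence_p == 1.0

    def test_monotone_decreasing_in_transmitted_count(self):
        ps = [
            wg.coincidence_probability(
                wg.SyncReport(42, k, np.full(k, 0.1), 0.3), 0.5
            ).coincidence_p
            for k in range(0, 43, 7)
        ]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_monte_carlo_requires_seed(self):
        report = wg.SyncReport(10, 5, np.full(5, 0.1), 0.3)
        with pytest.raises(ValueError):
            wg.coincidence_probability(report, 0.5, "monte-carlo")

    def test_monte_carlo_agrees_with_closed_form_in_the_tail(self):
        """In the far tail (the regime the statistic is used in) the
        pacemaker Monte-Carlo null and the binomial tail coincide; in the
        bulk they differ by construction (the periodic train has a fixed
        spike budget, so window hits are underdispersed vs binomial)."""
        report = wg.SyncReport(42, 20, np.full(20, 0.2), 0.3)
        cf = wg.coincidence_probability(report, 0.5, "closed-form").coincidence_p
        mc = wg.coincidence_probability(
            report, 0.5, "monte-carlo", n_draws=5000, seed=11,
            ref_times_s=np.arange(42.0),
        ).coincidence_p
        se = np.sqrt(max(cf, 1 / 5000) * (1 - cf) / 5000)
        assert abs(mc - cf) <= 3 * se


class TestCellChainModel:
    @pytest.mark.parametrize("distance,cells", [(1000, 10), (100, 1), (149, 1), (150, 2)])
    def test_cells_from_distance_rounds_half_up(self, distance, cells):
        assert wg.cells_from_distance(distance, 100.0) == cells

    def test_invalid_distance_rejected(self):
        with pytest.raises(ValueError):
            wg.cells_from_distance(-5, 100.0)

    def test_contact_time_arithmetic(self):
        ct = wg.monolayer_contact_time(np.array([0.06]), 10)
        assert ct.value_s == pytest.approx(0.006)

    def test_single_cell_contact_time_is_mean_dt(self):
        ct = wg.monolayer_contact_time(np.array([0.2, 0.3]), 1)
        assert ct.value_s == pytest.approx(0.25)

    def test_linearity_under_scaling(self, rng):
        dts = rng.uniform(0.1, 0.4, 8)
        a = wg.monolayer_contact_time(dts, 5)
        b = wg.monolayer_contact_time(2 * dts, 5)
        assert b.value_s == pytest.approx(2 * a.value_s)
        assert b.sigma_s == pytest.approx(2 * a.sigma_s)

    def test_quantization_floor_applies(self):
        dt_frame = 1 / 34.6
        ct = wg.monolayer_contact_time(np.array([0.3, 0.3, 0.3]), 10, dt_frame)
        assert ct.sigma_s == pytest.approx(dt_frame / (np.sqrt(12) * 10))


class TestEfficiencyRatio:
    def test_paper_scale_magnitude(self):
        """264 ms graft vs 6 ms monolayer contact: ratio 44 with ~28% error."""
        graft = wg.ContactTime(0.264, 0.2 * 0.264, "graft")
        mono = wg.ContactTime(0.006, 0.2 * 0.006, "direct-count")
        est = wg.efficiency_ratio(graft, mono)
        assert est.ratio == pytest.approx(44.0)
        assert est.sigma == pytest.approx(44.0 * np.sqrt(2) * 0.2, rel=1e-6)

    def test_equal_times_give_unity(self):
        ct = wg.ContactTime(0.1, 0.01, "graft")
        assert wg.efficiency_ratio(ct, ct).ratio == pytest.approx(1.0)

    def test_reciprocal_ratios_multiply_to_one(self, rng):
        a = wg.ContactTime(float(rng.uniform(0.01, 1)), 0.001, "graft")
        b = wg.ContactTime(float(rng.uniform(0.01, 1)), 0.001, "direct-count")
        assert wg.efficiency_ratio(a, b).ratio * wg.efficiency_ratio(b, a).ratio == \
            pytest.approx(1.0, abs=1e-9)


def test_match_events_greedy_earliest_first():
    # ref 0 takes 0.2 (earliest in window); ref 1 finds nothing in (1.0, 1.6];
    # ref 2 takes 2.5; the unconsumed 0.3 can never serve a later reference
    matches = match_events(np.array([0.0, 1.0, 2.0]), np.array([0.2, 0.3, 2.5]), 0.6)
    assert matches == [(0.0, 0.2), (2.0, 2.5)]
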