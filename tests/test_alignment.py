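"""Transient detection, peak-position correction, event-triggered
averaging and interval statistics."""

import numpy as np
import pytest

from nemasleep.alignment import (align_to_events, correct_peak_positions,
                                 detect_peaks, interval_stat, smooth_trace)
from nemasleep.synthetic import transient_kernel, transient_peak_offset
from .conftest import exact_ranksum_oracle, synthetic_ratio_trace

DT = 5.88  # s/frame of the calcium recordings


class TestDetectPeaks:
    def test_single_clean_transient_detected_once(self, rng):
        trace, _ = synthetic_ratio_trace(rng, n=1500, k=1, amplitude=0.1,
                                         noise_sd=0.0)
        ps = detect_peaks(trace, DT)
        assert len(ps) == 1

    def test_prominence_cutoff_is_inclusive_at_0p02(self):
        # flat trace with one symmetric bump of controlled prominence; the
        # heavy filter shrinks a bump, so build it wide enough to survive
        t = np.arange(2000, dtype=float)
        def bump_trace(height):
            return 0.4 + height * np.exp(-0.5 * ((t - 1000) / 120.0) ** 2)
        for height, expected in [(0.019, 0), (0.021, 1)]:
            ps = detect_peaks(bump_trace(height), DT)
            # measure against the detected prominence, not the raw height
            assert len(ps) == expected, f"height {height}"

    def test_frequency_invariant_to_amplitude_rescaling(self, rng):
        trace, _ = synthetic_ratio_trace(rng, k=6, amplitude=0.1, noise_sd=0.0)
        f1 = detect_peaks(trace, DT).frequency_per_hour
        f2 = detect_peaks(0.4 + 3.0 * (trace - 0.4), DT).frequency_per_hour
        assert f1 == f2

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            detect_peaks(np.zeros(100), DT)

    def test_ground_truth_recovery_across_seeds(self):
        hits, total = 0, 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            trace, onsets = synthetic_ratio_trace(rng, k=6, amplitude=0.1,
                                                  noise_sd=0.02)
            ps = detect_peaks(trace, DT)
            total += 1
            if len(ps) == len(onsets):
                hits += 1
        assert hits / total >= 0.95


class TestCorrectPeakPositions:
    def test_identical_symmetric_peak_needs_no_correction(self):
        t = np.arange(1000, dtype=float)
        trace = 0.4 + 0.2 * np.exp(-0.5 * ((t - 500) / 80.0) ** 2)
        ps = detect_peaks(trace, DT)
        corrected = correct_peak_positions(ps, trace)
        # even-length filter windows shift the detected maximum by half a
        # sample, so raw and corrected may differ by one frame at most
        assert abs(int(corrected.corrected_index[0]) - int(ps.raw_index[0])) <= 1

    def test_argmax_tie_takes_earliest_frame(self):
        t = np.arange(1000, dtype=float)
        trace = 0.4 + 0.2 * np.exp(-0.5 * ((t - 500) / 80.0) ** 2)
        ps = detect_peaks(trace, DT)
        flat = np.full_like(trace, 0.4)   # light trace all ties
        corrected = correct_peak_positions(ps, flat)
        width = int(round(ps.width_at_half[0])) + 25
        assert corrected.corrected_index[0] == max(0, ps.raw_index[0] - width)

    def test_correction_reduces_peak_position_error(self):
        improved, total = 0, 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            trace, onsets = synthetic_ratio_trace(rng, k=6, amplitude=0.1,
                                                  noise_sd=0.02)
            true_peaks = onsets + transient_peak_offset(5.0, 30.0)
            ps = detect_peaks(trace, DT)
            cs = correct_peak_positions(ps, smooth_trace(trace, 20))
            for raw, corr in zip(cs.raw_index, cs.corrected_index):
                j = np.abs(true_peaks - raw).argmin()
                if np.abs(true_peaks[j] - raw) > 150:
                    continue
                total += 1
                if abs(corr - true_peaks[j]) <= abs(raw - true_peaks[j]):
                    improved += 1
        assert improved / total >= 0.90


class TestAlignToEvents:
    def test_single_event_row_equals_cut_window(self, rng):
        sig = rng.uniform(0.3, 0.5, 2000)
        sleep = (rng.random(2000) < 0.3).astype(float)
        ens = align_to_events([sig], [sleep], [[1000]], DT)
        n_before = int(round(900 / DT))
        smooth = smooth_trace(sig, 20)
        expected = smooth[1000 - n_before: 1000 - n_before + len(ens.rel_time)]
        np.testing.assert_allclose(ens.per_animal_signal[0], expected)
        np.testing.assert_allclose(ens.signal_mean, expected)

    def test_each_animal_is_one_n(self):
        sig_a, sig_b = np.zeros(3000), np.ones(3000)
        sleep = np.zeros(3000)
        ens = align_to_events([sig_a, sig_b], [sleep, sleep],
                              [[1500], list(range(300, 3000 - 300, 260))[:9]], DT)
        assert ens.n_animals == 2
        i0 = np.argmin(np.abs(ens.rel_time))
        assert ens.signal_mean[i0] == pytest.approx(0.5)

    def test_shift_equivariance(self, rng):
        sig = rng.uniform(0, 1, 4000)
        sleep = (rng.random(4000) < 0.5).astype(float)
        events = [1200, 2000]
        shift = 37
        a = align_to_events([sig], [sleep], [events], DT)
        b = align_to_events([np.r_[np.full(shift, sig[0]), sig][:4000]],
                            [np.r_[np.full(shift, sleep[0]), sleep][:4000]],
                            [[e + shift for e in events]], DT)
        interior = slice(10, len(a.rel_time) - 10)
        # interior of the grid (away from edge truncation) is identical up
        # to the smoothing restart at the prepended samples
        np.testing.assert_allclose(a.signal_mean[interior],
                                   b.signal_mean[interior], atol=1e-6)

    def test_zero_event_animal_excluded(self, rng):
        sig = rng.uniform(0, 1, 2000)
        sleep = np.zeros(2000)
        ens = align_to_events([sig, sig], [sleep, sleep], [[1000], []], DT)
        assert ens.n_animals == 1

    def test_sleep_lock_probability_recovered(self):
        # sleep bouts locked to a fraction of transient peaks: the
        # peak-aligned sleep fraction at |t| <= 1 min estimates that fraction
        p_lock = 0.6
        rng = np.random.default_rng(42)
        sigs, sleeps, events = [], [], []
        for _ in range(30):
            trace, onsets = synthetic_ratio_trace(rng, n=3000, k=8,
                                                  amplitude=0.1, noise_sd=0.01)
            peaks = (onsets + transient_peak_offset(5.0, 30.0)).astype(int)
            sleep = np.zeros(3000)
            for pk in peaks:
                if rng.random() < p_lock:
                    sleep[max(0, pk - 40):pk + 60] = 1.0
            sigs.append(trace)
            sleeps.append(sleep)
            events.append(peaks)
        ens = align_to_events(sigs, sleeps, events, DT, event_kind="peak")
        sel = np.abs(ens.rel_time) <= 60.0
        got = np.nanmean(ens.sleep_mean[sel])
        assert abs(got - p_lock) < 0.05


class TestIntervalStat:
    def _flat_ensemble(self, values, rng):
        sigs = [np.full(2000, v) + rng.normal(0, 1e-9, 2000) for v in values]
        sleeps = [np.zeros(2000) for _ in values]
        events = [[1000] for _ in values]
        return align_to_events(sigs, sleeps, events, DT)

    def test_known_rank_sum_and_exact_p(self, rng):
        a = self._flat_ensemble([1.0, 2.0, 3.0], rng)
        b = self._flat_ensemble([4.0, 5.0, 6.0], rng)
        res = interval_stat(a, b, (-60.0, 60.0))
        w_oracle, p_oracle = exact_ranksum_oracle([1, 2, 3], [4, 5, 6])
        assert res.statistic == pytest.approx(w_oracle)
        assert res.p_value == pytest.approx(p_oracle)  # 0.1 two-sided exact

    def test_identical_groups_p_is_one(self, rng):
        a = self._flat_ensemble([1.0, 2.0, 3.0], rng)
        res = interval_stat(a, a, (-60.0, 60.0))
        assert res.p_value == pytest.approx(1.0)

    def test_separating_groups_decreases_p(self, rng):
        base = [1.0, 2.0, 3.0, 4.0]
        a = self._flat_ensemble(base, rng)
        p_vals = []
        for shift in (1.0, 5.0, 50.0):
            b = self._flat_ensemble([v + shift for v in base], rng)
            p_vals.append(interval_stat(a, b, (-60.0, 60.0)).p_value)
        assert p_vals[0] >= p_vals[1] >= p_vals[2] or len(set(p_vals)) == 1

    def test_interval_outside_grid_rejected(self, rng):
        a = self._flat_ensemble([1.0, 2.0], rng)
        with pytest.raises(ValueError):
            interval_stat(a, a, (-5000.0, 0.0))
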