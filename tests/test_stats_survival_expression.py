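"""Statistical primitives, survival-curve analysis and reporter
quantification, each checked against an independent brute-force oracle."""

import numpy as np
import pandas as pd
import pytest

from nemasleep.expression import quantify_reporter, reporter_series
from nemasleep.stats import fisher_exact_2x2, wilcoxon_rank_sum
from nemasleep.survival import (SurvivalCurve, effective_concentration,
                                fisher_at_median, smooth_survival)
from nemasleep.synthetic import gen_reporter_image, gen_survival_counts
from .conftest import exact_ranksum_oracle, fisher_oracle, otsu_bruteforce


class TestWilcoxon:
    @pytest.mark.parametrize("n1,n2", [(2, 2), (2, 5), (3, 3), (4, 6), (6, 6),
                                       (5, 3), (6, 2)])
    def test_matches_exhaustive_enumeration(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(5):
            x = rng.permutation(np.arange(1.0, n1 + n2 + 1.0))[:n1]
            y = np.setdiff1d(np.arange(1.0, n1 + n2 + 1.0), x)
            res = wilcoxon_rank_sum(x, y)
            w, p = exact_ranksum_oracle(x, y)
            assert res.method == "exact"
            assert res.statistic == pytest.approx(w)
            assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_textbook_example(self):
        res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert res.statistic == 6.0
        assert res.p_value == pytest.approx(0.1)

    def test_ties_fall_back_to_corrected_normal(self):
        res = wilcoxon_rank_sum([1.0, 2.0, 2.0, 3.0], [1.0, 2.0, 3.0, 3.0])
        assert res.method == "asymptotic"
        assert 0.0 < res.p_value <= 1.0


class TestFisher:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_hypergeometric_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        table = rng.integers(0, 31, (2, 2))  # margins <= 60
        _, p = fisher_exact_2x2(table)
        assert p == pytest.approx(fisher_oracle(table), abs=1e-10)

    def test_identical_rows_give_unit_odds_and_p(self):
        odds, p = fisher_exact_2x2([[30, 70], [30, 70]])
        assert odds == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_reference_table_against_oracle(self):
        _, p = fisher_exact_2x2([[30, 70], [50, 50]])
        assert p == pytest.approx(fisher_oracle([[30, 70], [50, 50]]), abs=1e-10)


class TestSmoothSurvival:
    def test_constant_curve_unchanged(self):
        c = SurvivalCurve(day=np.arange(8), n_alive=np.full(8, 40),
                          n_dead=np.full(8, 10))
        np.testing.assert_allclose(smooth_survival(c).smoothed_fraction, 0.8)

    def test_arithmetic_sequence_center_value(self):
        c = SurvivalCurve(day=np.arange(5), n_alive=[100, 90, 80, 70, 60],
                          n_dead=[0, 10, 20, 30, 40])
        assert smooth_survival(c).smoothed_fraction[2] == pytest.approx(0.8)

    def test_matches_truncated_window_oracle_everywhere(self, rng):
        frac = rng.uniform(0, 1, 17)
        n0 = 1000
        alive = np.round(frac * n0).astype(int)
        c = SurvivalCurve(day=np.arange(17), n_alive=alive, n_dead=n0 - alive)
        got = smooth_survival(c, window=5).smoothed_fraction
        f = c.fraction_alive
        for i in range(17):
            lo, hi = max(0, i - 2), min(17, i + 3)
            assert got[i] == pytest.approx(f[lo:hi].mean())


class TestFisherAtMedian:
    def _curve(self, fracs, n0=100, group=""):
        alive = np.round(np.asarray(fracs) * n0).astype(int)
        return SurvivalCurve(day=np.arange(len(fracs)), n_alive=alive,
                             n_dead=n0 - alive, group=group)

    def test_first_crossing_day_selected(self):
        # smoothing of a steep curve keeps the first <=0.5 crossing visible
        a = self._curve([1.0, 0.9, 0.8, 0.7, 0.6, 0.45, 0.3, 0.2, 0.1, 0.0], group="a")
        b = self._curve([1.0] * 10, group="b")
        res = fisher_at_median({"a": a, "b": b}, use_smoothed=False)
        assert res.day == 5
        assert res.reference_group == "a"

    def test_identical_groups_give_p_one(self):
        fr = [1.0, 0.8, 0.6, 0.4, 0.2]
        res = fisher_at_median({"x": self._curve(fr), "y": self._curve(fr)},
                               use_smoothed=False)
        odds, p = res.pairwise[("x", "y")]
        assert odds == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_no_crossing_raises_with_context(self):
        a = self._curve([1.0, 0.9, 0.8])
        with pytest.raises(ValueError, match="50%"):
            fisher_at_median({"a": a, "b": a})

    def test_separated_hazards_detected_on_generated_counts(self):
        wt = gen_survival_counts(0.05, 300, 30, seed=1, group="wt")
        mut = gen_survival_counts(0.12, 300, 30, seed=2, group="mut")
        res = fisher_at_median({"wt": wt, "mut": mut})
        assert res.reference_group == "mut"
        assert res.pairwise[("mut", "wt")][1] < 1e-4


class TestEffectiveConcentration:
    def test_aldicarb_dilution(self):
        c = effective_concentration(5.0, 10.0, 600.0)
        assert c == pytest.approx(5.0 * 10.0 / 610.0)
        assert round(c, 2) == 0.08

    def test_equal_volumes_halve(self):
        assert effective_concentration(1.0, 50.0, 50.0) == pytest.approx(0.5)

    def test_nothing_added_gives_zero(self):
        assert effective_concentration(1.0, 0.0, 100.0) == 0.0


class TestQuantifyReporter:
    def test_perfectly_bimodal_roi(self):
        roi = np.full((20, 20), 10.0)
        roi[5:15, 5:15] = 100.0
        m = quantify_reporter(roi)
        assert m.mean_above_threshold == pytest.approx(100.0)
        assert not m.flagged

    def test_affine_equivariance_against_bruteforce_otsu(self, rng):
        roi = np.where(rng.random((30, 30)) < 0.3,
                       rng.normal(200, 5, (30, 30)),
                       rng.normal(30, 5, (30, 30)))
        a, b = 1.7, 11.0
        m1 = quantify_reporter(roi)
        m2 = quantify_reporter(a * roi + b)
        assert m2.mean_above_threshold == pytest.approx(
            a * m1.mean_above_threshold + b, rel=1e-3)
        # brute-force oracle agrees on the classification up to histogram
        # binning (skimage quantizes to 256 bins)
        t_bf = otsu_bruteforce(roi.ravel())
        got_above = roi.ravel() > m1.threshold
        mismatch = np.mean(got_above != (roi.ravel() > t_bf))
        assert mismatch <= 0.01

    def test_recovers_known_worm_intensity(self):
        for seed in range(5):
            img, _ = gen_reporter_image(worm_intensity=180.0, background=25.0,
                                        noise_sd=6.0, seed=seed)
            m = quantify_reporter(img)
            assert abs(m.mean_above_threshold - 180.0) / 180.0 < 0.03

    def test_unimodal_roi_flagged(self, rng):
        with pytest.warns(UserWarning):
            m = quantify_reporter(rng.normal(100, 1, (20, 20)))
        assert m.flagged


class TestReporterSeries:
    def test_constant_fluorescence_gives_zero_dff(self):
        s = reporter_series(np.full((3, 6), 50.0))
        np.testing.assert_allclose(s.delta_f_over_f, 0.0)

    def test_dff_definition_and_last4(self):
        values = pd.DataFrame([[100.0, 150.0, 10.0, 20.0, 30.0, 40.0]],
                              columns=[0, 1, 2, 3, 4, 5])
        s = reporter_series(values)
        assert s.delta_f_over_f[0, 1] == pytest.approx(0.5)
        assert s.last4_mean[0] == pytest.approx(25.0)

    def test_nonpositive_day0_worm_excluded(self):
        values = pd.DataFrame([[100.0, 110.0], [0.0, 50.0]], columns=[0, 1])
        with pytest.warns(UserWarning):
            s = reporter_series(values)
        assert len(s.worm_ids) == 1
        assert s.excluded_worms == [1]

    def test_day0_required(self):
        with pytest.raises(ValueError):
            reporter_series(pd.DataFrame([[1.0, 2.0]], columns=[1, 2]))
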