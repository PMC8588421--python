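import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pcgsnr.degradation import SensitivityCurve
from pcgsnr.thresholds import (
    DEFAULT_EPSILONS,
    _runs_pmf,
    find_min_acceptable_snr,
    population_worst_case,
    runs_test_pvalue,
    runs_test_trend,
    threshold_vs_uncertainty,
    uncertainty_bounds,
)


class TestUncertaintyBounds:
    def test_zero_epsilon_is_degenerate(self):
        band = uncertainty_bounds(44.0, epsilon_pct=0.0)
        assert band.lower_ms == band.upper_ms == 44.0

    def test_ten_percent_band_around_44_ms(self):
        band = uncertainty_bounds(44.0, epsilon_pct=10.0)
        assert band.lower_ms == pytest.approx(39.6)
        assert band.upper_ms == pytest.approx(48.4)

    def test_absolute_mode_is_plus_minus_1_ms(self):
        band = uncertainty_bounds(368.0, absolute_1ms=True)
        assert (band.lower_ms, band.upper_ms) == (367.0, 369.0)

    def test_negative_epsilon_rejected(self):
        with pytest.raises(ValueError):
            uncertainty_bounds(44.0, epsilon_pct=-1.0)


class TestRunsDistribution:
    @pytest.mark.parametrize("n1,n2", [(3, 3), (4, 6), (8, 8), (5, 11)])
    def test_pmf_matches_bruteforce_enumeration(self, n1, n2):
        """Independent oracle: enumerate every arrangement of n1 plus and
        n2 minus signs and tally the runs counts."""
        n = n1 + n2
        counts = np.zeros(n + 2)
        total = 0
        for pos in itertools.combinations(range(n), n1):
            s = -np.ones(n)
            s[list(pos)] = 1
            runs = 1 + int((s[1:] != s[:-1]).sum())
            counts[runs] += 1
            total += 1
        pmf = _runs_pmf(n1, n2)
        np.testing.assert_allclose(pmf, counts[: n + 1] / total, atol=1e-12)

    def test_pvalue_close_to_normal_approximation_at_n40(self):
        # cross-check against the large-sample z statistic
        from scipy.stats import norm
        n1 = n2 = 20
        for runs in (12, 15, 26):
            n = n1 + n2
            mu = 1 + 2 * n1 * n2 / n
            var = 2 * n1 * n2 * (2 * n1 * n2 - n) / (n * n * (n - 1))
            p_norm = 2 * norm.sf(abs((runs - mu) / np.sqrt(var)))
            assert runs_test_pvalue(n1, n2, runs) == pytest.approx(p_norm, abs=0.03)

    def test_pvalue_agrees_with_statsmodels_runs_test(self):
        # independent implementation cross-check on concrete sequences
        from statsmodels.sandbox.stats.runs import runstest_1samp
        rng = np.random.default_rng(3)
        for _ in range(10):
            x = rng.choice([-1.0, 1.0], size=40)
            if len(set(x)) < 2:
                continue
            _, p_sm = runstest_1samp(x, cutoff=0, correction=False)
            n1 = int((x > 0).sum())
            runs = 1 + int((x[1:] != x[:-1]).sum())
            assert runs_test_pvalue(n1, 40 - n1, runs) == pytest.approx(
                p_sm, abs=0.05)


class TestRunsTestTrend:
    def test_alternating_signs_show_no_trend(self):
        devs = np.tile([1.0, -1.0], 10)
        res = runs_test_trend(devs)
        assert res.runs == 20 and not res.trend

    def test_two_blocks_of_ten_are_a_trend(self):
        devs = np.concatenate([np.ones(10), -np.ones(10)])
        res = runs_test_trend(devs)
        assert res.runs == 2 and res.p_value < 0.05 and res.trend

    def test_single_sign_sequence_is_a_trend_candidate(self):
        assert runs_test_trend(np.ones(15)).trend
        assert not runs_test_trend(np.ones(5)).trend  # too short

    def test_all_zero_deviations_carry_no_trend(self):
        res = runs_test_trend(np.zeros(30))
        assert not res.trend and res.p_value == 1.0

    def test_clustering_requirement_excludes_alternation_rejections(self):
        devs = np.tile([1.0, -1.0], 15)  # runs far above expectation
        res = runs_test_trend(devs)
        assert res.p_value < 0.05 and not res.trend


def _curve(grid, lat):
    comps = {c: (np.asarray(grid, dtype=float), np.asarray(lat, dtype=float))
             for c in ("mitral", "tricuspid", "aortic", "pulmonary")}
    return SensitivityCurve(components=comps, n_runs=1, run_curves=[])


def _breakdown_curve(break_snr=14.0, dev=3.0, hi=20.0, lo=6.0, ref=44.0,
                     pre_dev=0.5):
    grid = np.round(np.arange(hi * 10, lo * 10 - 1, -1)) / 10
    lat = np.where(grid > break_snr + 1e-9, ref + pre_dev, ref + dev)
    lat[0] = ref  # reference point
    return grid, lat


class TestFindMinAcceptableSnr:
    def test_flat_curve_returns_not_available(self):
        grid = np.arange(200, 59, -1) / 10
        res = find_min_acceptable_snr(grid, np.full_like(grid, 44.0),
                                      uncertainty_bounds(44.0, absolute_1ms=True))
        assert not res.available and res.snr_db is None

    def test_constructed_breakdown_found_at_exact_grid_point(self):
        grid, lat = _breakdown_curve(break_snr=14.0)
        res = find_min_acceptable_snr(grid, lat,
                                      uncertainty_bounds(44.0, absolute_1ms=True))
        assert res.available and res.snr_db == pytest.approx(14.0, abs=1e-9)

    def test_wider_band_triggers_at_or_below_the_1ms_threshold(self):
        grid, lat = _breakdown_curve(break_snr=14.0, dev=10.0)
        thr_abs = find_min_acceptable_snr(
            grid, lat, uncertainty_bounds(44.0, absolute_1ms=True)).snr_db
        thr_20 = find_min_acceptable_snr(
            grid, lat, uncertainty_bounds(44.0, epsilon_pct=20.0)).snr_db
        assert thr_20 <= thr_abs

    def test_scan_is_deterministic(self):
        grid, lat = _breakdown_curve()
        band = uncertainty_bounds(44.0, absolute_1ms=True)
        a = find_min_acceptable_snr(grid, lat, band)
        b = find_min_acceptable_snr(grid, lat, band)
        assert a.snr_db == b.snr_db

    def test_missing_grid_points_are_skipped_and_counted(self):
        grid, lat = _breakdown_curve()
        lat[5:8] = np.nan
        res = find_min_acceptable_snr(grid, lat,
                                      uncertainty_bounds(44.0, absolute_1ms=True))
        assert res.n_skipped == 3 and res.available

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        break_point=st.integers(min_value=30, max_value=110),
        drift=st.floats(min_value=1.5, max_value=12.0),
        ref=st.sampled_from([44.0, 77.0, 368.0, 392.0]),
    )
    def test_threshold_monotone_in_epsilon(self, break_point, drift, ref):
        """Band nesting: wider acceptable uncertainty can only move the
        threshold to the same or a lower SNR."""
        grid = np.arange(200, 59, -1) / 10
        lat = np.full_like(grid, ref)
        lat[break_point:] = ref + drift * ref / 44.0
        prev = np.inf
        for eps in DEFAULT_EPSILONS:
            res = find_min_acceptable_snr(
                grid, lat, uncertainty_bounds(ref, epsilon_pct=eps))
            value = res.snr_db if res.available else -np.inf
            assert value <= prev + 1e-9
            prev = value


class TestPopulationAggregation:
    def test_worst_case_is_the_maximum(self):
        results = [find_min_acceptable_snr(*_breakdown_curve(break_snr=b),
                                           uncertainty_bounds(44.0, absolute_1ms=True))
                   for b in (6.0, 10.0, 12.0)]
        assert population_worst_case(results) == (12.0, 0)

    def test_not_available_subjects_excluded_but_counted(self):
        grid = np.arange(200, 59, -1) / 10
        flat = find_min_acceptable_snr(
            grid, np.full_like(grid, 44.0), uncertainty_bounds(44.0, absolute_1ms=True))
        good = find_min_acceptable_snr(
            *_breakdown_curve(break_snr=9.0), uncertainty_bounds(44.0, absolute_1ms=True))
        value, n_na = population_worst_case([good, flat])
        assert value == 9.0 and n_na == 1

    def test_all_not_available_propagates(self):
        grid = np.arange(200, 59, -1) / 10
        flat = find_min_acceptable_snr(
            grid, np.full_like(grid, 44.0), uncertainty_bounds(44.0, absolute_1ms=True))
        assert population_worst_case([flat]) == (None, 1)


class TestThresholdVsUncertainty:
    REFS = {"mitral": 44.0, "tricuspid": 77.0, "aortic": 368.0, "pulmonary": 392.0}

    def test_rows_non_increasing_as_epsilon_grows(self):
        grid, lat = _breakdown_curve(break_snr=12.0, dev=9.0)
        curves = {"s1": _curve(grid, lat)}
        df = threshold_vs_uncertainty(curves, self.REFS, DEFAULT_EPSILONS)
        for comp in self.REFS:
            assert np.all(np.diff(df[comp].to_numpy()) <= 1e-9)

    def test_never_deviating_curve_falls_back_to_min_snr_reached(self):
        grid = np.arange(200, 59, -1) / 10
        curves = {"s1": _curve(grid, np.full_like(grid, 368.0))}
        df = threshold_vs_uncertainty(curves, self.REFS, [20.0])
        assert df.loc[0, "aortic"] == pytest.approx(6.0)

    def test_single_subject_table_equals_that_subject(self):
        grid, lat = _breakdown_curve(break_snr=10.0, dev=30.0, ref=44.0)
        curves = {"only": _curve(grid, lat)}
        df = threshold_vs_uncertainty(curves, self.REFS, [2.5])
        single = find_min_acceptable_snr(
            grid, lat, uncertainty_bounds(44.0, epsilon_pct=2.5)).snr_db
        assert df.loc[0, "mitral"] == pytest.approx(single)
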