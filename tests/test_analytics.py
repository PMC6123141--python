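"""DVH band aggregation, endpoint tables, time series, two-group tests,
correlations, and regressions."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dvhdb.analytics import (
    aggregate_dvhs,
    compare_groups,
    correlation_matrix,
    endpoint_table,
    fit_multivariable,
    fit_univariable,
    time_series,
)
from dvhdb.dvh import DoseVolumeHistogram, EndpointSpec


def _uniform_dvh(dose, volume, bw=0.01):
    diff = np.zeros(int(dose / bw) + 2)
    diff[int(dose / bw)] = volume
    cum = np.cumsum(diff[::-1])[::-1]
    return DoseVolumeHistogram(
        bin_width=bw, diff_counts=diff, cumulative=cum, volume=volume,
        min_dose=dose, mean_dose=dose, max_dose=dose, rx_dose=dose,
    )


def _random_dvh(rng, bw=0.05):
    n = rng.integers(50, 200)
    diff = rng.uniform(0, 1, n)
    cum = np.cumsum(diff[::-1])[::-1]
    return DoseVolumeHistogram(
        bin_width=bw, diff_counts=diff, cumulative=cum, volume=float(diff.sum()),
        min_dose=0.0, mean_dose=1.0, max_dose=n * bw,
    )


class TestAggregateDvhs:
    def test_identical_sample_degenerate_bands(self):
        dvh = _uniform_dvh(60.0, 8.0)
        bands = aggregate_dvhs([dvh] * 5)
        ref = np.interp(bands.dose_axis, dvh.dose_edges, dvh.cumulative, right=0.0)
        for curve in (bands.mean, bands.median, bands.q1, bands.q3):
            np.testing.assert_allclose(curve, ref)

    def test_two_step_dvhs_relative(self):
        bands = aggregate_dvhs(
            [_uniform_dvh(50.0, 8.0), _uniform_dvh(70.0, 8.0)], relative=True
        )
        axis = bands.dose_axis
        assert bands.mean[axis <= 49.9].min() == pytest.approx(100.0)
        mid = (axis > 50.05) & (axis <= 69.9)
        np.testing.assert_allclose(bands.mean[mid], 50.0)
        assert bands.mean[axis > 70.0].max() == pytest.approx(0.0)

    def test_matches_per_bin_percentile_oracle(self):
        rng = np.random.default_rng(11)
        sample = [_random_dvh(rng) for _ in range(20)]
        bands = aggregate_dvhs(sample, percentiles=(25, 75))
        axis = bands.dose_axis
        curves = np.vstack(
            [np.interp(axis, d.dose_edges, d.cumulative, right=0.0) for d in sample]
        )
        for i, d in enumerate(sample):  # beyond each curve's max the volume is zero
            curves[i, axis > d.dose_edges[-1]] = 0.0
        np.testing.assert_allclose(bands.median, np.median(curves, axis=0))
        np.testing.assert_allclose(bands.q1, np.percentile(curves, 25, axis=0))
        np.testing.assert_allclose(bands.q3, np.percentile(curves, 75, axis=0))

    def test_bands_ordered_and_monotone(self):
        rng = np.random.default_rng(3)
        bands = aggregate_dvhs([_random_dvh(rng) for _ in range(10)])
        assert np.all(bands.q1 <= bands.median + 1e-12)
        assert np.all(bands.median <= bands.q3 + 1e-12)
        for curve in (bands.mean, bands.median, bands.q1, bands.q3):
            assert np.all(np.diff(curve) <= 1e-9)

    def test_empty_sample_is_error(self):
        with pytest.raises(ValueError):
            aggregate_dvhs([])


class TestEndpointTable:
    def test_uniform_sample_d95(self):
        entries = [
            {"mrn": f"M{i}", "roi_name": "PTV", "dvh": _uniform_dvh(60.0, 8.0)}
            for i in range(3)
        ]
        table = endpoint_table(entries, [EndpointSpec("D", 95, "%")])
        np.testing.assert_allclose(table["D_95%"], 60.0, atol=0.011)

    def test_two_specs_two_columns(self):
        entries = [{"mrn": "M", "roi_name": "r", "dvh": _uniform_dvh(60.0, 8.0)}]
        table = endpoint_table(
            entries, [EndpointSpec("D", 2, "cc"), EndpointSpec("V", 20, "Gy")]
        )
        assert {"D_2cc", "V_20Gy"} <= set(table.columns)

    def test_values_equal_direct_calls(self):
        from dvhdb.dvh import evaluate_endpoint

        rng = np.random.default_rng(8)
        dvhs = [_random_dvh(rng) for _ in range(5)]
        specs = [EndpointSpec("D", 50, "%"), EndpointSpec("V", 2, "Gy")]
        table = endpoint_table(
            [{"mrn": str(i), "roi_name": "r", "dvh": d} for i, d in enumerate(dvhs)],
            specs,
        )
        for i, d in enumerate(dvhs):
            for spec in specs:
                assert table.loc[i, spec.label] == pytest.approx(
                    evaluate_endpoint(d, spec)
                )

    def test_ninth_endpoint_rejected(self):
        with pytest.raises(ValueError, match="8"):
            endpoint_table([], [EndpointSpec("D", v, "%") for v in range(1, 10)])


class TestTimeSeries:
    def test_constant_series(self):
        res = time_series(np.arange(10), np.full(10, 7.0), lookback_window=3)
        np.testing.assert_allclose(res.moving_average, 7.0)
        assert res.band_low == res.band_high == 7.0
        assert res.sample_mean == 7.0

    def test_window_oracle(self):
        """Values 1..10 on 10 dates, window of 3 dates: MA at the last date
        is mean(8, 9, 10) = 9."""
        res = time_series(np.arange(10), np.arange(1.0, 11.0), lookback_window=3)
        assert res.moving_average[-1] == pytest.approx(9.0)
        assert res.moving_average[0] == pytest.approx(1.0)
        assert res.moving_average[4] == pytest.approx(np.mean([3, 4, 5]))

    def test_window_in_distinct_dates_not_rows(self):
        """Two values on one date count as one simulation date."""
        dates = np.array([0, 1, 1, 2])
        values = np.array([1.0, 2.0, 4.0, 9.0])
        res = time_series(dates, values, lookback_window=2)
        # at date 2, window covers dates {1, 2}: mean(2, 4, 9)
        assert res.moving_average[-1] == pytest.approx(np.mean([2, 4, 9]))

    def test_exclusion_removed_from_ma_and_mean(self):
        values = np.array([1.0, 2.0, 3.0, 100.0, 5.0])
        res = time_series(np.arange(5), values, lookback_window=5, excluded={3})
        assert res.moving_average[-1] == pytest.approx(np.mean([1, 2, 3, 5]))
        assert res.sample_mean == pytest.approx(np.mean([1, 2, 3, 5]))

    def test_full_window_equals_running_mean(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=12)
        res = time_series(np.arange(12), values, lookback_window=100)
        running = np.cumsum(values) / np.arange(1, 13)
        np.testing.assert_allclose(res.moving_average, running)

    def test_all_excluded_is_error(self):
        with pytest.raises(ValueError):
            time_series([0, 1], [1.0, 2.0], excluded={0, 1})


class TestCompareGroups:
    def test_identical_groups(self):
        g = [1.0, 2.0, 3.0, 4.0]
        res = compare_groups(g, g)
        assert res.p_ttest == pytest.approx(1.0)
        assert res.p_wilcoxon == pytest.approx(1.0)

    def test_separated_groups_tiny_p(self):
        rng = np.random.default_rng(0)
        g1 = rng.normal(0, 1, 50)
        g2 = rng.normal(5, 1, 50)
        res = compare_groups(g1, g2)
        assert res.p_ttest < 1e-10
        assert res.p_wilcoxon < 1e-10

    def test_ranksum_matches_exact_enumeration(self):
        """For a 5+5 toy sample the rank-sum p equals enumeration of all
        C(10,5) rank assignments."""
        g1 = [1.2, 3.4, 2.2, 5.0, 0.7]
        g2 = [2.9, 4.1, 6.3, 1.9, 7.7]
        res = compare_groups(g1, g2)
        pooled = np.array(g1 + g2)
        ranks = stats.rankdata(pooled)
        n1 = len(g1)
        u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
        us = np.array(
            [ranks[list(c)].sum() - n1 * (n1 + 1) / 2
             for c in combinations(range(len(pooled)), n1)]
        )
        p_exact = min(1.0, 2 * min(np.mean(us <= u_obs), np.mean(us >= u_obs)))
        assert res.p_wilcoxon == pytest.approx(p_exact, rel=1e-12)

    def test_symmetric_in_group_order(self):
        rng = np.random.default_rng(4)
        g1, g2 = rng.normal(0, 1, 12), rng.normal(0.5, 2, 15)
        a, b = compare_groups(g1, g2), compare_groups(g2, g1)
        assert a.p_ttest == pytest.approx(b.p_ttest)
        assert a.p_wilcoxon == pytest.approx(b.p_wilcoxon)
        assert a.p_normality_g1 == b.p_normality_g2

    def test_constant_group_normality_undefined(self):
        res = compare_groups([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])
        assert res.p_normality_g1 is None
        assert res.p_normality_g2 is not None

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0, 2.0], [1.0, 2.0, 3.0])


class TestCorrelation:
    def test_perfect_positive_and_negative(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"x": x, "y": x.copy(), "z": -2 * x + 3})
        m = correlation_matrix(df, ["x", "y", "z"])
        assert m.r[0, 1] == pytest.approx(1.0)
        assert m.r[0, 2] == pytest.approx(-1.0)
        np.testing.assert_allclose(m.r, m.r.T)
        np.testing.assert_allclose(np.diag(m.r), 1.0)

    def test_independent_normals_near_zero(self):
        rng = np.random.default_rng(12)
        df = pd.DataFrame({"a": rng.normal(size=1000), "b": rng.normal(size=1000)})
        m = correlation_matrix(df, ["a", "b"])
        assert abs(m.r[0, 1]) < 0.1

    def test_insufficient_pairs_undefined(self):
        df = pd.DataFrame({"x": [1.0, 2.0, np.nan, np.nan],
                           "y": [np.nan, np.nan, 1.0, 2.0]})
        m = correlation_matrix(df, ["x", "y"])
        assert np.isnan(m.r[0, 1])


class TestRegression:
    def test_exact_line(self):
        x = np.arange(10.0)
        fit = fit_univariable(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.n == 10

    def test_noisy_recovery_within_3se(self):
        rng = np.random.default_rng(21)
        x = rng.uniform(0, 10, 200)
        y = 2 * x + 1 + rng.normal(0, 0.1, 200)
        fit = fit_univariable(x, y)
        assert abs(fit.slope - 2.0) < 3 * fit.std_err

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_univariable([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="constant"):
            fit_univariable([3.0, 3.0, 3.0], [1.0, 2.0, 3.0])

    def test_slope_r_identity(self):
        """slope * sd(x)/sd(y) equals the Pearson R of the same pair."""
        rng = np.random.default_rng(31)
        x = rng.uniform(0, 5, 100)
        y = 0.7 * x + rng.normal(0, 1, 100)
        fit = fit_univariable(x, y)
        m = correlation_matrix(pd.DataFrame({"x": x, "y": y}), ["x", "y"])
        assert fit.slope * np.std(x) / np.std(y) == pytest.approx(m.r[0, 1], rel=1e-9)

    def test_multivariable_exact_plane(self):
        rng = np.random.default_rng(41)
        X = pd.DataFrame({"x1": rng.uniform(0, 10, 50), "x2": rng.uniform(0, 10, 50)})
        y = 2 * X["x1"] - 3 * X["x2"] + 5
        fit = fit_multivariable(X, y)
        assert fit.coefficients["x1"] == pytest.approx(2.0)
        assert fit.coefficients["x2"] == pytest.approx(-3.0)
        assert fit.intercept == pytest.approx(5.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_multivariable_noisy_recovery(self):
        rng = np.random.default_rng(51)
        n = 500
        X = pd.DataFrame({"x1": rng.uniform(0, 10, n), "x2": rng.uniform(0, 10, n)})
        y = 2 * X["x1"] - 3 * X["x2"] + 5 + rng.normal(0, 0.5, n)
        fit = fit_multivariable(X, y)
        import statsmodels.api as sm

        model = sm.OLS(y, sm.add_constant(X)).fit()
        for name, truth in (("x1", 2.0), ("x2", -3.0)):
            assert abs(fit.coefficients[name] - truth) < 3 * model.bse[name]
        assert fit.f_prob < 1e-10

    def test_single_predictor_reproduces_univariable(self):
        rng = np.random.default_rng(61)
        x = rng.uniform(0, 10, 80)
        y = 1.5 * x + rng.normal(0, 1, 80)
        uni = fit_univariable(x, y)
        multi = fit_multivariable(pd.DataFrame({"x": x}), y)
        assert multi.coefficients["x"] == pytest.approx(uni.slope, rel=1e-9)
        assert multi.intercept == pytest.approx(uni.intercept, rel=1e-9)
        assert multi.r_squared == pytest.approx(uni.r_squared, rel=1e-9)
        assert multi.p_values["x"] == pytest.approx(uni.p_value, rel=1e-6)

    def test_collinear_design_names_columns(self):
        x = np.arange(10.0)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="collinear"):
            fit_multivariable(X, x)
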