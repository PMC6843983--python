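"""Year-over-year statistic, seasonal summaries, trend model, kriging."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from ecolattice import simulate, temperature
from ecolattice.errors import (
    DegenerateInputError,
    InsufficientDataError,
    NumericalConditioningError,
)
from ecolattice.spde import MaternSpec, matern1_correlation


def _series(dates, values, variable="min"):
    col = "tmin_c" if variable == "min" else "tmax_c"
    other = "tmax_c" if variable == "min" else "tmin_c"
    return pd.DataFrame({"date": pd.to_datetime(dates), col: values, other: values})


@pytest.mark.parametrize(
    "date,season",
    [
        ("2008-07-15", "summer"),
        ("2008-12-01", "winter"),
        ("2008-03-01", "spring"),
        ("2008-11-30", "autumn"),
        ("2008-02-29", "winter"),
    ],
)
def test_season_of_meteorological_boundaries(date, season):
    assert temperature.season_of(date) == season


class TestYoyDifferences:
    def test_identical_years_give_zero(self):
        dates = pd.date_range("2007-01-01", "2008-12-31")
        vals = np.tile(np.arange(365.0), 3)[: len(dates)]
        # force exact same-calendar-day values
        df = _series(dates, [d.month * 1.0 + d.day for d in dates])
        out = temperature.yoy_differences(df, "min")
        assert len(out) > 300
        assert np.allclose(out["diff"], 0.0)

    def test_constant_shift_propagates(self):
        dates = pd.date_range("2007-01-01", "2008-12-31")
        vals = np.where(pd.to_datetime(dates).year == 2008, 10.5, 10.0)
        out = temperature.yoy_differences(_series(dates, vals), "min")
        assert np.allclose(out["diff"], 0.5)

    def test_feb29_excluded(self):
        dates = pd.date_range("2007-01-01", "2009-12-31")  # includes 2008-02-29
        out = temperature.yoy_differences(_series(dates, np.zeros(len(dates))), "min")
        assert not ((out.date.dt.month == 2) & (out.date.dt.day == 29)).any()

    def test_matches_bruteforce_loop_with_missingness(self):
        cfg = simulate.GeneratorConfig(n_stations=1, missing_rate=0.10, seed=17)
        st = simulate.generate_station_series(cfg)
        out = temperature.yoy_differences(st, "max")
        # oracle: explicit double loop over calendar-matched (day, month) pairs
        d = pd.to_datetime(st.date)
        lookup = {}
        for dd, v in zip(d, st.tmax_c):
            if not (dd.month == 2 and dd.day == 29) and not np.isnan(v):
                lookup[(dd.year, dd.month, dd.day)] = v
        expected = {}
        for (y, m, day), v in lookup.items():
            if (y - 1, m, day) in lookup:
                expected[dt.date(y, m, day)] = v - lookup[(y - 1, m, day)]
        got = {d.date(): v for d, v in zip(out.date, out["diff"])}
        assert got.keys() == expected.keys()
        assert all(abs(got[k] - expected[k]) < 1e-12 for k in expected)

    def test_antisymmetry_under_year_swap(self):
        rng = np.random.default_rng(3)
        dates = pd.date_range("2007-01-01", "2008-12-31")
        vals = rng.normal(10, 3, len(dates))
        fwd = temperature.yoy_differences(_series(dates, vals), "min")
        # swap the two years' values day by day
        d = pd.to_datetime(dates)
        frame = pd.DataFrame({"m": d.month, "d": d.day, "y": d.year, "v": vals})
        sw = frame.copy()
        sw["y"] = np.where(sw.y == 2007, 2008, 2007)
        sw = sw[~((sw.m == 2) & (sw.d == 29))]
        sw_dates = pd.to_datetime(
            {"year": sw.y, "month": sw.m, "day": sw.d}
        )
        rev = temperature.yoy_differences(_series(sw_dates, sw.v.to_numpy()), "min")
        merged = fwd.merge(rev, on="date", suffixes=("_f", "_r"))
        assert len(merged) == len(fwd)
        np.testing.assert_allclose(merged.diff_f, -merged.diff_r)

    def test_single_year_rejected(self):
        dates = pd.date_range("2007-01-01", "2007-12-31")
        with pytest.raises(InsufficientDataError):
            temperature.yoy_differences(_series(dates, np.zeros(len(dates))), "min")


class TestSummarizeVariation:
    def test_single_july_difference(self):
        diffs = pd.DataFrame({"date": [pd.Timestamp("2008-07-10")], "diff": [1.0]})
        out = temperature.summarize_variation(diffs).set_index("season")
        assert out.loc["summer", "mean_variation"] == 1.0
        assert out.loc["summer", "n_pairs"] == 1
        for s in ("spring", "autumn", "winter"):
            assert out.loc[s, "n_pairs"] == 0
            assert np.isnan(out.loc[s, "mean_variation"])
        assert out.loc["annual", "n_pairs"] == 1

    def test_annual_is_pair_weighted_mean_of_seasons(self, rng):
        dates = pd.date_range("2008-01-01", "2008-12-31")
        diffs = pd.DataFrame({"date": dates, "diff": rng.normal(size=len(dates))})
        out = temperature.summarize_variation(diffs).set_index("season")
        seasonal = out.loc[list(temperature.SEASONS)]
        weighted = np.average(seasonal.mean_variation, weights=seasonal.n_pairs)
        assert out.loc["annual", "mean_variation"] == pytest.approx(weighted)

    def test_matches_bruteforce_groupby(self, rng):
        dates = pd.to_datetime(
            rng.integers(
                pd.Timestamp("2008-01-01").value // 10**9,
                pd.Timestamp("2010-12-31").value // 10**9,
                1000,
            ),
            unit="s",
        ).normalize()
        vals = rng.normal(size=1000)
        out = temperature.summarize_variation(
            pd.DataFrame({"date": dates, "diff": vals})
        ).set_index("season")
        for s in temperature.SEASONS:
            mask = np.array([temperature.season_of(d) == s for d in dates])
            assert out.loc[s, "mean_variation"] == pytest.approx(vals[mask].mean())
            assert out.loc[s, "n_pairs"] == mask.sum()


class TestFitTrend:
    def test_null_trend_interval_covers_zero(self):
        hits = 0
        for r in range(20):
            cfg = simulate.GeneratorConfig(
                n_stations=5,
                trend_tmax=0.0,
                date_end=dt.date(2009, 12, 31),
                seed=500 + r,
            )
            st = simulate.generate_station_series(cfg)
            tf = temperature.fit_trend(st, "max")
            if tf.trend_q025 <= 0.0 <= tf.trend_q975:
                hits += 1
        assert hits >= 18

    def test_recovers_study_scale_minimum_trend(self):
        cfg = simulate.GeneratorConfig(n_stations=40, trend_tmin=0.332, seed=77)
        st = simulate.generate_station_series(cfg)
        tf = temperature.fit_trend(st, "min")
        assert abs(tf.trend5_mean - 0.332) <= 3 * tf.trend5_sd
        assert tf.trend5_q025 <= tf.trend5_mean <= tf.trend5_q975

    def test_matches_closed_form_least_squares_without_harmonics(self):
        rng = np.random.default_rng(9)
        dates = pd.date_range("2007-01-01", "2009-12-31")
        t = np.arange(len(dates)) / 365.25
        vals = 5.0 + 0.2 * t + rng.normal(0, 0.5, len(dates))
        df = pd.DataFrame(
            {"station_id": "s0", "date": dates, "tmax_c": vals, "tmin_c": vals}
        )
        tf = temperature.fit_trend(df, "max", n_harmonics=0, station_effects=False)
        tc = t - t.mean()
        X = np.column_stack([np.ones(len(t)), tc])
        beta = np.linalg.solve(X.T @ X, X.T @ vals)
        assert tf.trend_mean == pytest.approx(beta[1], abs=1e-10)

    def test_single_day_design_rejected(self):
        df = pd.DataFrame(
            {
                "station_id": ["a", "b"] * 3,
                "date": ["2007-05-01"] * 6,
                "tmax_c": np.arange(6.0),
                "tmin_c": np.arange(6.0),
            }
        )
        with pytest.raises((DegenerateInputError, InsufficientDataError)):
            temperature.fit_trend(df, "max")


class TestKriging:
    SPEC = MaternSpec(range_m=30_000.0, sd=1.0)

    def _stations(self, rng, n=8):
        return pd.DataFrame(
            {
                "x": rng.uniform(0, 100_000, n),
                "y": rng.uniform(0, 100_000, n),
                "value": rng.normal(0, 1, n),
            }
        )

    def test_exact_interpolation_without_nugget(self, rng):
        st = self._stations(rng)
        pred = temperature.krige_to_cells(st, st[["x", "y"]], self.SPEC, nugget_sd=0.0)
        np.testing.assert_allclose(pred["mean"], st.value, atol=1e-8)
        np.testing.assert_allclose(pred["sd"], 0.0, atol=1e-6)

    def test_constant_field_predicts_constant(self, rng):
        st = self._stations(rng)
        st["value"] = 3.7
        cells = pd.DataFrame({"x": [10_000.0, 55_000.0], "y": [20_000.0, 70_000.0]})
        pred = temperature.krige_to_cells(st, cells, self.SPEC, nugget_sd=0.0)
        np.testing.assert_allclose(pred["mean"], 3.7, atol=1e-8)

    def test_matches_dense_gp_conditional_mean(self, rng):
        st = self._stations(rng, n=10)
        cells = pd.DataFrame(
            {"x": rng.uniform(0, 100_000, 15), "y": rng.uniform(0, 100_000, 15)}
        )
        nug = 0.3
        pred = temperature.krige_to_cells(st, cells, self.SPEC, nugget_sd=nug)
        # oracle: explicit dense conditional-mean formula
        pts = st[["x", "y"]].to_numpy()
        z = st.value.to_numpy()
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        K = matern1_correlation(d, self.SPEC.range_m) + nug**2 * np.eye(len(pts))
        ones = np.ones(len(pts))
        Ki = np.linalg.inv(K)
        m = ones @ Ki @ z / (ones @ Ki @ ones)
        cx = cells[["x", "y"]].to_numpy()
        ks = matern1_correlation(
            np.linalg.norm(cx[:, None] - pts[None, :], axis=2), self.SPEC.range_m
        )
        expect = m + ks @ Ki @ (z - m)
        np.testing.assert_allclose(pred["mean"], expect, atol=1e-8)

    def test_conditional_sd_bounded_by_prior_sd(self, rng):
        st = self._stations(rng)
        cells = pd.DataFrame(
            {"x": rng.uniform(-50_000, 150_000, 30), "y": rng.uniform(-50_000, 150_000, 30)}
        )
        pred = temperature.krige_to_cells(st, cells, self.SPEC, nugget_sd=0.0)
        assert (pred["sd"] <= self.SPEC.sd + 1e-9).all()

    def test_duplicate_stations_without_nugget_rejected(self):
        st = pd.DataFrame({"x": [0.0, 0.0, 5.0], "y": [0.0, 0.0, 5.0], "value": [1.0, 2.0, 3.0]})
        cells = pd.DataFrame({"x": [1.0], "y": [1.0]})
        with pytest.raises(NumericalConditioningError):
            temperature.krige_to_cells(st, cells, self.SPEC, nugget_sd=0.0)

    def test_maximum_likelihood_estimation_runs(self, rng):
        st = self._stations(rng, n=25)
        cells = pd.DataFrame({"x": [50_000.0], "y": [50_000.0]})
        pred = temperature.krige_to_cells(st, cells, estimate=True)
        assert np.isfinite(pred["mean"]).all() and np.isfinite(pred["sd"]).all()

    def test_too_few_stations_rejected(self):
        st = pd.DataFrame({"x": [0.0, 1.0], "y": [0.0, 1.0], "value": [1.0, 2.0]})
        with pytest.raises(InsufficientDataError):
            temperature.krige_to_cells(st, st[["x", "y"]], self.SPEC)


class TestTrendCoverageInvariant:
    def test_interval_coverage_over_replicates(self):
        """95% interval covers the generating trend in >= 42 of 50 small runs."""
        hits = 0
        for r in range(50):
            cfg = simulate.GeneratorConfig(
                n_stations=4,
                trend_tmax=0.2,
                date_end=dt.date(2008, 12, 31),
                seed=9000 + r,
            )
            st = simulate.generate_station_series(cfg)
            tf = temperature.fit_trend(st, "max")
            if tf.trend5_q025 <= 0.2 <= tf.trend5_q975:
                hits += 1
        assert hits >= 42
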