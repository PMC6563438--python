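"""Agroclimatic engine: vernalization model, pfrost, aggregation, catalogue,
variable clustering and PCA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eaakit import agroclim
from eaakit.agroclim import (SeasonSpec, aggregate, build_catalogue,
                             cluster_variables, composite_variable,
                             daily_vernalization, diurnal_sine, pca_env,
                             pfrost, vern_effectiveness, verna_nd)
from conftest import make_series


class TestVernEffectiveness:
    @pytest.mark.parametrize("temp,expected", [
        (0.0, 0.0), (4.0, 1.0), (8.0, 1.0), (15.0, 0.0),   # boundary points
        (2.0, 0.5), (11.5, 0.5),                            # ramp midpoints
        (-3.0, 0.0), (20.0, 0.0),                           # outside support
        (6.0, 1.0),
    ])
    def test_piecewise_linear_form(self, temp, expected):
        assert vern_effectiveness(temp) == pytest.approx(expected)

    @given(st.floats(-30, 45, allow_nan=False))
    @settings(max_examples=200, deadline=None)
    def test_bounded_and_continuous(self, temp):
        v = vern_effectiveness(temp)
        assert 0.0 <= v <= 1.0
        # continuity: small perturbations move the response by O(eps)
        assert abs(vern_effectiveness(temp + 1e-6) - v) < 1e-5


class TestDiurnalSine:
    def test_constant_day(self):
        assert np.allclose(diurnal_sine(5, 5, 24), 5.0)

    def test_attains_extremes_and_midpoint_mean(self):
        s = diurnal_sine(0, 10, 24)
        assert s.min() == pytest.approx(0.0)
        assert s.max() == pytest.approx(10.0)
        assert s.mean() == pytest.approx(5.0, abs=1e-9)

    def test_samples_bounded(self, rng):
        for _ in range(20):
            lo, hi = np.sort(rng.uniform(-10, 30, 2))
            s = diurnal_sine(lo, hi, 24)
            assert s.min() >= lo - 1e-9 and s.max() <= hi + 1e-9

    def test_inverted_range_errors(self):
        with pytest.raises(ValueError):
            diurnal_sine(10, 0)


class TestDailyVernalization:
    def test_degenerate_days(self):
        assert daily_vernalization(4, 4) == pytest.approx(1.0)
        assert daily_vernalization(20, 25) == pytest.approx(0.0)
        assert daily_vernalization(-10, -1) == pytest.approx(0.0)

    def test_matches_quadrature_oracle(self, rng):
        """The 24-step curve mean must agree with a 10,000-step numerical
        integration of the effectiveness over the sine curve within 1e-3."""
        h = np.arange(10_000) * (24.0 / 10_000)
        phase = np.sin(2 * np.pi * h / 24.0 - np.pi / 2.0)
        worst = 0.0
        for _ in range(100):
            lo, hi = np.sort(rng.uniform(-10, 25, 2))
            oracle = vern_effectiveness(
                (hi + lo) / 2 + (hi - lo) / 2 * phase).mean()
            worst = max(worst, abs(daily_vernalization(lo, hi) - oracle))
        assert worst < 1e-3


class TestVernaNd:
    def test_constant_four_degrees(self, constant_series):
        # 5 imbibition days + 10 fully effective days = day 15 since sowing
        assert verna_nd(constant_series, 10) == pytest.approx(15.0)

    def test_never_reached_is_nan(self):
        warm = make_series(n_years=2, tmin=25, tmax=25)
        with pytest.warns(UserWarning):
            assert np.isnan(verna_nd(warm, 10))

    def test_identical_years_average_equals_single(self):
        one = make_series(n_years=2, tmin=2, tmax=6)
        three = make_series(n_years=4, tmin=2, tmax=6)
        assert verna_nd(one, 20) == pytest.approx(verna_nd(three, 20))

    def test_nonstandard_target_warns(self, constant_series):
        with pytest.warns(UserWarning):
            verna_nd(constant_series, 15)


def _frost_series(last_frost_doy_by_year, n_years=30):
    """tmin = +5 except a single frost day per year at the given DOY."""
    dates = pd.date_range("1981-01-01", f"{1980 + n_years}-12-31", freq="D")
    tmin = np.full(len(dates), 5.0)
    doy = dates.dayofyear.to_numpy()
    year = dates.year.to_numpy()
    for i, y in enumerate(range(1981, 1981 + n_years)):
        d = last_frost_doy_by_year(i)
        if d is not None:
            tmin[(year == y) & (doy == d)] = -2.0
    return pd.DataFrame({"date": dates, "tmin": tmin, "tmax": tmin + 10,
                         "pcp": 0.0, "et0": 1.0})


class TestPfrost:
    def test_no_frost_returns_one(self):
        assert pfrost(_frost_series(lambda i: None)) == 1.0

    def test_every_year_last_frost_on_150(self):
        assert pfrost(_frost_series(lambda i: 150)) == 151.0

    def test_three_of_thirty_years_at_101(self):
        # 27 years end frost on DOY 100, 3 on DOY 101:
        # q(100) = 1 > 0.10 but q(101) = 3/30 = 0.10 -> first qualifying day
        assert pfrost(_frost_series(
            lambda i: 101 if i < 3 else 100)) == 101.0

    def test_matches_brute_force_definition(self, rng):
        """Return-period reading: min{d : (#years with frost on/after d)/n
        <= 0.10}, checked against exhaustive evaluation."""
        lasts = rng.integers(20, 170, size=30)
        series = _frost_series(lambda i: int(lasts[i]))
        n = 30
        brute = next(d for d in range(1, 183)
                     if (lasts >= d).sum() / n <= 0.10)
        assert pfrost(series) == float(brute)

    def test_monotone_under_added_late_frosts(self):
        early = _frost_series(lambda i: 60)
        later = _frost_series(lambda i: 60 if i else 140)
        assert pfrost(later) >= pfrost(early)

    def test_too_few_years_errors(self):
        with pytest.raises(ValueError):
            pfrost(_frost_series(lambda i: 100, n_years=5))


class TestAggregate:
    def test_constant_precip_january_sum(self):
        s = make_series(n_years=2, pcp=1.0)
        assert aggregate(s, "pcp", "jan") == pytest.approx(31.0)

    def test_frost_days_count(self):
        s = make_series(n_years=2, tmin=-1.0, tmax=5.0)
        assert aggregate(s, "frost", "jan") == pytest.approx(31.0)

    def test_water_balance_month(self):
        s = make_series(n_years=2, pcp=2.0, et0=1.0)
        # 30-day month: (2-1) * 30
        assert aggregate(s, "bal", "apr") == pytest.approx(30.0)

    def test_unknown_variable_errors(self, constant_series):
        with pytest.raises(ValueError):
            aggregate(constant_series, "wind", "jan")


@pytest.fixture(scope="module")
def catalogue(weather_two_sites):
    params, sites, weather = weather_two_sites
    series = {sid: g.drop(columns="site")
              for sid, g in weather.groupby("site", sort=False)}
    return build_catalogue(series, sites)


class TestCatalogue:
    def test_exactly_147_agroclimatic_variables(self, catalogue):
        assert len(catalogue.agroclimatic) == 147
        assert len(set(catalogue.agroclimatic)) == 147

    def test_pfrost_appears_once_annual_only(self, catalogue):
        assert [c for c in catalogue.agroclimatic
                if c.startswith("pfrost")] == ["pfrost"]

    def test_geo_columns_appended(self, catalogue):
        assert {"lon", "lat", "alt"} <= set(catalogue.data.columns)

    def test_analysis_subset_drops_summer_and_jul_oct(self, catalogue):
        sub = catalogue.analysis_subset()
        for col in sub.columns:
            assert not any(col.endswith(s)
                           for s in ("_jul", "_aug", "_sep", "_oct",
                                     "_summer"))

    def test_multi_month_composite_is_sum_of_months(self, catalogue):
        comp = composite_variable(catalogue.data, "pcp", ["mar", "apr"])
        expected = catalogue.data["pcp_mar"] + catalogue.data["pcp_apr"]
        assert np.allclose(comp, expected)

    def test_seasonal_balance_additive_over_months(self, catalogue):
        # win = DJF: bal_win == bal_dec + bal_jan + bal_feb
        d = catalogue.data
        assert np.allclose(d["bal_win"],
                           d["bal_dec"] + d["bal_jan"] + d["bal_feb"])

    def test_selected_preset_has_20_variables(self, catalogue):
        sel = catalogue.selected()
        assert sel.shape[1] == 20
        assert list(sel.columns) == agroclim.SELECTED_VARIABLES

    def test_no_nan_for_complete_series(self, catalogue):
        assert not catalogue.data[catalogue.agroclimatic].isna().any().any()


class TestClusterVariables:
    def test_duplicated_variable_shares_cluster(self, catalogue):
        df = catalogue.data[catalogue.agroclimatic[:30]].copy()
        df["twin"] = df[df.columns[0]]
        labels, _ = cluster_variables(df, k=5)
        assert labels[df.columns[0]] == labels["twin"]

    def test_k_equal_to_nvars_gives_singletons(self, rng):
        df = pd.DataFrame(rng.normal(size=(20, 6)),
                          columns=list("abcdef"))
        labels, _ = cluster_variables(df, k=6)
        assert labels.nunique() == 6

    def test_two_block_structure_recovered(self, rng):
        base1 = rng.normal(size=50)
        base2 = rng.normal(size=50)
        cols = {f"a{i}": base1 + 0.05 * rng.normal(size=50) for i in range(4)}
        cols |= {f"b{i}": base2 + 0.05 * rng.normal(size=50) for i in range(4)}
        labels, _ = cluster_variables(pd.DataFrame(cols), k=2)
        a_labels = {labels[f"a{i}"] for i in range(4)}
        b_labels = {labels[f"b{i}"] for i in range(4)}
        assert len(a_labels) == 1 and len(b_labels) == 1
        assert a_labels != b_labels

    def test_constant_variable_dropped_with_warning(self, rng):
        df = pd.DataFrame(rng.normal(size=(20, 5)), columns=list("abcde"))
        df["const"] = 1.0
        with pytest.warns(UserWarning):
            labels, _ = cluster_variables(df, k=3)
        assert "const" not in labels.index


class TestPcaEnv:
    def test_single_variable_explains_everything(self, rng):
        res = pca_env(pd.DataFrame({"x": rng.normal(size=10)}))
        assert res.variance_fraction[0] == pytest.approx(1.0)

    def test_perfectly_correlated_pair(self, rng):
        x = rng.normal(size=15)
        res = pca_env(pd.DataFrame({"x": x, "y": 3 * x + 1}))
        assert res.variance_fraction[0] == pytest.approx(1.0, abs=1e-12)
        assert len(res.variance_fraction) == 1  # rank truncation

    def test_reconstruction_identity(self, rng):
        df = pd.DataFrame(rng.normal(size=(10, 100)))
        res = pca_env(df)
        z = (df - df.mean()) / df.std(ddof=0)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        assert np.allclose(recon, z.to_numpy(), atol=1e-8)

    def test_variance_fractions_non_increasing(self, catalogue):
        res = pca_env(catalogue.analysis_subset())
        vf = res.variance_fraction
        assert np.all(np.diff(vf) <= 1e-12)
        assert vf.sum() <= 1.0 + 1e-9
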