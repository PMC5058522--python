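import numpy as np
import pandas as pd
import pytest

from udshift.grids import GridSpec, Raster
from udshift.trends import (home_range_disturbed_fraction, lmm_trend,
                            metric_trends, ols_trend, overlap_trends,
                            remove_hr_outlier, extract_use_metrics, vif_screen)
from udshift.ud import HomeRange

from conftest import make_track


class TestHomeRangeDisturbedFraction:
    def _hr(self, grid, mask):
        return HomeRange(grid, mask, 0.95, {})

    def test_trivial_cases(self):
        g = GridSpec(0, 0, 250.0, 4, 4)
        mask = np.zeros((4, 4), bool)
        mask[:2] = True
        zero = Raster(g, np.zeros((4, 4)), "proportion")
        full = Raster(g, np.ones((4, 4)), "proportion")
        assert home_range_disturbed_fraction(self._hr(g, mask), zero) == 0.0
        assert home_range_disturbed_fraction(self._hr(g, mask), full) == 1.0

    def test_half_and_half(self):
        g = GridSpec(0, 0, 250.0, 4, 4)
        mask = np.zeros((4, 4), bool)
        mask[0] = True  # 4 member cells
        vals = np.zeros((4, 4))
        vals[0, :2] = 1.0
        dist = Raster(g, vals, "proportion")
        assert home_range_disturbed_fraction(self._hr(g, mask), dist) == 0.5

    def test_empty_home_range_rejected(self):
        g = GridSpec(0, 0, 250.0, 4, 4)
        dist = Raster(g, np.zeros((4, 4)), "proportion")
        with pytest.raises(ValueError, match="empty"):
            home_range_disturbed_fraction(self._hr(g, np.zeros((4, 4), bool)), dist)


class TestExtractUseMetrics:
    def test_hand_placed_fixes(self):
        g = GridSpec(0, 0, 100.0, 10, 10)
        elev = Raster(g, np.full((10, 10), 1500.0))
        lc = np.full((10, 10), 1.0)      # conifer
        lc[:, 5:] = 2.0                  # nonforest on the east half
        landcover = Raster(g, lc)
        # 6 fixes west (conifer), 4 fixes east (nonforest)
        xy = [(50, 50)] * 6 + [(850, 850)] * 4
        tr = make_track(xy, pd.date_range("2000-01-01", periods=10, freq="h",
                                          tz="UTC"))
        m = extract_use_metrics(tr, elev, landcover)
        assert m["elevation"] == 1500.0
        assert m["prop_conifer"] == pytest.approx(0.6)
        assert m["prop_nonforest"] == pytest.approx(0.4)

    def test_too_many_off_raster_fixes_rejected(self):
        g = GridSpec(0, 0, 100.0, 10, 10)
        elev = Raster(g, np.zeros((10, 10)))
        lc = Raster(g, np.ones((10, 10)))
        xy = [(50, 50)] * 5 + [(-500, -500)] * 5
        tr = make_track(xy, pd.date_range("2000-01-01", periods=10, freq="h",
                                          tz="UTC"))
        with pytest.raises(ValueError, match="outside"):
            extract_use_metrics(tr, elev, lc)


class TestOutlierRule:
    @pytest.mark.parametrize("sizes,expect_removed", [
        ([10.0, 12.0, 30.0], [30.0]),
        ([10.0, 12.0, 20.0], []),
        ([10.0, 12.0, 30.0, 100.0], [100.0, 30.0]),
    ])
    def test_double_the_rest_rule_iterated(self, sizes, expect_removed):
        df = pd.DataFrame({"home_range_km2": sizes})
        out, removed = remove_hr_outlier(df)
        assert removed == expect_removed
        assert sorted(out["home_range_km2"]) == sorted(set(sizes) - set(expect_removed))

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            remove_hr_outlier(pd.DataFrame({"home_range_km2": [1.0, 2.0]}))


class TestVifScreen:
    def test_orthogonal_predictors_vif_one(self):
        df = pd.DataFrame({"a": [1, -1, 1, -1.0], "b": [1, 1, -1, -1.0]})
        out = vif_screen(df)
        assert out["vif"].iloc[0] == pytest.approx(1.0)
        assert out["passed"].all()

    def test_r_056_passes_below_three(self, rng):
        # correlation 0.56 -> VIF = 1/(1-0.3136) ~ 1.46
        n = 4000
        x = rng.standard_normal(n)
        y = 0.56 * x + np.sqrt(1 - 0.56**2) * rng.standard_normal(n)
        out = vif_screen(pd.DataFrame({"year": x, "npi": y}))
        assert out["vif"].iloc[0] == pytest.approx(1 / (1 - 0.56**2), rel=0.1)
        assert out["passed"].all()

    def test_r_09_fails(self):
        x = np.linspace(0, 1, 50)
        y = 0.9 * x + np.sqrt(1 - 0.81) * np.sin(np.arange(50) * 2.4)
        r = np.corrcoef(x, y)[0, 1]
        out = vif_screen(pd.DataFrame({"a": x, "b": y}))
        assert out["vif"].iloc[0] == pytest.approx(1 / (1 - r**2), rel=1e-9)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            vif_screen(pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]}))


def normal_equation_fit(X, y):
    """Independent closed-form (X'X)^-1 X'y with classical SEs."""
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    sigma2 = resid @ resid / df
    se = np.sqrt(np.diag(sigma2 * XtX_inv))
    return beta, se


class TestOlsTrend:
    def test_perfect_line_slope_one_se_zero(self):
        df = pd.DataFrame({"year": np.arange(10.0)})
        df["value"] = df["year"]
        res = ols_trend(df, "value", ("year",))
        assert res.term("year")["beta"] == pytest.approx(1.0, abs=1e-12)
        assert res.term("year")["se"] == pytest.approx(0.0, abs=1e-10)
        assert bool(res.term("year")["supported"])

    def test_constant_response_unsupported(self):
        df = pd.DataFrame({"year": np.arange(8.0), "value": 2.5})
        res = ols_trend(df, "value", ("year",))
        assert res.term("year")["beta"] == pytest.approx(0.0, abs=1e-12)
        assert not bool(res.term("year")["supported"])

    def test_matches_normal_equation_oracle(self, rng):
        n = 12
        df = pd.DataFrame({"year": np.arange(n, dtype=float),
                           "npi": rng.standard_normal(n)})
        df["value"] = 0.3 * df["year"] - 0.8 * df["npi"] + rng.standard_normal(n)
        res = ols_trend(df, "value", ("year", "npi"))
        X = np.column_stack([np.ones(n), df["year"], df["npi"]])
        beta, se = normal_equation_fit(X, df["value"].to_numpy())
        assert res.term("year")["beta"] == pytest.approx(beta[1], abs=1e-10)
        assert res.term("npi")["beta"] == pytest.approx(beta[2], abs=1e-10)
        assert res.term("year")["se"] == pytest.approx(se[1], abs=1e-10)

    def test_rank_deficient_design_rejected(self):
        df = pd.DataFrame({"year": np.arange(8.0)})
        df["npi"] = 2.0 * df["year"]
        df["value"] = df["year"]
        with pytest.raises(ValueError, match="collinear"):
            ols_trend(df, "value", ("year", "npi"))

    def test_wald_ci_option(self):
        df = pd.DataFrame({"year": np.arange(8.0)})
        df["value"] = df["year"] * 0.5 + np.sin(np.arange(8.0))
        res = ols_trend(df, "value", ("year",), ci="wald")
        t = res.term("year")
        assert t["ci_low"] == pytest.approx(t["beta"] - 1.96 * t["se"])


class TestLmmTrend:
    def _panel(self, rng, n_ind=20, n_year=8, slope=0.5, re_sd=0.0):
        years = np.tile(np.arange(n_year, dtype=float), n_ind)
        ids = np.repeat([f"a{i}" for i in range(n_ind)], n_year)
        intercepts = np.repeat(rng.normal(0.0, re_sd, n_ind), n_year)
        y = 1.0 + slope * years + intercepts + rng.normal(0, 1.0, n_ind * n_year)
        return pd.DataFrame({"animal_id": ids, "year": years, "value": y})

    def test_zero_between_individual_variance_matches_ols(self, rng):
        df = self._panel(rng, re_sd=0.0)
        lmm = lmm_trend(df, "value", ("year",))
        ols = ols_trend(df, "value", ("year",))
        assert lmm.term("year")["beta"] == pytest.approx(
            ols.term("year")["beta"], abs=1e-6)
        assert lmm.random_effect_var == pytest.approx(0.0, abs=0.05)

    def test_known_slope_and_variance_recovered(self):
        df = self._panel(np.random.default_rng(7), n_ind=50, slope=0.5, re_sd=1.0)
        res = lmm_trend(df, "value", ("year",))
        t = res.term("year")
        assert abs(t["beta"] - 0.5) < 2 * t["se"]
        assert 0.5 < res.random_effect_var < 1.5  # true variance 1.0
        assert res.flags["converged"]

    def test_single_individual_rejected(self, rng):
        df = self._panel(rng, n_ind=1)
        with pytest.raises(ValueError, match="2 individuals"):
            lmm_trend(df, "value", ("year",))


class TestTidyTables:
    def test_overlap_trends_one_model_per_stratum(self, rng):
        years = np.arange(2006, 2014)
        climate = pd.Series(rng.standard_normal(len(years)), index=years)
        rows = []
        for herd in ("A", "B"):
            for idx, tgt in (("PHR", "alpine"), ("UDOI", "baseline")):
                for y in years:
                    rows.append({"herd": herd, "season": "winter", "year": y,
                                 "index": idx, "target": tgt,
                                 "value": rng.random()})
        tab = overlap_trends(pd.DataFrame(rows), climate)
        # 2 herds x 2 (index,target) x 3 terms (const, year, npi)
        assert len(tab) == 12
        assert set(tab["term"]) == {"const", "year", "npi"}

    def test_metric_trends_produces_coefficients(self, rng):
        n_ind, n_year = 12, 6
        ids = np.repeat([f"a{i}" for i in range(n_ind)], n_year)
        years = np.tile(np.arange(2000, 2000 + n_year, dtype=float), n_ind)
        df = pd.DataFrame({
            "animal_id": ids, "herd": "A", "season": "winter", "year": years,
            "npi": rng.standard_normal(n_ind * n_year),
            "prop_disturbed": rng.random(n_ind * n_year),
            "movement_rate": rng.random(n_ind * n_year) + 1,
            "home_range_km2": rng.random(n_ind * n_year) * 100 + 50,
            "elevation": rng.normal(1500, 100, n_ind * n_year),
            "prop_conifer": rng.random(n_ind * n_year),
            "prop_nonforest": rng.random(n_ind * n_year),
        })
        tab = metric_trends(df)
        assert {"movement_rate", "home_range_km2", "elevation"} <= set(tab["response"])
        assert (tab.loc[tab["term"] == "year", "se"] > 0).all()
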