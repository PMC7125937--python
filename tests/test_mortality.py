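"""Baseline rates, attributable deaths, projection, aggregation, evaluation."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

import heatmort as hm
from heatmort._calendar import DAYS_PER_YEAR, MONTH_LENGTHS, month_of_doy
from heatmort.errors import AlignmentError, MaskError

# Printed evaluation columns for the ten benchmark cities
# (annual-average heat deaths, generalized vs observed curves)
TABLE_GENERALIZED = [83, 149, 290, 86, 32, 61, 32, 507, 92, 114]
TABLE_OBSERVED = [105, 83, 503, 17, 35, 182, 43, 368, 46, 177]


def _temps_da(values, years):
    """(n_years*365, n_lat, n_lon) values -> DataArray with coords."""
    values = np.asarray(values, dtype=float)
    n_years = len(years)
    year = np.repeat(years, DAYS_PER_YEAR).astype("int32")
    doy = np.tile(np.arange(1, DAYS_PER_YEAR + 1), n_years).astype("int32")
    return xr.DataArray(
        values,
        dims=("time", "lat", "lon"),
        coords={"time": np.arange(values.shape[0]),
                "year": ("time", year), "doy": ("time", doy)},
    )


class TestBaselineRate:
    def test_uniform_shares_give_constant_daily_rate(self):
        bm = hm.BaselineMortality.uniform(0.0087)
        rates = [hm.daily_baseline_rate(bm, d) for d in (1, 100, 250, 365)]
        np.testing.assert_allclose(rates, 0.0087 / 365, rtol=1e-12)

    def test_daily_rates_sum_to_annual_rate(self, baseline_mortality):
        profile = hm.daily_rate_profile(baseline_mortality)
        assert profile.sum() == pytest.approx(
            baseline_mortality.annual_rate, abs=1e-12
        )
        assert profile.shape == (365,)

    def test_january_hand_value(self):
        shares = np.full(12, 0.9 / 11)
        shares[0] = 0.10
        bm = hm.BaselineMortality(0.0087, shares / shares.sum())
        # Jan 15: annual_rate x january share / 31 days
        assert hm.daily_baseline_rate(bm, 15) == pytest.approx(
            0.0087 * shares[0] / 31, rel=1e-9
        )

    def test_invalid_shares_rejected(self):
        with pytest.raises(ValueError):
            hm.BaselineMortality(0.008, np.full(12, 0.1))


class TestAttributableDeaths:
    def test_no_excess_risk_no_deaths(self):
        assert hm.attributable_deaths(1e6, 2e-5, np.ones(10)).sum() == 0.0

    def test_direct_arithmetic(self):
        assert hm.attributable_deaths(1_000_000, 2.5e-5, 1.2) == pytest.approx(5.0)

    def test_conventional_af_variant(self):
        got = hm.attributable_deaths(1e6, 2.5e-5, 1.2, "rr_minus_1_over_rr")
        assert got == pytest.approx(1e6 * 2.5e-5 * 0.2 / 1.2)

    def test_grid_totals_match_triple_loop_oracle(self):
        rng = np.random.default_rng(4)
        pop = rng.integers(0, 1000, size=(3, 4)).astype(float)
        rate = rng.uniform(1e-5, 3e-5, size=20)
        rr = 1 + rng.uniform(0, 0.5, size=(20, 3, 4))
        got = hm.attributable_deaths(pop[None], rate[:, None, None], rr).sum()
        expected = 0.0
        for t in range(20):
            for i in range(3):
                for j in range(4):
                    expected += pop[i, j] * rate[t] * (rr[t, i, j] - 1)
        assert got == pytest.approx(expected, rel=1e-9)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            hm.attributable_deaths(-1.0, 1e-5, 1.1)


class TestProjection:
    def test_all_days_below_ot_give_zero(self, published_params, baseline_mortality):
        temps = _temps_da(np.full((730, 2, 2), 10.0), [2010, 2011])
        exposure = hm.ExposureFields(
            ot=np.full((2, 2), 25.0), smt=np.full((2, 2), 24.0), period=(2010, 2011)
        )
        res = hm.project_scenario(
            temps, np.full((2, 2), 1e5), baseline_mortality, exposure, published_params
        )
        assert res.national_annual_mean == 0.0
        assert (res.deaths_cell_year == 0).all()

    def test_identical_years_make_decadal_mean_equal_single_year(
        self, published_params, baseline_mortality
    ):
        one_year = 24.0 + 8 * np.cos(
            2 * np.pi * (np.arange(1, 366) - 196) / 365
        )
        vals = np.tile(one_year, 3)[:, None, None] * np.ones((1, 2, 2))
        temps = _temps_da(vals, [2010, 2011, 2012])
        exposure = hm.ExposureFields(
            ot=np.full((2, 2), 28.0), smt=np.full((2, 2), 24.0), period=(2010, 2012)
        )
        res = hm.project_scenario(
            temps, np.full((2, 2), 1e5), baseline_mortality, exposure, published_params
        )
        assert res.national_annual_mean > 0
        np.testing.assert_allclose(
            res.national_by_year, res.national_by_year[0], rtol=1e-12
        )

    def test_three_cell_two_year_manual_accumulation(
        self, published_params, baseline_mortality
    ):
        rng = np.random.default_rng(8)
        vals = rng.uniform(15, 35, size=(730, 1, 3))
        temps = _temps_da(vals, [2010, 2011])
        pop = np.array([[1000.0, 5000.0, 250.0]])
        ot = np.array([[26.0, 28.0, 24.0]])
        smt = np.array([[22.0, 27.0, 25.0]])
        exposure = hm.ExposureFields(ot=ot, smt=smt, period=(2010, 2011))
        res = hm.project_scenario(
            temps, pop, baseline_mortality, exposure, published_params
        )
        # spreadsheet-style accumulation, one cell-day at a time
        expected = 0.0
        for t in range(730):
            doy = t % 365 + 1
            rate = hm.daily_baseline_rate(baseline_mortality, doy)
            for j in range(3):
                rr = hm.relative_risk(
                    vals[t, 0, j], ot[0, j], smt[0, j], published_params
                )
                expected += pop[0, j] * rate * (rr - 1)
        assert res.deaths_cell_year.sum() == pytest.approx(expected, rel=1e-9)

    def test_population_doubling_doubles_deaths(self, published_params, baseline_mortality):
        spec = hm.default_climate_spec(3, 3, [2010, 2011], seed=6)
        temps = hm.gen_temperature_grid(spec)
        exposure = hm.derive_exposure(temps, (2010, 2011))
        pop = hm.gen_population_grid(3, 3, 100000, seed=1).astype(float)
        r1 = hm.project_scenario(temps, pop, baseline_mortality, exposure, published_params)
        r2 = hm.project_scenario(
            temps, 2 * pop, baseline_mortality, exposure, published_params
        )
        np.testing.assert_allclose(
            r2.deaths_cell_year, 2 * r1.deaths_cell_year, rtol=1e-12
        )
        # pop_scale behaves identically
        r3 = hm.project_scenario(
            temps, pop, baseline_mortality, exposure, published_params, pop_scale=2.0
        )
        np.testing.assert_allclose(
            r3.deaths_cell_year, 2 * r1.deaths_cell_year, rtol=1e-12
        )

    def test_grid_mismatch_names_dimension(self, published_params, baseline_mortality):
        temps = _temps_da(np.full((365, 2, 2), 30.0), [2010])
        exposure = hm.ExposureFields(
            ot=np.full((2, 2), 25.0), smt=np.full((2, 2), 24.0), period=(2010, 2010)
        )
        with pytest.raises(AlignmentError, match="lat"):
            hm.project_scenario(
                temps, np.ones((3, 2)), baseline_mortality, exposure, published_params
            )


class TestAggregation:
    def _result(self, published_params, baseline_mortality):
        spec = hm.default_climate_spec(4, 4, [2010, 2011], seed=13)
        temps = hm.gen_temperature_grid(spec)
        exposure = hm.derive_exposure(temps, (2010, 2011))
        pop = hm.gen_population_grid(4, 4, 400000, seed=2).astype(float)
        res = hm.project_scenario(
            temps, pop, baseline_mortality, exposure, published_params
        )
        return res, pop

    def test_single_state_rate_is_national_rate(self, published_params, baseline_mortality):
        res, pop = self._result(published_params, baseline_mortality)
        res = hm.aggregate_regions(res, pop, np.zeros((4, 4), dtype=int))
        national_rate = res.national_annual_mean / pop.sum() * 1e6
        assert res.per_capita_by_state[0] == pytest.approx(national_rate, rel=1e-12)

    def test_two_state_split_matches_hand_computation(
        self, published_params, baseline_mortality
    ):
        res, pop = self._result(published_params, baseline_mortality)
        mask = np.zeros((4, 4), dtype=int)
        mask[2:] = 1
        res = hm.aggregate_regions(res, pop, mask, city_boxes={"empty": []})
        annual = res.deaths_cell_year.mean(axis=0)
        for s, sel in ((0, mask == 0), (1, mask == 1)):
            assert res.per_capita_by_state[s] == pytest.approx(
                annual[sel].sum() / pop[sel].sum() * 1e6, rel=1e-12
            )
        assert res.city_box_totals["empty"] == 0.0
        # additivity: states partition the national total
        state_total = sum(
            annual[mask == s].sum() for s in (0, 1)
        )
        assert state_total == pytest.approx(res.national_annual_mean, rel=1e-12)

    def test_populated_cell_without_state_raises(self, published_params, baseline_mortality):
        res, pop = self._result(published_params, baseline_mortality)
        mask = np.zeros((4, 4), dtype=int)
        mask[0, 0] = -1
        with pytest.raises(MaskError):
            hm.aggregate_regions(res, pop, mask)


class TestEvaluation:
    def test_observed_lookup_interpolates_clamps_and_counts(self):
        curve = hm.gen_city_erf(hm.SyntheticCitySpec(smt_true=25.7, t_range=5.0))
        counters = hm.RunCounters()
        t = np.array([curve.ot - 5.0, curve.ot + 1.0, curve.ot + 99.0])
        rr = hm.observed_relative_risk(curve, t, counters)
        assert rr[0] == 1.0  # cold side
        assert rr[2] == max(curve.rr[-1], 1.0)  # flat extrapolation
        assert counters.erf_lookup_above_range == 1

    def test_self_consistent_params_give_zero_error_rows(
        self, published_params, baseline_mortality
    ):
        """When the observed curve IS the generalized quadratic and daily
        temperatures sit on the 0.1 degC sample grid, both routes agree."""
        curve = hm.gen_city_erf(
            hm.SyntheticCitySpec(smt_true=28.0, t_range=8.0)
        )
        doy = np.arange(1, 366)
        temps = np.full(365, curve.ot - 5.0)
        temps[180:220] = curve.ot + np.round(np.linspace(0, 6, 40), 1)
        cs = hm.CitySeries(curve=curve, temps=temps, doy=doy, population=1e6)
        frame = hm.evaluation_report([cs], published_params, baseline_mortality)
        assert frame.loc[curve.city_id, "abs_error"] == pytest.approx(0.0, abs=1e-9)
        assert frame.loc["Total", "rel_error_pct"] == 0

    def test_totals_row_arithmetic_on_printed_columns(self):
        tot = hm.totals_row(TABLE_GENERALIZED, TABLE_OBSERVED)
        assert tot["generalized"] == 1446
        assert tot["observed"] == 1559
        assert tot["abs_error"] == -113
        assert tot["rel_error_pct"] == -7

    def test_single_city_absolute_error(self):
        # second city of the printed table: 149 generalized vs 83 observed
        assert TABLE_GENERALIZED[1] - TABLE_OBSERVED[1] == 66
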