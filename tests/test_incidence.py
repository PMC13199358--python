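import numpy as np
import pandas as pd
import pytest

import ductsim as d


@pytest.fixture(scope="module")
def observed():
    return d.load_table("japan_breast_2018")


@pytest.fixture(scope="module")
def lagged():
    return d.load_table("baseline_rates_lagged")


@pytest.fixture(scope="module")
def exposed_reference():
    return d.load_table("exposed_rates_0p1gy_age30")


class TestLagShift:
    def test_five_year_shift_reproduces_lagged_table(self, observed, lagged):
        shifted = d.lag_shift(observed, 5)
        pd.testing.assert_frame_equal(shifted.df, lagged.df, check_dtype=False)

    def test_zero_lag_is_identity(self, observed):
        pd.testing.assert_frame_equal(d.lag_shift(observed, 0).df, observed.df)

    def test_shift_preserves_rate_multiset(self, observed):
        shifted = d.lag_shift(observed, 10)
        assert sorted(shifted.rates) == sorted(observed.rates)

    def test_lag_must_match_group_width(self, observed):
        with pytest.raises(ValueError):
            d.lag_shift(observed, 3)


class TestBaselineHazard:
    @pytest.mark.parametrize(
        "age,expected",
        [(62, 255), (32, 98), (47, 266), (72, 207)],
    )
    def test_plateau_and_flank_values(self, age, expected):
        assert round(d.baseline_hazard(age)) == expected

    def test_vanishes_at_young_ages(self):
        assert d.baseline_hazard(1.0) < 1e-9
        assert d.baseline_hazard(10.0) < 0.1

    def test_rise_plateau_decline_shape(self):
        ages = np.arange(15, 90)
        lam = d.baseline_hazard(ages)
        peak = ages[np.argmax(lam)]
        assert 45 <= peak <= 62
        assert np.all(np.diff(lam[ages < 45]) > 0)
        assert np.all(np.diff(lam[ages > 65]) < 0)


class TestExcessRelativeRisk:
    def test_reference_scenario_value(self):
        # 0.1 Gy at age 47: R = 5.2 * 0.1 * 25 / 37 = 13/37
        assert d.excess_relative_risk(47, 0.1) == pytest.approx(13 / 37)

    def test_linear_in_dose_and_zero_without_dose(self):
        assert d.excess_relative_risk(50, 0.0) == 0.0
        assert d.excess_relative_risk(50, 0.2) == pytest.approx(
            2 * d.excess_relative_risk(50, 0.1)
        )

    def test_gated_before_exposure_plus_lag(self):
        assert d.excess_relative_risk(32, 0.1, exposure_age=30, lag=5) == 0.0
        assert d.excess_relative_risk(35, 0.1, exposure_age=30, lag=5) > 0.0

    def test_age_domain_guard(self):
        with pytest.raises(ValueError):
            d.excess_relative_risk(10, 0.1)


class TestExposedRates:
    def test_reproduces_reference_scenario_table(self, lagged, exposed_reference):
        out = d.exposed_rates(lagged, dose_gy=0.1, exposure_age=30, lag=5)
        np.testing.assert_array_equal(out.rates, exposed_reference.rates)
        np.testing.assert_array_equal(out.age_low, exposed_reference.age_low)

    def test_zero_dose_rounds_the_baseline_fit(self, lagged):
        out = d.exposed_rates(lagged, dose_gy=0.0, exposure_age=30)
        mids = out.age_low + 2
        for low, rate, mid in zip(out.age_low, out.rates, mids):
            if low >= 30:
                assert rate == round(d.baseline_hazard(mid))

    def test_groups_before_exposure_keep_observed_rates(self, lagged):
        out = d.exposed_rates(lagged, dose_gy=0.5, exposure_age=30)
        keep = lagged.age_low < 30
        np.testing.assert_array_equal(out.rates[keep], lagged.rates[keep])


class TestModelToIncidence:
    def test_no_cancer_probability_gives_zero_rates(self):
        out = d.model_to_incidence(np.zeros(600), 1000, [(20, 25), (25, 30)])
        assert np.all(out.rates == 0)

    def test_single_cell_step_inside_one_group(self):
        """N=1 tissue whose cell turns cancerous at age 38 with probability q:
        diagnoses fall at 43, i.e. entirely in the 40-45 group."""
        q = 0.25
        prob = np.zeros(12 * 60 + 1)
        prob[38 * 12:] = q
        out = d.model_to_incidence(prob, 1, [(35, 40), (40, 45), (45, 50)], lag=5)
        assert out.rates[0] == 0.0
        assert out.rates[1] == pytest.approx(1e5 * q / 5)
        assert out.rates[2] == 0.0

    def test_small_hazard_first_order_limit(self):
        """Constant per-cell hazard r: early group rates ~ 100000 * N * r * 12
        per year (before saturation)."""
        r = 1e-11  # small enough that saturation of F is negligible
        n = 100_000
        t = np.arange(12 * 40 + 1)
        prob = 1.0 - (1.0 - r) ** t
        out = d.model_to_incidence(prob, n, [(20, 25)], lag=5)
        assert out.rates[0] == pytest.approx(1e5 * n * r * 12, rel=0.005)

    def test_monotone_in_probability_and_tissue_size(self):
        t = np.arange(12 * 50 + 1)
        groups = [(20, 25), (25, 30)]
        lo = d.model_to_incidence(1 - (1 - 1e-9) ** t, 1000, groups)
        hi_p = d.model_to_incidence(1 - (1 - 2e-9) ** t, 1000, groups)
        hi_n = d.model_to_incidence(1 - (1 - 1e-9) ** t, 2000, groups)
        assert np.all(hi_p.rates >= lo.rates)
        assert np.all(hi_n.rates >= lo.rates)

    def test_decreasing_probability_rejected(self):
        with pytest.raises(ValueError):
            d.model_to_incidence([0.0, 0.2, 0.1], 10, [(20, 25)])


class TestIncidenceTable:
    def test_round_trip_csv(self, tmp_path, observed):
        path = tmp_path / "t.csv"
        observed.to_csv(path)
        again = d.IncidenceTable.read_csv(path)
        pd.testing.assert_frame_equal(again.df, observed.df)

    def test_open_final_group_spans_five_years(self, lagged):
        assert lagged.bounds()[-1] == (85, 90)

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            d.IncidenceTable.from_records([(20, 24, -1.0)])
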