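import numpy as np
import pytest
from hypothesis import given, strategies as st

from catex import che_core as cc
from catex.io_model import MONEY_COLUMNS, PeriodError, SurveyDataset, MoneyConvention

from brute_force import bf_decompose
from conftest import annual_dataset, random_survey_frame


class TestEquivalizedSize:
    @pytest.mark.parametrize("size,beta,expected", [
        (1, 0.56, 1.0),
        (4, 1.0, 4.0),
        (4, 0.56, 4 ** 0.56),
    ])
    def test_values(self, size, beta, expected):
        assert cc.equivalized_size(size, beta) == pytest.approx(expected)

    @pytest.mark.parametrize("beta", [0.0, -0.2, 1.5])
    def test_invalid_beta(self, beta):
        with pytest.raises(ValueError):
            cc.equivalized_size(3, beta)

    @given(st.integers(1, 40))
    def test_concave_increments_for_beta_below_one(self, n):
        beta = 0.56
        d1 = cc.equivalized_size(n + 1, beta) - cc.equivalized_size(n, beta)
        d2 = cc.equivalized_size(n + 2, beta) - cc.equivalized_size(n + 1, beta)
        assert d2 < d1


class TestFoodShare:
    def test_values(self):
        assert cc.food_share(2400.0, 4800.0) == 0.5
        assert cc.food_share(0.0, 100.0) == 0.0
        assert cc.food_share(100.0, 100.0) == 1.0

    def test_zero_total_is_nan(self):
        assert np.isnan(cc.food_share(0.0, 0.0))


def _tiny_frame(rows):
    """Annual-period dataset from (total, food, size[, oop]) tuples."""
    n = len(rows)
    frame = random_survey_frame(np.random.default_rng(0), n)
    frame["expenditure_total"] = [r[0] for r in rows]
    frame["expenditure_food"] = [r[1] for r in rows]
    frame["household_size"] = [r[2] for r in rows]
    for c in ["oop_consultation", "oop_hospitalization", "oop_medicines",
              "oop_diagnostics", "oop_transport"]:
        frame[c] = 0.0
    if len(rows[0]) > 3:
        frame["oop_medicines"] = [r[3] for r in rows]
    return SurveyDataset(frame, MoneyConvention("MXN", 20.48, "annual"))


class TestPovertyLine:
    def test_crafted_window_mean(self):
        # distinct food shares 0.1..0.9; with n=10 the nearest-rank 45th/55th
        # percentiles are the 5th and 6th order statistics (shares 0.45, 0.5),
        # whose households have per-equivalent-adult food spending 1000, 1400
        shares = [0.1, 0.2, 0.3, 0.4, 0.45, 0.5, 0.6, 0.7, 0.8, 0.9]
        rows = []
        for s in shares:
            if s == 0.45:
                rows.append((1000.0 / s, 1000.0, 1))
            elif s == 0.5:
                rows.append((1400.0 / s, 1400.0, 1))
            else:
                rows.append((10000.0, 10000.0 * s, 1))
        pl = cc.poverty_line(_tiny_frame(rows))
        assert pl.value_per_eq_adult == pytest.approx(1200.0)
        assert pl.n_reference == 2

    def test_identical_households(self):
        ds = _tiny_frame([(8000.0, 3000.0, 4)] * 7)
        pl = cc.poverty_line(ds, beta=0.56)
        assert pl.value_per_eq_adult == pytest.approx(3000.0 / 4 ** 0.56)
        assert pl.n_reference == 7

    def test_single_household_is_its_own_window(self):
        ds = _tiny_frame([(5000.0, 2000.0, 3)])
        pl = cc.poverty_line(ds, beta=0.56)
        assert pl.value_per_eq_adult == pytest.approx(2000.0 / 3 ** 0.56)
        assert pl.n_reference == 1

    def test_all_zero_food_is_degenerate(self):
        ds = _tiny_frame([(5000.0, 0.0, 2)] * 4)
        with pytest.raises(cc.DegenerateLineError):
            cc.poverty_line(ds)

    def test_requires_annual_period(self, rng):
        ds = SurveyDataset(random_survey_frame(rng, 5),
                           MoneyConvention("MXN", 20.48, "monthly"))
        with pytest.raises(PeriodError):
            cc.poverty_line(ds)

    def test_weight_column_used_when_given(self):
        ds = _tiny_frame([(1000.0, 500.0, 1), (1000.0, 500.0, 1)])
        ds.frame["expenditure_food"] = [400.0, 600.0]
        ds.frame["w"] = [3.0, 1.0]
        pl = cc.poverty_line(ds, window=(0, 100), weight_col="w")
        assert pl.value_per_eq_adult == pytest.approx(
            (3 * 400 + 600) / 4)


class TestSubsistenceAndCapacity:
    def test_subsistence_composition(self):
        pl = cc.PovertyLine(1200.0, 45, 55, 3)
        assert cc.subsistence_expenditure(1, pl, 0.56) == pytest.approx(1200)
        assert cc.subsistence_expenditure(4, pl, 1.0) == pytest.approx(4800)
        assert cc.subsistence_expenditure(4, pl, 0.56) == pytest.approx(
            1200 * 4 ** 0.56)

    def test_capacity_direct_and_substituted(self):
        assert cc.capacity_to_pay(5000.0, 1000.0, 1200.0) == (3800.0, False)
        # very poor household: THE − SE < 0, poverty line replaced by food
        assert cc.capacity_to_pay(1000.0, 600.0, 1500.0) == (400.0, True)
        assert cc.capacity_to_pay(1000.0, 600.0, 1000.0) == (0.0, False)

    def test_food_above_total_is_integrity_error(self):
        with pytest.raises(ValueError):
            cc.capacity_to_pay(400.0, 500.0, 100.0)


class TestCheFlag:
    @pytest.mark.parametrize("oop,pc,z,expected", [
        (30.0, 100.0, 0.30, 1),     # closed boundary: ratio == threshold
        (29.999, 100.0, 0.30, 0),
        (0.0, 50.0, 0.10, 0),
        (5.0, 0.0, 0.30, 1),        # positive OOP against zero capacity
        (0.0, 0.0, 0.30, 0),
    ])
    def test_values(self, oop, pc, z, expected):
        assert cc.che_flag(oop, pc, z) == expected

    @pytest.mark.parametrize("z", [0.0, 1.0, -0.1])
    def test_invalid_threshold(self, z):
        with pytest.raises(ValueError):
            cc.che_flag(1.0, 1.0, z)


class TestIncidence:
    def test_exact_ratio_and_bounds(self):
        flags = [1] * 135 + [0] * 252  # 135 of 387
        res = cc.che_incidence(flags, 0.30)
        assert res.incidence_pct == pytest.approx(100 * 135 / 387)
        assert res.n_che == 135 and res.n_households == 387
        assert res.ci95[0] < res.incidence_pct < res.ci95[1]

    def test_extremes(self):
        assert cc.che_incidence([0, 0, 0], 0.3).incidence_pct == 0.0
        assert cc.che_incidence([1, 1], 0.3).incidence_pct == 100.0

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            cc.che_incidence([], 0.3)


class TestSensitivity:
    def test_four_thresholds_monotone(self, rng):
        ds = annual_dataset(random_survey_frame(rng, 60))
        table = cc.sensitivity_analysis(ds)
        assert len(table) == 4
        assert (np.diff(table["incidence_pct"]) <= 0).all()

    def test_single_threshold_matches_direct_incidence(self, rng):
        ds = annual_dataset(random_survey_frame(rng, 40))
        table = cc.sensitivity_analysis(ds, thresholds=[0.30])
        _, dec = cc.decompose(ds, thresholds=[0.30])
        direct = cc.che_incidence(dec["flag_30"].to_numpy(), 0.30)
        assert len(table) == 1
        assert table.iloc[0]["incidence_pct"] == direct.incidence_pct

    def test_zero_oop_gives_zero_incidence(self, rng):
        frame = random_survey_frame(rng, 25)
        for c in ["oop_consultation", "oop_hospitalization", "oop_medicines",
                  "oop_diagnostics", "oop_transport"]:
            frame[c] = 0.0
        table = cc.sensitivity_analysis(annual_dataset(frame))
        assert (table["incidence_pct"] == 0).all()

    def test_unsorted_thresholds_rejected(self, rng):
        ds = annual_dataset(random_survey_frame(rng, 10))
        with pytest.raises(ValueError):
            cc.sensitivity_analysis(ds, thresholds=[0.3, 0.1])


class TestOracleAndInvariants:
    def test_matches_brute_force_on_random_data(self, rng):
        for _ in range(25):
            n = int(rng.integers(1, 50))
            ds = annual_dataset(random_survey_frame(rng, n))
            pl, dec = cc.decompose(ds)
            bf_pl, bf_nref, bf_rows = bf_decompose(
                ds.frame, cc.DEFAULT_BETA, cc.DEFAULT_WINDOW,
                cc.DEFAULT_THRESHOLDS)
            assert pl.value_per_eq_adult == pytest.approx(bf_pl, rel=1e-12)
            assert pl.n_reference == bf_nref
            for i, row in enumerate(bf_rows):
                assert dec.loc[i, "pc_h"] == pytest.approx(row["pc"], rel=1e-12)
                assert bool(dec.loc[i, "substitution_applied"]) == row["substituted"]
                for z in cc.DEFAULT_THRESHOLDS:
                    assert dec.loc[i, f"flag_{int(z*100)}"] == row["flags"][z]

    def test_scale_invariance_of_flags(self, rng):
        ds = annual_dataset(random_survey_frame(rng, 50))
        _, base = cc.decompose(ds)
        for c in (1e-3, 0.7, 13.0, 1e4):
            scaled = ds.frame.copy()
            scaled[MONEY_COLUMNS] = scaled[MONEY_COLUMNS] * c
            _, dec = cc.decompose(SurveyDataset(
                scaled, MoneyConvention("MXN", 20.48, "annual")))
            for z in cc.DEFAULT_THRESHOLDS:
                col = f"flag_{int(z*100)}"
                assert (dec[col] == base[col]).all()

    def test_substitution_guarantees_positive_capacity(self, rng):
        # engineered so many households sit below subsistence
        frame = random_survey_frame(rng, 80)
        frame.loc[:30, "expenditure_total"] = rng.uniform(100, 400, 31)
        frame.loc[:30, "expenditure_food"] = (
            frame.loc[:30, "expenditure_total"] * 0.8)
        frame.loc[:30, "household_size"] = 8
        ds = annual_dataset(frame)
        _, dec = cc.decompose(ds)
        strictly_poorer = dec["the_h"] > dec["food_h"]
        assert (dec.loc[strictly_poorer, "pc_h"] > 0).all()
        assert (dec["substitution_applied"] ==
                (dec["the_h"] - dec["se_h"] < 0)).all()
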