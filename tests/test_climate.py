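"""Extraterrestrial radiation, Hargreaves PET, and water-balance aggregates."""

import numpy as np
import pandas as pd
import pytest

from dendrosem.climate import (
    extraterrestrial_radiation,
    hargreaves_pet,
    seasonal_mean,
    water_balance,
    water_year_total,
    zscore,
)


def _ra_oracle(lat_deg, doy):
    """Independently coded FAO-56 Ra (MJ m-2 day-1 -> mm/day) for cross-checks."""
    import math

    phi = math.radians(lat_deg)
    delta = 0.409 * math.sin(2 * math.pi / 365 * doy - 1.39)
    dr = 1 + 0.033 * math.cos(2 * math.pi / 365 * doy)
    x = max(-1.0, min(1.0, -math.tan(phi) * math.tan(delta)))
    ws = math.acos(x)
    ra = (
        24 * 60 / math.pi * 0.0820 * dr
        * (ws * math.sin(phi) * math.sin(delta) + math.cos(phi) * math.cos(delta) * math.sin(ws))
    )
    return max(ra, 0.0) * 0.408


class TestRadiation:
    def test_polar_night_is_zero(self):
        assert extraterrestrial_radiation(70.0, 12) == 0.0

    def test_hemispheric_symmetry_up_to_eccentricity(self):
        # Ra(phi, m) ~ Ra(-phi, m+6) once the inverse-distance factor dr
        # (orbital eccentricity, +-3.3%) is divided out
        import math

        doy = [15, 46, 74, 105, 135, 166, 196, 227, 258, 288, 319, 349]
        dr = lambda m: 1 + 0.033 * math.cos(2 * math.pi / 365 * doy[m - 1])
        for lat in (10, 30, 50):
            for month in range(1, 13):
                opposite = (month + 5) % 12 + 1
                a = extraterrestrial_radiation(lat, month) / dr(month)
                b = extraterrestrial_radiation(-lat, opposite) / dr(opposite)
                # mid-month sampling leaves a ~3% declination asymmetry
                assert a == pytest.approx(b, rel=0.04)

    @pytest.mark.parametrize("lat,month,doy", [(41.4, 7, 196), (41.4, 1, 15), (-20.0, 10, 288)])
    def test_matches_independent_oracle(self, lat, month, doy):
        ours = extraterrestrial_radiation(lat, month)
        assert ours == pytest.approx(_ra_oracle(lat, doy), rel=1e-4)

    def test_latitude_domain(self):
        with pytest.raises(ValueError):
            extraterrestrial_radiation(91.0, 6)

    def test_nonnegative_everywhere(self):
        lats = np.linspace(-90, 90, 37)
        for lat in lats:
            assert np.all(extraterrestrial_radiation(lat, np.arange(1, 13)) >= 0)


class TestHargreaves:
    def test_zero_diurnal_range_gives_zero(self):
        assert hargreaves_pet(15.0, 15.0, 41.4, 2000, 7) == 0.0

    def test_formula_root_at_minus_17_8(self):
        assert hargreaves_pet(-20.8, -14.8, 41.4, 2000, 1) == 0.0

    def test_compositional_hand_check(self):
        ra = extraterrestrial_radiation(41.4, 7)
        expected = 0.0023 * ra * (23.0 + 17.8) * np.sqrt(12.0) * 31
        assert hargreaves_pet(17.0, 29.0, 41.4, 2001, 7) == pytest.approx(expected)

    def test_leap_awareness(self):
        feb_leap = hargreaves_pet(0.0, 10.0, 41.4, 2000, 2)
        feb_norm = hargreaves_pet(0.0, 10.0, 41.4, 2001, 2)
        assert feb_leap / feb_norm == pytest.approx(29 / 28)

    def test_monotone_in_diurnal_range(self):
        pets = [hargreaves_pet(10 - d / 2, 10 + d / 2, 41.4, 2000, 6) for d in (2, 6, 12)]
        assert pets[0] < pets[1] < pets[2]

    def test_inverted_range_rejected(self):
        with pytest.raises(ValueError):
            hargreaves_pet(20.0, 10.0, 41.4, 2000, 6)


def _monthly_table(years=(2000, 2002), prcp=50.0):
    rows = [
        {"year": y, "month": m, "tmin": 5.0, "tmax": 15.0, "prcp": prcp}
        for y in range(years[0], years[1] + 1)
        for m in range(1, 13)
    ]
    return pd.DataFrame(rows)


class TestWaterBalance:
    def test_zero_precip_gives_minus_pet(self):
        t = water_balance(_monthly_table(prcp=0.0), 41.4)
        assert np.allclose(t["wbal"], -t["pet"])

    def test_additivity_in_precipitation(self):
        base = water_balance(_monthly_table(), 41.4)
        plus = _monthly_table()
        plus["prcp"] += 10.0
        shifted = water_balance(plus, 41.4)
        assert np.allclose(shifted["wbal"] - base["wbal"], 10.0)

    def test_missing_rows_reported(self):
        t = _monthly_table()
        t.loc[3, "tmin"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            water_balance(t, 41.4)


class TestAggregates:
    def test_constant_series_passthrough(self):
        t = _monthly_table()
        t["v"] = 7.0
        s = seasonal_mean(t, "v")
        assert np.allclose(s, 7.0)

    def test_jja_arithmetic(self):
        t = _monthly_table((2000, 2000))
        t.loc[t["month"].isin([6, 7, 8]), "prcp"] = [10.0, 20.0, 30.0]
        assert seasonal_mean(t, "prcp").loc[2000] == pytest.approx(20.0)

    def test_incomplete_season_dropped(self):
        t = _monthly_table()
        t = t[~((t["year"] == 2001) & (t["month"] == 7))]
        with pytest.warns(UserWarning, match="incomplete"):
            s = seasonal_mean(t, "prcp")
        assert 2001 not in s.index

    def test_empty_month_set_rejected(self):
        with pytest.raises(ValueError):
            seasonal_mean(_monthly_table(), "prcp", months=[])

    def test_water_year_unit_total(self):
        t = _monthly_table((1998, 2001))
        t["dep"] = 1.0
        wy = water_year_total(t[["year", "month", "dep"]])
        assert np.allclose(wy.loc[[1999, 2000, 2001]], 12.0)

    def test_november_pulse_lands_in_next_water_year(self):
        t = _monthly_table((1998, 2001))
        t["dep"] = 0.0
        t.loc[(t["year"] == 1999) & (t["month"] == 11), "dep"] = 5.0
        wy = water_year_total(t[["year", "month", "dep"]])
        assert wy.loc[2000] == pytest.approx(5.0)
        assert wy.loc[1999] == pytest.approx(0.0)

    def test_annual_input_passthrough(self):
        annual = pd.DataFrame({"year": [2000, 2001], "dep": [3.0, 4.0]})
        wy = water_year_total(annual)
        assert list(wy) == [3.0, 4.0]


class TestZscore:
    def test_whole_series_moments(self, rng):
        s = pd.Series(rng.normal(5, 3, 60), index=np.arange(1950, 2010))
        z = zscore(s)
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0)

    def test_affine_invariance(self, rng):
        s = pd.Series(rng.normal(size=40), index=np.arange(1960, 2000))
        assert np.allclose(zscore(s), zscore(3.0 * s - 7.0))

    def test_reference_period_shift_detection(self, rng):
        idx = np.arange(1950, 2015)
        x = rng.normal(0, 1, len(idx)) + np.where(idx > 1983, 1.0, 0.0)
        z = zscore(pd.Series(x, index=idx), reference_period=(1950, 1983))
        assert z[z.index > 1983].mean() > 0.5

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            zscore(pd.Series(np.ones(20), index=np.arange(20)))
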