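"""Weather QC, agro-climatic variables, day intervals and EC aggregation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metml import weather as wx


# ---------------------------------------------------------------------------
# elementary formulas
# ---------------------------------------------------------------------------

def test_saturation_vapor_pressure_reference_points():
    assert wx.saturation_vapor_pressure(0.0) == pytest.approx(0.6108, abs=1e-12)
    # hand evaluation of the Tetens closed form at 25 degC
    assert wx.saturation_vapor_pressure(25.0) == pytest.approx(3.1668, abs=2e-3)


def test_vpd_zero_when_saturated_and_clipped_when_supersaturated():
    es = wx.saturation_vapor_pressure(20.0)
    assert wx.vpd_daily(20.0, 20.0, es) == pytest.approx(0.0, abs=1e-14)
    assert wx.vpd_daily(20.0, 20.0, es + 0.5) == 0.0  # clipped, not negative


@pytest.mark.parametrize(
    "tmin, tmax, t_base, t_cap, expected",
    [
        (20, 30, 10, 30, 15.0),   # plain arithmetic
        (5, 8, 10, 30, 0.0),      # tmax below base -> floored at zero
        (25, 40, 10, 30, 17.5),   # cap applied to tmax
    ],
)
def test_gdd_daily(tmin, tmax, t_base, t_cap, expected):
    assert wx.gdd_daily(tmin, tmax, t_base, t_cap) == pytest.approx(expected)


def test_cumulative_gdd_is_nondecreasing_sum():
    series = np.full(10, 12.0)
    cum = wx.cumulative_gdd(series)
    assert cum[-1] == pytest.approx(120.0)
    assert (np.diff(cum) >= 0).all()


def test_daylength_equator_and_equinox_and_polar_rejection():
    for doy in (1, 100, 200, 300):
        assert wx.daylength(0.0, doy) == pytest.approx(12.0, abs=0.2)
    assert wx.daylength(45.0, 80) == pytest.approx(12.0, abs=0.35)
    with pytest.raises(ValueError, match="polar"):
        wx.daylength(70.0, 100)


def test_photothermal_time_is_product():
    assert wx.photothermal_time(10.0, 14.0) == pytest.approx(140.0)


# ---------------------------------------------------------------------------
# FAO-56 reference evapotranspiration
# ---------------------------------------------------------------------------

def _et0_oracle(tmean, tmax, tmin, rs, u2, rh, lat_deg, doy, elev):
    """Independent step-by-step FAO-56 daily computation (scalar, math module)."""
    es_tmax = 0.6108 * math.exp(17.27 * tmax / (tmax + 237.3))
    es_tmin = 0.6108 * math.exp(17.27 * tmin / (tmin + 237.3))
    es = (es_tmax + es_tmin) / 2.0
    ea = rh / 100.0 * es
    delta = 4098.0 * (0.6108 * math.exp(17.27 * tmean / (tmean + 237.3))) / (tmean + 237.3) ** 2
    pressure = 101.3 * ((293.0 - 0.0065 * elev) / 293.0) ** 5.26
    gamma = 0.000665 * pressure
    phi = math.radians(lat_deg)
    dr = 1.0 + 0.033 * math.cos(2.0 * math.pi * doy / 365.0)
    decl = 0.409 * math.sin(2.0 * math.pi * doy / 365.0 - 1.39)
    ws = math.acos(max(-1.0, min(1.0, -math.tan(phi) * math.tan(decl))))
    ra = 24.0 * 60.0 / math.pi * 0.0820 * dr * (
        ws * math.sin(phi) * math.sin(decl) + math.cos(phi) * math.cos(decl) * math.sin(ws)
    )
    rso = (0.75 + 2e-5 * elev) * ra
    rns = 0.77 * rs
    rel = min(max(rs / rso, 0.0), 1.0) if rso > 0 else 0.0
    rnl = 4.903e-9 * (((tmax + 273.16) ** 4 + (tmin + 273.16) ** 4) / 2.0) \
        * (0.34 - 0.14 * math.sqrt(ea)) * (1.35 * rel - 0.35)
    rn = rns - rnl
    num = 0.408 * delta * rn + gamma * 900.0 / (tmean + 273.0) * u2 * (es - ea)
    den = delta + gamma * (1.0 + 0.34 * u2)
    return max(num / den, 0.0)


def test_et0_zero_when_no_wind_and_no_net_radiation():
    out = wx.et0_penman_monteith(
        tmean=20.0, tmax=25.0, tmin=15.0, solar_radiation=0.0, wind_speed_2m=0.0,
        ea=1.0, latitude=40.0, doy=180, rn=0.0,
    )
    assert float(out) == 0.0


def test_et0_strictly_increases_with_net_radiation():
    kwargs = dict(tmean=20.0, tmax=25.0, tmin=15.0, solar_radiation=0.0,
                  wind_speed_2m=2.0, ea=1.0, latitude=40.0, doy=180)
    lo = wx.et0_penman_monteith(rn=5.0, **kwargs)
    hi = wx.et0_penman_monteith(rn=10.0, **kwargs)
    assert hi > lo


def test_et0_missing_wind_or_humidity_errors():
    with pytest.raises(ValueError, match="wind_speed_2m"):
        wx.et0_penman_monteith(20, 25, 15, 15.0, None, 1.0, 40.0, 180)
    with pytest.raises(ValueError, match="ea"):
        wx.et0_penman_monteith(20, 25, 15, 15.0, 2.0, None, 40.0, 180)


def test_et0_agrees_with_independent_oracle_over_30_days():
    rng = np.random.default_rng(42)
    lat, elev = 41.5, 250.0
    for i in range(30):
        doy = 120 + i
        tmin = float(rng.uniform(5, 18))
        tmax = tmin + float(rng.uniform(4, 14))
        tmean = (tmin + tmax) / 2
        rs = float(rng.uniform(8, 28))
        u2 = float(rng.uniform(0.3, 6))
        rh = float(rng.uniform(35, 95))
        ea = rh / 100.0 * 0.5 * (
            wx.saturation_vapor_pressure(tmax) + wx.saturation_vapor_pressure(tmin)
        )
        ours = float(
            wx.et0_penman_monteith(tmean, tmax, tmin, rs, u2, ea, lat, doy, elevation=elev)
        )
        ref = _et0_oracle(tmean, tmax, tmin, rs, u2, rh, lat, doy, elev)
        assert ours == pytest.approx(ref, rel=0.01)


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

def test_qc_clean_series_is_identity(toy_weather):
    clean, report = wx.qc_daily_weather(toy_weather)
    assert report.n_flags == 0 and report.n_imputed == 0
    pd.testing.assert_frame_equal(
        clean.reset_index(drop=True), toy_weather.reset_index(drop=True),
        check_dtype=False,
    )


def test_qc_swaps_inverted_tmin_tmax(toy_weather):
    bad = toy_weather.copy()
    bad.loc[3, ["tmin", "tmax"]] = [20.0, 10.0]
    bad.loc[3, "tmean"] = 15.0
    clean, report = wx.qc_daily_weather(bad)
    assert "tmax_lt_tmin" in set(report.flags["rule_violated"])
    assert clean.loc[3, "tmin"] == 10.0 and clean.loc[3, "tmax"] == 20.0


def test_qc_interpolates_missing_tmean(toy_weather):
    bad = toy_weather.copy()
    bad.loc[10, "tmean"] = np.nan
    clean, report = wx.qc_daily_weather(bad)
    assert report.n_imputed == 1
    expected = (toy_weather.loc[9, "tmean"] + toy_weather.loc[11, "tmean"]) / 2
    assert clean.loc[10, "tmean"] == pytest.approx(expected)


def test_qc_missing_day_reindexed_and_precip_imputed_zero(toy_weather):
    gappy = toy_weather.drop(index=5).reset_index(drop=True)
    clean, report = wx.qc_daily_weather(gappy)
    assert len(clean) == 20
    assert (report.flags["rule_violated"] == "missing_day").sum() == 1
    assert clean.loc[5, "precipitation"] == 0.0


def test_qc_hard_error_when_too_many_days_flagged(toy_weather):
    bad = toy_weather.copy()
    bad.loc[:8, "tmax"] = 99.0  # 9/20 days out of physical range
    with pytest.raises(ValueError, match="unusable"):
        wx.qc_daily_weather(bad)


def test_qc_is_idempotent(toy_weather):
    bad = toy_weather.copy()
    bad.loc[2, "tmean"] = np.nan
    bad.loc[7, ["tmin", "tmax"]] = [18.0, 9.0]
    bad.loc[7, "tmean"] = 13.0
    once, _ = wx.qc_daily_weather(bad)
    twice, report2 = wx.qc_daily_weather(once)
    assert report2.n_flags == 0
    pd.testing.assert_frame_equal(once, twice, check_dtype=False)


# ---------------------------------------------------------------------------
# day intervals
# ---------------------------------------------------------------------------

def test_fixed_number_default_ten_equal_windows():
    iv = wx.define_intervals("e", 100, method="fixed_number", n_intervals=10)
    assert iv.intervals == [(k * 10, (k + 1) * 10) for k in range(10)]


def test_fixed_number_remainder_to_earliest_windows():
    iv = wx.define_intervals("e", 23, method="fixed_number", n_intervals=4)
    assert iv.intervals == [(0, 6), (6, 12), (12, 18), (18, 23)]


def test_fixed_length_truncates_last_window():
    iv = wx.define_intervals("e", 25, method="fixed_length", interval_length=10)
    assert iv.intervals == [(0, 10), (10, 20), (20, 25)]


def test_gdd_stage_breakpoints_at_threshold_crossings():
    iv = wx.define_intervals(
        "e", 20, method="gdd_stages", gdd_thresholds=[50, 100],
        daily_gdd=np.full(20, 10.0),
    )
    assert iv.intervals == [(0, 5), (5, 10), (10, 20)]


def test_gdd_threshold_never_reached_warns_and_absorbs():
    with pytest.warns(UserWarning, match="never reached"):
        iv = wx.define_intervals(
            "e", 10, method="gdd_stages", gdd_thresholds=[20, 1000],
            daily_gdd=np.full(10, 5.0),
        )
    assert iv.intervals == [(0, 4), (4, 10)]


def test_user_defined_breakpoints_validated():
    iv = wx.define_intervals("e", 30, method="user_defined", breakpoints=[0, 12, 30])
    assert iv.intervals == [(0, 12), (12, 30)]
    with pytest.raises(ValueError, match="cover"):
        wx.define_intervals("e", 30, method="user_defined", breakpoints=[0, 12, 25])


@settings(max_examples=60, deadline=None)
@given(
    season=st.integers(min_value=5, max_value=400),
    method=st.sampled_from(["fixed_number", "fixed_length"]),
    param=st.integers(min_value=1, max_value=30),
)
def test_intervals_cover_the_season_exactly(season, method, param):
    kwargs = {"n_intervals": param} if method == "fixed_number" else {"interval_length": param}
    iv = wx.define_intervals("e", season, method=method, **kwargs)
    starts, ends = zip(*iv.intervals)
    assert starts[0] == 0 and ends[-1] == season
    assert all(e == s for s, e in zip(starts[1:], ends[:-1]))  # contiguous


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def _env_info_for(toy_weather):
    return pd.DataFrame(
        [{
            "env_id": "Toy_2020", "year": 2020, "location": "Toy",
            "longitude": -93.0, "latitude": 42.0, "elevation": 200.0,
            "planting_date": pd.Timestamp("2020-05-01"),
            "harvest_date": pd.Timestamp("2020-05-20"),
        }]
    )


def test_aggregation_matches_brute_force_on_toy_table(toy_weather):
    env_info = _env_info_for(toy_weather)
    daily = wx.compute_derived_daily(toy_weather, env_info)
    iv = wx.define_intervals("Toy_2020", 20, method="fixed_number", n_intervals=4)
    ecs = wx.aggregate_ecs(daily, [iv])

    # independent brute-force recomputation, cell by cell
    for k, (s, e) in enumerate(iv.intervals, start=1):
        win = daily.iloc[s:e]
        assert ecs.loc["Toy_2020", f"mean_tmean_{k}"] == pytest.approx(
            sum(win["tmean"]) / len(win), abs=1e-9)
        assert ecs.loc["Toy_2020", f"sum_precipitation_{k}"] == pytest.approx(
            sum(win["precipitation"]), abs=1e-9)
        assert ecs.loc["Toy_2020", f"sum_gdd_{k}"] == pytest.approx(
            sum(max(0.0, (min(t, 30) + max(b, 10)) / 2 - 10)
                for b, t in zip(win["tmin"], win["tmax"])), abs=1e-9)
        assert ecs.loc["Toy_2020", f"sum_photothermal_{k}"] == pytest.approx(
            sum(win["gdd"] * win["daylength"]), abs=1e-9)
        assert ecs.loc["Toy_2020", f"freq_P_sup10_{k}"] == pytest.approx(
            sum(1 for p in win["precipitation"] if p > 10) / len(win), abs=1e-9)
        assert ecs.loc["Toy_2020", f"sum_et0_{k}"] == pytest.approx(
            sum(win["et0"]), abs=1e-9)


def test_heavy_rain_frequency_example():
    dates = pd.date_range("2021-06-01", periods=10, freq="D")
    precip = np.zeros(10)
    precip[2], precip[7] = 12.0, 15.0
    daily = pd.DataFrame({
        "env_id": "E_2021", "date": dates, "tmin": 10.0, "tmax": 20.0, "tmean": 15.0,
        "precipitation": precip, "solar_radiation": 20.0, "wind_speed_2m": 2.0,
        "relative_humidity": 60.0,
    })
    iv = wx.define_intervals("E_2021", 10, method="fixed_number", n_intervals=1)
    ecs = wx.aggregate_ecs(daily, [iv], recipes={"freq_P_sup10": ("precipitation", "freq_gt_10"),
                                                 "mean_tmean": ("tmean", "mean")})
    assert ecs.loc["E_2021", "freq_P_sup10_1"] == pytest.approx(0.2)
    assert ecs.loc["E_2021", "mean_tmean_1"] == pytest.approx(15.0)


def test_ec_names_parse_back_to_variable_and_interval():
    assert wx.parse_ec_name("freq_P_sup10_2") == ("freq_P_sup10", 2)
    assert wx.parse_ec_name("sum_et0_10") == ("sum_et0", 10)


def test_derived_variables_nonnegative_after_qc(toy_weather):
    env_info = _env_info_for(toy_weather)
    clean, _ = wx.qc_daily_weather(toy_weather)
    daily = wx.compute_derived_daily(clean, env_info)
    for col in ("vpd", "gdd", "photothermal", "et0", "daylength"):
        assert (daily[col] >= 0).all()


# ---------------------------------------------------------------------------
# weather providers
# ---------------------------------------------------------------------------

def test_file_source_passthrough_and_gap_error(toy_weather):
    src = wx.FileWeatherSource(toy_weather)
    got = src.get_daily("Toy_2020", 42.0, -93.0, "2020-05-01", "2020-05-20")
    assert len(got) == 20
    pd.testing.assert_series_equal(
        got["tmean"].reset_index(drop=True), toy_weather["tmean"], check_names=False
    )
    src_gappy = wx.FileWeatherSource(toy_weather.drop(index=4))
    with pytest.raises(LookupError, match="missing"):
        src_gappy.get_daily("Toy_2020", 42.0, -93.0, "2020-05-01", "2020-05-20")


def test_provider_called_only_for_environments_without_in_field_data(toy_weather):
    second = toy_weather.copy()
    second["env_id"] = "Other_2020"
    env_info = pd.concat([_env_info_for(toy_weather), _env_info_for(toy_weather)],
                         ignore_index=True)
    env_info.loc[1, ["env_id", "location"]] = ["Other_2020", "Other"]
    src = wx.FileWeatherSource(second)
    ecs, report, prov = wx.get_ecs(env_info, raw_weather=toy_weather, source=src,
                                   n_intervals=4)
    assert src.calls == ["Other_2020"]
    assert prov == {"Toy_2020": "in_field", "Other_2020": "retrieved"}
    assert set(ecs.index) == {"Toy_2020", "Other_2020"}


def test_provider_failure_lists_missing_environments(toy_weather):
    env_info = _env_info_for(toy_weather)
    env_info.loc[0, "env_id"] = "Nowhere_2020"
    src = wx.FileWeatherSource(toy_weather)  # has no rows for Nowhere_2020
    with pytest.raises(RuntimeError, match="Nowhere_2020"):
        wx.fetch_satellite_weather(env_info, src)
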