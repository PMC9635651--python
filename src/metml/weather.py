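"""Daily weather quality control, agro-climatic variables, and environmental covariates.

This module turns raw daily weather series (one per environment of a
multi-environment trial) into the environment x covariate matrix ``W`` used by
all downstream prediction models.  The processing chain is

1. :func:`qc_daily_weather` — physical-range checks, repair and gap imputation;
2. :func:`compute_derived_daily` — vapour pressure deficit, FAO-56 reference
   evapotranspiration, growing degree-days, daylength, photothermal time;
3. :func:`define_intervals` — split the growing season into day windows by one
   of four methods (fixed number, fixed length, user breakpoints, GDD stages);
4. :func:`aggregate_ecs` — aggregate daily values within each window into named
   covariates such as ``sum_et0_3`` or ``freq_P_sup10_2`` (1-based window index).

Weather can come from in-field records or from a pluggable
:class:`WeatherSource` (e.g. a file-backed table standing in for a satellite
weather service); :func:`fetch_satellite_weather` fills in the environments
that lack in-field data.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Protocol, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Columns a daily weather table must provide (plus one of
#: ``relative_humidity`` / ``dewpoint``).
WEATHER_COLUMNS = (
    "env_id",
    "date",
    "tmin",
    "tmax",
    "tmean",
    "precipitation",
    "solar_radiation",
    "wind_speed_2m",
)

# physical-range QC bounds
_T_MIN, _T_MAX = -50.0, 60.0
_PRECIP_MAX = 500.0
_QC_MAX_FLAG_FRACTION = 0.30

# default cardinal temperatures for thermal time (maize convention, per-crop override)
DEFAULT_T_BASE = 10.0
DEFAULT_T_CAP = 30.0

_SOLAR_CONSTANT = 0.0820  # MJ m-2 min-1
_STEFAN_BOLTZMANN = 4.903e-9  # MJ K-4 m-2 day-1


# ---------------------------------------------------------------------------
# elementary agro-climatic formulas
# ---------------------------------------------------------------------------

def saturation_vapor_pressure(temp_c):
    """Saturation vapour pressure ``es`` in kPa at air temperature ``temp_c`` (°C).

    Tetens form: ``es(T) = 0.6108 * exp(17.27 T / (T + 237.3))``.
    """
    t = np.asarray(temp_c, dtype=float)
    return 0.6108 * np.exp(17.27 * t / (t + 237.3))


def slope_saturation_vapor_pressure(temp_c):
    """Slope of the saturation vapour pressure curve (kPa/°C) at ``temp_c``."""
    t = np.asarray(temp_c, dtype=float)
    return 4098.0 * saturation_vapor_pressure(t) / (t + 237.3) ** 2


def vpd_daily(tmax, tmin, actual_vapor_pressure):
    """Daily vapour pressure deficit (kPa), clipped at zero.

    VPD = (es(tmax) + es(tmin)) / 2 − ea.  Supersaturated inputs (ea above the
    mean saturation pressure) are clipped to zero and logged.
    """
    es_mean = 0.5 * (saturation_vapor_pressure(tmax) + saturation_vapor_pressure(tmin))
    vpd = es_mean - np.asarray(actual_vapor_pressure, dtype=float)
    n_super = int(np.sum(np.asarray(vpd) < 0))
    if n_super:
        logger.info("vpd_daily: clipped %d supersaturated day(s) to 0", n_super)
    return np.maximum(vpd, 0.0)


def actual_vapor_pressure(tmax, tmin, relative_humidity=None, dewpoint=None):
    """Actual vapour pressure ``ea`` (kPa) from mean RH (%) or dewpoint (°C)."""
    if dewpoint is not None:
        return saturation_vapor_pressure(dewpoint)
    if relative_humidity is None:
        raise ValueError("need relative_humidity or dewpoint to compute ea")
    es_mean = 0.5 * (saturation_vapor_pressure(tmax) + saturation_vapor_pressure(tmin))
    return np.asarray(relative_humidity, dtype=float) / 100.0 * es_mean


def extraterrestrial_radiation(latitude, doy):
    """Daily extraterrestrial radiation Ra (MJ m-2 day-1) for latitude/day-of-year."""
    lat = math.radians(float(latitude))
    doy = np.asarray(doy, dtype=float)
    dr = 1.0 + 0.033 * np.cos(2.0 * np.pi * doy / 365.0)
    decl = 0.409 * np.sin(2.0 * np.pi * doy / 365.0 - 1.39)
    x = np.clip(-np.tan(lat) * np.tan(decl), -1.0, 1.0)
    ws = np.arccos(x)
    ra = (24.0 * 60.0 / np.pi) * _SOLAR_CONSTANT * dr * (
        ws * math.sin(lat) * np.sin(decl) + math.cos(lat) * np.cos(decl) * np.sin(ws)
    )
    return np.maximum(ra, 0.0)


def daylength(latitude, doy):
    """Astronomical daylength in hours.

    Solar declination ``delta = 0.409 sin(2 pi doy / 365 - 1.39)``;
    daylength = ``24/pi * arccos(-tan(lat) tan(delta))``.  Polar latitudes
    (|lat| > 66°) are rejected: the arccos argument can leave [-1, 1].
    """
    if abs(float(latitude)) > 66.0:
        raise ValueError(
            f"latitude {latitude} is polar (|lat| > 66); daylength undefined "
            "on polar day/night"
        )
    lat = math.radians(float(latitude))
    doy = np.asarray(doy, dtype=float)
    decl = 0.409 * np.sin(2.0 * np.pi * doy / 365.0 - 1.39)
    return 24.0 / np.pi * np.arccos(np.clip(-np.tan(lat) * np.tan(decl), -1.0, 1.0))


def gdd_daily(tmin, tmax, t_base=DEFAULT_T_BASE, t_cap=DEFAULT_T_CAP):
    """Daily growing degree-days (°C day) with base/cap temperatures.

    GDD = max(0, (min(tmax, t_cap) + max(tmin, t_base)) / 2 − t_base).
    """
    if not t_base < t_cap:
        raise ValueError(f"t_base ({t_base}) must be below t_cap ({t_cap})")
    tmax_c = np.minimum(np.asarray(tmax, dtype=float), t_cap)
    tmin_c = np.maximum(np.asarray(tmin, dtype=float), t_base)
    return np.maximum(0.0, 0.5 * (tmax_c + tmin_c) - t_base)


def cumulative_gdd(daily_gdd):
    """Running (non-decreasing) sum of a daily GDD series."""
    return np.cumsum(np.asarray(daily_gdd, dtype=float))


def photothermal_time(daily_gdd, daylength_hours):
    """Photothermal time (°C h): daily thermal time weighted by photoperiod."""
    return np.asarray(daily_gdd, dtype=float) * np.asarray(daylength_hours, dtype=float)


def et0_penman_monteith(
    tmean,
    tmax,
    tmin,
    solar_radiation,
    wind_speed_2m,
    ea,
    latitude,
    doy,
    elevation=0.0,
    rn=None,
):
    """FAO-56 daily reference evapotranspiration (mm/day) for a grass surface.

    ET0 = [0.408 Δ (Rn − G) + γ 900/(T+273) u2 (es − ea)] / [Δ + γ (1 + 0.34 u2)]

    with soil heat flux G = 0 at the daily step.  Net radiation ``Rn`` is
    computed from measured short-wave radiation via the FAO-56 albedo (0.23)
    and net long-wave terms, unless supplied directly through ``rn``.
    Missing elevation defaults to sea level.  The result is clipped at 0.
    """
    for name, val in (("wind_speed_2m", wind_speed_2m), ("ea", ea)):
        if val is None or np.any(pd.isna(val)):
            raise ValueError(f"et0_penman_monteith: missing required variable {name!r}")
    t = np.asarray(tmean, dtype=float)
    u2 = np.asarray(wind_speed_2m, dtype=float)
    ea = np.asarray(ea, dtype=float)
    rs = np.asarray(solar_radiation, dtype=float)

    delta = slope_saturation_vapor_pressure(t)
    pressure = 101.3 * ((293.0 - 0.0065 * float(elevation)) / 293.0) ** 5.26
    gamma = 0.000665 * pressure
    es = 0.5 * (saturation_vapor_pressure(tmax) + saturation_vapor_pressure(tmin))

    if rn is None:
        ra = extraterrestrial_radiation(latitude, doy)
        rso = (0.75 + 2e-5 * float(elevation)) * ra
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.where(rso > 0, np.clip(rs / np.where(rso > 0, rso, 1.0), 0.0, 1.0), 0.0)
        rns = (1.0 - 0.23) * rs
        tk4 = 0.5 * (
            (np.asarray(tmax, dtype=float) + 273.16) ** 4
            + (np.asarray(tmin, dtype=float) + 273.16) ** 4
        )
        rnl = _STEFAN_BOLTZMANN * tk4 * (0.34 - 0.14 * np.sqrt(np.maximum(ea, 0.0))) * (
            1.35 * rel - 0.35
        )
        rn = rns - rnl
    rn = np.asarray(rn, dtype=float)

    g = 0.0  # daily soil heat flux
    num = 0.408 * delta * (rn - g) + gamma * (900.0 / (t + 273.0)) * u2 * (es - ea)
    den = delta + gamma * (1.0 + 0.34 * u2)
    return np.maximum(num / den, 0.0)


def wind_to_2m(wind_speed, measurement_height):
    """FAO-56 logarithmic wind-profile conversion to the standard 2 m height."""
    z = float(measurement_height)
    if z == 2.0:
        return np.asarray(wind_speed, dtype=float)
    return np.asarray(wind_speed, dtype=float) * 4.87 / math.log(67.8 * z - 5.42)


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    """Flagged cells and imputation counts from daily-weather quality control."""

    flags: pd.DataFrame  # env_id, date, variable, rule_violated, original_value
    n_imputed: int = 0

    def to_csv(self, path) -> None:
        self.flags.to_csv(path, index=False)

    @property
    def n_flags(self) -> int:
        return len(self.flags)


def _flag(records, env_id, date, variable, rule, value):
    records.append(
        {
            "env_id": env_id,
            "date": date,
            "variable": variable,
            "rule_violated": rule,
            "original_value": value,
        }
    )


def qc_daily_weather(
    weather: pd.DataFrame,
    date_ranges: Mapping[str, tuple] | None = None,
) -> tuple[pd.DataFrame, QCReport]:
    """Quality-control a daily weather table; return the repaired table + report.

    Rules, applied per environment:

    * ``tmax < tmin`` — values swapped (flag ``tmax_lt_tmin``);
    * temperatures outside [-50, 60] °C, precipitation outside [0, 500] mm,
      negative radiation, relative humidity outside [0, 100] — set missing
      and flagged with the rule name;
    * ``tmean`` outside [tmin, tmax] — set missing (flag ``tmean_out_of_range``);
    * duplicated (env, date) rows rejected; date gaps within planting→harvest
      (or the observed span) re-indexed and counted as missing.

    Missing / invalidated values are imputed by linear interpolation in time
    within the environment; precipitation is imputed as 0.  An environment
    where more than 30% of days are flagged raises ``ValueError``.
    Idempotent: re-running on its own output yields zero flags.
    """
    required = [c for c in WEATHER_COLUMNS if c != "env_id"]
    missing_cols = [c for c in required if c not in weather.columns]
    if missing_cols:
        raise ValueError(f"weather table missing columns: {missing_cols}")
    has_rh = "relative_humidity" in weather.columns
    has_dew = "dewpoint" in weather.columns
    if not (has_rh or has_dew):
        raise ValueError("weather table needs relative_humidity or dewpoint")

    weather = weather.copy()
    weather["date"] = pd.to_datetime(weather["date"])
    if weather.duplicated(subset=["env_id", "date"]).any():
        dup = weather[weather.duplicated(subset=["env_id", "date"])].iloc[0]
        raise ValueError(f"duplicate weather row for {dup['env_id']} {dup['date']}")

    records: list[dict] = []
    n_imputed = 0
    out_frames = []
    value_cols = [c for c in weather.columns if c not in ("env_id", "date")]

    for env_id, grp in weather.groupby("env_id", sort=True):
        grp = grp.sort_values("date").set_index("date")
        if date_ranges and env_id in date_ranges:
            start, end = date_ranges[env_id]
            full_index = pd.date_range(start, end, freq="D")
        else:
            full_index = pd.date_range(grp.index.min(), grp.index.max(), freq="D")
        n_gap = len(full_index.difference(grp.index))
        if n_gap:
            for d in full_index.difference(grp.index):
                _flag(records, env_id, d, "all", "missing_day", np.nan)
        grp = grp.reindex(full_index)
        grp["env_id"] = env_id

        # ordering repair: swap before range checks
        bad_order = grp["tmax"] < grp["tmin"]
        for d in grp.index[bad_order.fillna(False)]:
            _flag(records, env_id, d, "tmax", "tmax_lt_tmin", grp.at[d, "tmax"])
        swapped_min = grp["tmax"].where(bad_order, grp["tmin"])
        grp["tmax"] = grp["tmin"].where(bad_order, grp["tmax"])
        grp["tmin"] = swapped_min

        def invalidate(col, mask, rule):
            nonlocal records
            for d in grp.index[mask.fillna(False)]:
                _flag(records, env_id, d, col, rule, grp.at[d, col])
            grp.loc[mask.fillna(False), col] = np.nan

        for col in ("tmin", "tmax", "tmean"):
            invalidate(col, (grp[col] < _T_MIN) | (grp[col] > _T_MAX), f"{col}_out_of_physical_range")
        invalidate(
            "precipitation",
            (grp["precipitation"] < 0) | (grp["precipitation"] > _PRECIP_MAX),
            "precip_out_of_range",
        )
        invalidate("solar_radiation", grp["solar_radiation"] < 0, "negative_radiation")
        if has_rh:
            invalidate(
                "relative_humidity",
                (grp["relative_humidity"] < 0) | (grp["relative_humidity"] > 100),
                "rh_out_of_range",
            )
        invalidate("wind_speed_2m", grp["wind_speed_2m"] < 0, "negative_wind")
        invalidate(
            "tmean",
            (grp["tmean"] < grp["tmin"]) | (grp["tmean"] > grp["tmax"]),
            "tmean_out_of_range",
        )

        n_flagged_days = len({r["date"] for r in records if r["env_id"] == env_id})
        if n_flagged_days > _QC_MAX_FLAG_FRACTION * len(grp):
            raise ValueError(
                f"environment {env_id}: {n_flagged_days}/{len(grp)} days flagged "
                f"(> {_QC_MAX_FLAG_FRACTION:.0%}); weather unusable"
            )

        # imputation
        for col in value_cols:
            n_na = int(grp[col].isna().sum())
            if n_na == 0:
                continue
            n_imputed += n_na
            if col == "precipitation":
                grp[col] = grp[col].fillna(0.0)
            else:
                grp[col] = grp[col].interpolate(method="linear", limit_direction="both")
        # re-impose ordering after interpolation
        both = grp[["tmin", "tmax"]].to_numpy()
        grp["tmin"], grp["tmax"] = both.min(axis=1), both.max(axis=1)
        grp["tmean"] = grp["tmean"].clip(grp["tmin"], grp["tmax"])

        grp = grp.reset_index().rename(columns={"index": "date"})
        out_frames.append(grp[["env_id", "date"] + value_cols])

    clean = pd.concat(out_frames, ignore_index=True)
    if clean[value_cols].isna().any().any():
        bad = clean.columns[clean.isna().any()].tolist()
        raise ValueError(f"columns {bad} entirely missing in one environment; cannot impute")
    flags = pd.DataFrame.from_records(
        records, columns=["env_id", "date", "variable", "rule_violated", "original_value"]
    )
    return clean, QCReport(flags=flags, n_imputed=n_imputed)


# ---------------------------------------------------------------------------
# derived daily variables
# ---------------------------------------------------------------------------

def compute_derived_daily(
    weather: pd.DataFrame,
    env_info: pd.DataFrame,
    t_base: float = DEFAULT_T_BASE,
    t_cap: float = DEFAULT_T_CAP,
    compute_et0: bool = True,
) -> pd.DataFrame:
    """Add derived agro-climatic columns to a QC-passed daily table.

    Adds ``vpd`` (kPa), ``gdd`` (°C day), ``daylength`` (h), ``photothermal``
    (°C h) and, when ``compute_et0``, ``et0`` (mm/day).  ``env_info`` supplies
    latitude and (optionally) elevation per ``env_id``.
    """
    env_meta = env_info.set_index("env_id")
    frames = []
    for env_id, grp in weather.groupby("env_id", sort=True):
        if env_id not in env_meta.index:
            raise KeyError(f"weather references unknown environment {env_id!r}")
        grp = grp.sort_values("date").copy()
        lat = float(env_meta.at[env_id, "latitude"])
        elev = 0.0
        if "elevation" in env_meta.columns and pd.notna(env_meta.at[env_id, "elevation"]):
            elev = float(env_meta.at[env_id, "elevation"])
        doy = pd.to_datetime(grp["date"]).dt.dayofyear.to_numpy()
        ea = actual_vapor_pressure(
            grp["tmax"],
            grp["tmin"],
            relative_humidity=grp.get("relative_humidity"),
            dewpoint=grp.get("dewpoint"),
        )
        grp["vpd"] = vpd_daily(grp["tmax"], grp["tmin"], ea)
        grp["gdd"] = gdd_daily(grp["tmin"], grp["tmax"], t_base=t_base, t_cap=t_cap)
        grp["daylength"] = daylength(lat, doy)
        grp["photothermal"] = photothermal_time(grp["gdd"], grp["daylength"])
        if compute_et0:
            grp["et0"] = et0_penman_monteith(
                grp["tmean"],
                grp["tmax"],
                grp["tmin"],
                grp["solar_radiation"],
                grp["wind_speed_2m"],
                ea,
                latitude=lat,
                doy=doy,
                elevation=elev,
            )
        frames.append(grp)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# day intervals
# ---------------------------------------------------------------------------

INTERVAL_METHODS = ("fixed_number", "fixed_length", "user_defined", "gdd_stages")


@dataclass
class IntervalSet:
    """Contiguous half-open day windows covering one environment's season.

    ``breaks`` holds n+1 cut points with day 0 = planting date, so window ``k``
    (1-based in covariate names) spans ``[breaks[k-1], breaks[k])``.
    """

    env_id: str
    breaks: np.ndarray
    method: str

    def __post_init__(self):
        self.breaks = np.asarray(self.breaks, dtype=int)
        if self.method not in INTERVAL_METHODS:
            raise ValueError(f"unknown interval method {self.method!r}")
        if len(self.breaks) < 2 or self.breaks[0] != 0:
            raise ValueError("breaks must start at day 0 and define >= 1 interval")
        if np.any(np.diff(self.breaks) <= 0):
            raise ValueError("breaks must be strictly increasing (no empty intervals)")

    @property
    def intervals(self) -> list[tuple[int, int]]:
        return list(zip(self.breaks[:-1].tolist(), self.breaks[1:].tolist()))

    @property
    def n_intervals(self) -> int:
        return len(self.breaks) - 1

    @property
    def season_length(self) -> int:
        return int(self.breaks[-1])


def define_intervals(
    env_id: str,
    season_length: int,
    method: str = "fixed_number",
    n_intervals: int = 10,
    interval_length: int | None = None,
    breakpoints: Sequence[int] | None = None,
    gdd_thresholds: Sequence[float] | None = None,
    daily_gdd: Sequence[float] | None = None,
) -> IntervalSet:
    """Define the day windows used to aggregate daily weather into covariates.

    ``fixed_number`` (default, n=10): near-equal windows, the remainder days
    going to the earliest windows.  ``fixed_length``: ceil(season/len) windows,
    the last truncated.  ``user_defined``: validated pass-through of explicit
    breakpoints.  ``gdd_stages``: a window boundary at the first day on which
    cumulative GDD crosses each threshold; thresholds never reached are
    absorbed by the final window with a warning.
    """
    season_length = int(season_length)
    if season_length < 1:
        raise ValueError("season_length must be >= 1")
    if method == "fixed_number":
        n = min(int(n_intervals), season_length)
        base, rem = divmod(season_length, n)
        widths = [base + 1] * rem + [base] * (n - rem)
        breaks = np.concatenate([[0], np.cumsum(widths)])
    elif method == "fixed_length":
        if not interval_length or interval_length < 1:
            raise ValueError("fixed_length requires interval_length >= 1")
        breaks = list(range(0, season_length, int(interval_length))) + [season_length]
        breaks = np.unique(breaks)
    elif method == "user_defined":
        if breakpoints is None:
            raise ValueError("user_defined requires explicit breakpoints")
        breaks = np.asarray(sorted(set(int(b) for b in breakpoints)), dtype=int)
        if breaks[0] != 0 or breaks[-1] != season_length:
            raise ValueError(
                f"user breakpoints must cover [0, {season_length}); got {breaks.tolist()}"
            )
    elif method == "gdd_stages":
        if gdd_thresholds is None or daily_gdd is None:
            raise ValueError("gdd_stages requires gdd_thresholds and daily_gdd")
        daily_gdd = np.asarray(daily_gdd, dtype=float)
        if len(daily_gdd) < season_length:
            raise ValueError("daily_gdd shorter than the season")
        cum = cumulative_gdd(daily_gdd[:season_length])
        breaks = [0]
        for thr in sorted(gdd_thresholds):
            crossed = np.nonzero(cum >= thr)[0]
            if len(crossed) == 0:
                warnings.warn(
                    f"{env_id}: GDD threshold {thr} never reached; "
                    "final interval absorbs the remainder",
                    stacklevel=2,
                )
                break
            day = int(crossed[0]) + 1  # boundary after the crossing day
            if 0 < day < season_length and day > breaks[-1]:
                breaks.append(day)
        breaks.append(season_length)
        breaks = np.unique(breaks)
    else:
        raise ValueError(f"unknown interval method {method!r}; use one of {INTERVAL_METHODS}")
    return IntervalSet(env_id=env_id, breaks=np.asarray(breaks, dtype=int), method=method)


# ---------------------------------------------------------------------------
# aggregation into the EC matrix
# ---------------------------------------------------------------------------

#: Aggregation recipe per daily variable: means for states, sums for fluxes,
#: plus the frequency of heavy-rain days (> 10 mm).
EC_RECIPES: dict[str, tuple[str, str]] = {
    "mean_tmin": ("tmin", "mean"),
    "mean_tmax": ("tmax", "mean"),
    "mean_tmean": ("tmean", "mean"),
    "mean_vpd": ("vpd", "mean"),
    "mean_solar_radiation": ("solar_radiation", "mean"),
    "mean_daylength": ("daylength", "mean"),
    "sum_precipitation": ("precipitation", "sum"),
    "sum_et0": ("et0", "sum"),
    "sum_gdd": ("gdd", "sum"),
    "sum_photothermal": ("photothermal", "sum"),
    "freq_P_sup10": ("precipitation", "freq_gt_10"),
}

HEAVY_RAIN_MM = 10.0


def parse_ec_name(name: str) -> tuple[str, int]:
    """Split an EC column name ``varname_k`` into (variable, 1-based interval)."""
    stem, _, idx = name.rpartition("_")
    return stem, int(idx)


def aggregate_ecs(
    daily: pd.DataFrame,
    intervals: Mapping[str, IntervalSet] | Sequence[IntervalSet],
    recipes: Mapping[str, tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Aggregate derived daily weather into the environment x covariate matrix.

    ``daily`` must carry the derived columns from :func:`compute_derived_daily`
    and cover each environment's season from planting (day 0).  Every
    environment must yield the identical covariate column set; environments
    with differing interval counts therefore require the ``fixed_number`` or
    ``user_defined`` methods with equal window counts.
    """
    if recipes is None:
        recipes = {k: v for k, v in EC_RECIPES.items() if v[0] in daily.columns or v[0] == "precipitation"}
    if not isinstance(intervals, Mapping):
        intervals = {iv.env_id: iv for iv in intervals}

    rows = {}
    for env_id, iv in sorted(intervals.items()):
        grp = daily[daily["env_id"] == env_id].sort_values("date")
        if len(grp) < iv.season_length:
            raise ValueError(
                f"{env_id}: weather covers {len(grp)} day(s), season needs {iv.season_length}"
            )
        grp = grp.iloc[: iv.season_length]
        row = {}
        for k, (start, end) in enumerate(iv.intervals, start=1):
            window = grp.iloc[start:end]
            if len(window) == 0:
                raise ValueError(f"{env_id}: interval {k} [{start},{end}) has no days")
            for ec_name, (var, how) in recipes.items():
                if var not in window.columns:
                    raise KeyError(f"daily table lacks column {var!r} needed for {ec_name}")
                vals = window[var].to_numpy(dtype=float)
                if how == "mean":
                    agg = float(np.mean(vals))
                elif how == "sum":
                    agg = float(np.sum(vals))
                elif how == "freq_gt_10":
                    agg = float(np.mean(vals > HEAVY_RAIN_MM))
                else:
                    raise ValueError(f"unknown aggregation {how!r}")
                row[f"{ec_name}_{k}"] = agg
        rows[env_id] = row

    ecs = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    ecs.index.name = "env_id"
    if ecs.isna().any().any():
        bad = ecs.columns[ecs.isna().any()].tolist()
        raise ValueError(
            f"EC matrix has missing cells in {bad}; environments must share one "
            "covariate column set (equal interval counts)"
        )
    return ecs


# ---------------------------------------------------------------------------
# weather providers
# ---------------------------------------------------------------------------

class WeatherSource(Protocol):
    """Provider of daily weather for one environment (satellite service or file)."""

    def get_daily(self, env_id: str, latitude: float, longitude: float,
                  start, end) -> pd.DataFrame: ...


class FileWeatherSource:
    """File/dict-backed :class:`WeatherSource` serving pre-tabulated daily weather.

    Stands in for a remote satellite-weather service in offline runs; accepts
    either a CSV path with a standard weather table or a ready DataFrame.
    """

    def __init__(self, table: pd.DataFrame | str):
        if isinstance(table, (str,)) or hasattr(table, "__fspath__"):
            table = pd.read_csv(table)
        table = table.copy()
        table["date"] = pd.to_datetime(table["date"])
        self.table = table
        self.calls: list[str] = []

    def get_daily(self, env_id, latitude, longitude, start, end):
        self.calls.append(env_id)
        sel = self.table[
            (self.table["env_id"] == env_id)
            & (self.table["date"] >= pd.Timestamp(start))
            & (self.table["date"] <= pd.Timestamp(end))
        ].copy()
        expected = pd.date_range(start, end, freq="D")
        missing = expected.difference(pd.DatetimeIndex(sel["date"]))
        if len(missing):
            raise LookupError(
                f"weather source missing {len(missing)} day(s) for {env_id} "
                f"(first: {missing[0].date()})"
            )
        return sel.reset_index(drop=True)


def fetch_satellite_weather(
    env_info: pd.DataFrame,
    source: WeatherSource,
    env_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Fetch daily weather from a provider for the given environments.

    Only environments in ``env_ids`` (default: all of ``env_info``) are
    queried, so environments that already have in-field records are skipped.
    Provider failures are collected and reported together.
    """
    meta = env_info.set_index("env_id")
    if env_ids is None:
        env_ids = list(meta.index)
    frames, failed = [], []
    for env_id in env_ids:
        row = meta.loc[env_id]
        try:
            tab = source.get_daily(
                env_id,
                latitude=float(row["latitude"]),
                longitude=float(row["longitude"]),
                start=pd.Timestamp(row["planting_date"]),
                end=pd.Timestamp(row["harvest_date"]),
            )
        except Exception as exc:  # noqa: BLE001 - aggregate provider errors
            failed.append((env_id, str(exc)))
            continue
        tab = tab.copy()
        tab["env_id"] = env_id
        frames.append(tab)
    if failed:
        detail = "; ".join(f"{e}: {m}" for e, m in failed)
        raise RuntimeError(f"weather retrieval failed for environment(s): {detail}")
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# orchestration: daily weather -> EC matrix for a set of environments
# ---------------------------------------------------------------------------

def get_ecs(
    env_info: pd.DataFrame,
    raw_weather: pd.DataFrame | None = None,
    source: WeatherSource | None = None,
    method: str = "fixed_number",
    n_intervals: int = 10,
    interval_length: int | None = None,
    breakpoints: Mapping[str, Sequence[int]] | None = None,
    gdd_thresholds: Sequence[float] | None = None,
    t_base: float = DEFAULT_T_BASE,
    t_cap: float = DEFAULT_T_CAP,
    compute_et0: bool = True,
) -> tuple[pd.DataFrame, QCReport, dict[str, str]]:
    """Run the full weather→EC pipeline for every environment.

    Environments present in ``raw_weather`` use their in-field records; the
    remainder are fetched from ``source``.  Returns the EC matrix, the QC
    report, and a per-environment provenance tag (``in_field``/``retrieved``).
    """
    env_ids = list(env_info["env_id"])
    provenance: dict[str, str] = {}
    pieces = []
    if raw_weather is not None and len(raw_weather):
        in_field = [e for e in env_ids if e in set(raw_weather["env_id"])]
        for e in in_field:
            provenance[e] = "in_field"
        pieces.append(raw_weather[raw_weather["env_id"].isin(in_field)])
    missing = [e for e in env_ids if e not in provenance]
    if missing:
        if source is None:
            raise ValueError(
                f"no in-field weather for environments {missing} and no weather source given"
            )
        fetched = fetch_satellite_weather(env_info, source, env_ids=missing)
        for e in missing:
            provenance[e] = "retrieved"
        pieces.append(fetched)
    weather = pd.concat(pieces, ignore_index=True)

    date_ranges = {
        r["env_id"]: (pd.Timestamp(r["planting_date"]), pd.Timestamp(r["harvest_date"]))
        for _, r in env_info.iterrows()
    }
    clean, report = qc_daily_weather(weather, date_ranges=date_ranges)
    daily = compute_derived_daily(clean, env_info, t_base=t_base, t_cap=t_cap,
                                  compute_et0=compute_et0)

    intervals = {}
    for _, r in env_info.iterrows():
        env_id = r["env_id"]
        season = (pd.Timestamp(r["harvest_date"]) - pd.Timestamp(r["planting_date"])).days + 1
        kwargs: dict = {}
        if method == "user_defined":
            if breakpoints is None or env_id not in breakpoints:
                raise ValueError(f"user_defined intervals need breakpoints for {env_id}")
            kwargs["breakpoints"] = breakpoints[env_id]
        if method == "gdd_stages":
            g = daily[daily["env_id"] == env_id].sort_values("date")["gdd"].to_numpy()
            kwargs.update(gdd_thresholds=gdd_thresholds, daily_gdd=g)
        intervals[env_id] = define_intervals(
            env_id, season, method=method, n_intervals=n_intervals,
            interval_length=interval_length, **kwargs,
        )
    n_windows = {iv.n_intervals for iv in intervals.values()}
    if method in ("fixed_length", "gdd_stages") and len(n_windows) > 1:
        raise ValueError(
            f"interval method {method!r} produced unequal window counts {sorted(n_windows)} "
            "across environments; covariate columns would not align. Use fixed_number, or "
            "equalize season lengths/thresholds."
        )
    ecs = aggregate_ecs(daily, intervals)
    return ecs, report, provenance
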