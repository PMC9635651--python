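"""Synthetic MET data generator with controllable genetic, environmental and G×E signal.

Every module of the package is testable offline against data from this
generator.  It emulates two canonical trial shapes:

* a **rice-like** series — one location, five consecutive years
  (320 genotypes, 2009–2013, ~130-day seasons), and
* a **maize-like** network — six North-American locations over four years
  (2014–2017) forming 22 environments (two site-years missing, as in sparse
  trial networks).

Phenotypes follow an additive + environmental + product-interaction model

    y_ij = mu + x_i' beta  +  w_j' gamma  +  sum_k (x_i' b_k)(w_j' c_k)  +  e_ij

whose components are empirically rescaled to hit requested variance fractions,
with the full truth record (effects, realized shares) returned for oracle
tests.  Weather series are built to pass quality control with zero flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import weather as _weather
from .data_model import METData, create_met_data, make_env_id


@dataclass
class SimulationConfig:
    """Study-condition knobs for the generator (defaults = maize-like network)."""

    n_genotypes: int = 150
    p_markers: int = 400
    n_chromosomes: int = 10
    years: tuple = (2014, 2015, 2016, 2017)
    locations: tuple = ("Ames", "Champaign", "Lincoln", "Columbia", "Kingston", "Guelph")
    freq_range: tuple = (0.05, 0.5)
    v_g: float = 0.35
    v_w: float = 0.25
    v_gw: float = 0.15
    v_e: float = 0.25
    total_variance: float = 1.0
    mu: float = 100.0
    interaction_rank: int = 3
    season_length: int = 120
    trait: str = "trait"
    seed: int = 2024

    def __post_init__(self):
        fracs = np.array([self.v_g, self.v_w, self.v_gw, self.v_e])
        if (fracs < 0).any() or abs(fracs.sum() - 1.0) > 1e-8:
            raise ValueError("variance fractions must be >= 0 and sum to 1")
        if self.n_genotypes < 10:
            raise ValueError("n_genotypes must be >= 10")
        if self.p_markers < 20:
            raise ValueError("p_markers must be >= 20")


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent sub-stream per generation stage, so layers regenerate alone."""
    ints = [seed] + [ord(c) for c in stage]
    return np.random.default_rng(np.random.SeedSequence(ints))


# approximate coordinates for the built-in location names
_COORDS = {
    "Ames": (42.0, -93.6, 291.0),
    "Champaign": (40.1, -88.2, 222.0),
    "Lincoln": (40.8, -96.7, 358.0),
    "Columbia": (38.9, -92.3, 274.0),
    "Kingston": (41.5, -71.5, 30.0),
    "Guelph": (43.5, -80.2, 334.0),
    "TreintaYTres": (-33.2, -54.4, 46.0),
}


def simulate_markers(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Binomial(2, f) dosages with allele frequencies uniform in ``freq_range``."""
    rng = _stage_rng(config.seed, "markers")
    freqs = rng.uniform(*config.freq_range, size=config.p_markers)
    dosages = rng.binomial(2, freqs, size=(config.n_genotypes, config.p_markers))
    geno_ids = [f"G{i + 1:04d}" for i in range(config.n_genotypes)]
    marker_ids = [f"M{j + 1:05d}" for j in range(config.p_markers)]
    markers = pd.DataFrame(dosages.astype(np.int8), index=geno_ids, columns=marker_ids)
    markers.index.name = "genotype_id"

    chrom = np.sort(rng.integers(1, config.n_chromosomes + 1, size=config.p_markers))
    pos = np.zeros(config.p_markers)
    for c in np.unique(chrom):
        mask = chrom == c
        pos[mask] = np.sort(rng.uniform(0, 3e8, size=mask.sum()))
    genetic_map = pd.DataFrame(
        {"marker_id": marker_ids, "chromosome": chrom, "position": pos.astype(int)}
    )
    return markers, genetic_map


def simulate_env_info(config: SimulationConfig, drop_env_ids=()) -> pd.DataFrame:
    """Environment metadata for every location x year, minus ``drop_env_ids``."""
    rows = []
    for loc in config.locations:
        lat, lon, elev = _COORDS.get(loc, (40.0, -90.0, 200.0))
        for year in config.years:
            env_id = make_env_id(loc, year)
            if env_id in drop_env_ids:
                continue
            # planting around late spring in the hemisphere of the site
            start_doy = 120 if lat >= 0 else 300
            planting = pd.Timestamp(year=year, month=1, day=1) + pd.Timedelta(days=start_doy)
            harvest = planting + pd.Timedelta(days=config.season_length - 1)
            rows.append(
                {
                    "env_id": env_id,
                    "year": year,
                    "location": loc,
                    "longitude": lon,
                    "latitude": lat,
                    "elevation": elev,
                    "planting_date": planting.strftime("%Y-%m-%d"),
                    "harvest_date": harvest.strftime("%Y-%m-%d"),
                }
            )
    return pd.DataFrame(rows)


def simulate_weather(env_info: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Daily weather per environment that passes quality control with zero flags.

    Temperature is a latitude/day-of-year sinusoid plus AR(1) noise (with a
    per-environment year effect), precipitation a Bernoulli–gamma mixture,
    and radiation a sunniness fraction of the clear-sky bound for the site.
    """
    frames = []
    for _, row in env_info.sort_values("env_id").iterrows():
        env_id = row["env_id"]
        rng = _stage_rng(seed, f"weather:{env_id}")
        dates = pd.date_range(row["planting_date"], row["harvest_date"], freq="D")
        doy = dates.dayofyear.to_numpy(dtype=float)
        lat = float(row["latitude"])
        warm_peak_doy = 200.0 if lat >= 0 else 20.0  # mid-summer in each hemisphere
        seasonal = 5.0 * np.cos(2 * np.pi * (doy - warm_peak_doy) / 365.0)
        base = 24.0 - 0.35 * abs(lat)
        year_shift = rng.normal(0, 1.2)
        ar = np.zeros(len(doy))
        eps = rng.normal(0, 1.6, size=len(doy))
        for i in range(1, len(doy)):
            ar[i] = 0.7 * ar[i - 1] + eps[i]
        tmean = np.clip(base + seasonal + year_shift + ar, -30.0, 45.0)
        half_range = rng.uniform(3.0, 7.0, size=len(doy))
        tmin = tmean - half_range
        tmax = tmean + half_range

        wet = rng.random(len(doy)) < 0.30
        precip = np.where(wet, rng.gamma(2.0, 5.0, size=len(doy)), 0.0)
        precip = np.clip(precip, 0.0, 400.0)

        ra = _weather.extraterrestrial_radiation(lat, doy)
        rso = (0.75 + 2e-5 * float(row.get("elevation", 0.0))) * ra
        sunniness = np.clip(rng.beta(4, 2, size=len(doy)) - 0.25 * wet, 0.15, 0.98)
        radiation = np.maximum(rso * sunniness, 0.1)

        wind = np.clip(rng.lognormal(mean=0.6, sigma=0.35, size=len(doy)), 0.2, 15.0)
        rh_base = np.clip(rng.normal(65, 8, size=len(doy)) + 12 * wet, 20.0, 98.0)

        frames.append(
            pd.DataFrame(
                {
                    "env_id": env_id,
                    "date": dates,
                    "tmin": np.round(tmin, 2),
                    "tmax": np.round(tmax, 2),
                    "tmean": np.round(tmean, 2),
                    "precipitation": np.round(precip, 2),
                    "solar_radiation": np.round(radiation, 2),
                    "wind_speed_2m": np.round(wind, 2),
                    "relative_humidity": np.round(rh_base, 1),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _center_scale(mat: np.ndarray) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    mu = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (mat - mu) / sd


def _scale_to_variance(x: np.ndarray, target_var: float) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        if target_var > 0:
            raise ValueError("cannot scale a constant component to positive variance")
        return x
    return x * np.sqrt(target_var) / sd


def simulate_phenotypes(
    markers: pd.DataFrame,
    ecs: pd.DataFrame,
    config: SimulationConfig,
    seed: int | None = None,
    pheno_index: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate trait values on a (genotype x environment) grid with known truth.

    Each component (genetic, environmental, interaction, noise) is rescaled on
    the realized design so its variance share matches the requested fraction.
    Returns the phenotype table and a truth record with all effects and
    realized shares.
    """
    seed = config.seed if seed is None else seed
    rng = _stage_rng(seed, "phenotypes")
    env_ids = list(ecs.index)
    if config.v_gw > 0 and len(env_ids) < 2:
        raise ValueError("G x E variance requested with a single environment")

    if pheno_index is None:
        pheno_index = pd.DataFrame(
            [(g, e) for g in markers.index for e in env_ids],
            columns=["genotype_id", "env_id"],
        )
    geno_pos = pd.Index(markers.index).get_indexer(pheno_index["genotype_id"])
    env_pos = pd.Index(env_ids).get_indexer(pheno_index["env_id"])

    X = _center_scale(markers.to_numpy())
    W = _center_scale(ecs.to_numpy())
    p, q = X.shape[1], W.shape[1]
    total = config.total_variance

    beta = rng.normal(0, 1, size=p)
    gamma = rng.normal(0, 1, size=q)
    g_geno = X @ beta / np.sqrt(p)
    w_env = W @ gamma / np.sqrt(q)
    g_obs = _scale_to_variance(g_geno[geno_pos], config.v_g * total)
    w_obs = _scale_to_variance(w_env[env_pos], config.v_w * total)

    gw_obs = np.zeros(len(pheno_index))
    b_k = rng.normal(0, 1, size=(config.interaction_rank, p))
    c_k = rng.normal(0, 1, size=(config.interaction_rank, q))
    if config.v_gw > 0:
        raw = np.zeros(len(pheno_index))
        for k in range(config.interaction_rank):
            gs = (X @ b_k[k]) / np.sqrt(p)
            ws = (W @ c_k[k]) / np.sqrt(q)
            raw += gs[geno_pos] * ws[env_pos]
        gw_obs = _scale_to_variance(raw, config.v_gw * total)

    e_obs = _scale_to_variance(rng.normal(0, 1, size=len(pheno_index)), config.v_e * total) \
        if config.v_e > 0 else np.zeros(len(pheno_index))

    y = config.mu + g_obs + w_obs + gw_obs + e_obs

    pheno = pheno_index.copy()
    loc_year = pheno["env_id"].str.rsplit("_", n=1, expand=True)
    pheno["location"] = loc_year[0]
    pheno["year"] = loc_year[1].astype(int)
    pheno[config.trait] = y
    pheno = pheno[["genotype_id", "year", "location", config.trait]]

    var_y = y.var(ddof=0)
    truth = {
        "mu": config.mu,
        "beta": beta,
        "gamma": gamma,
        "interaction_b": b_k,
        "interaction_c": c_k,
        "g_obs": g_obs,
        "w_obs": w_obs,
        "gw_obs": gw_obs,
        "e_obs": e_obs,
        "realized_shares": {
            "v_g": g_obs.var(ddof=0) / var_y,
            "v_w": w_obs.var(ddof=0) / var_y,
            "v_gw": gw_obs.var(ddof=0) / var_y,
            "v_e": e_obs.var(ddof=0) / var_y,
        },
    }
    return pheno, truth


def simulate_met_data(
    config: SimulationConfig | None = None,
    drop_env_ids=(),
    compute_ecs: bool = True,
    ec_options: dict | None = None,
) -> tuple[METData, dict]:
    """End-to-end synthetic METData: markers → weather → ECs → phenotypes.

    Daily weather comes from :func:`simulate_weather` served through a
    file-backed weather source, so the assembled object exercises the same
    retrieval path as real satellite-based runs.
    """
    config = config or SimulationConfig()
    markers, genetic_map = simulate_markers(config)
    env_info = simulate_env_info(config, drop_env_ids=drop_env_ids)
    wx = simulate_weather(env_info, config.seed)
    source = _weather.FileWeatherSource(wx)
    ecs, _, _ = _weather.get_ecs(env_info, source=source, **(ec_options or {}))
    pheno, truth = simulate_phenotypes(markers, ecs, config)
    met = create_met_data(
        markers,
        genetic_map,
        pheno,
        env_info,
        climate_variables=None if compute_ecs else ecs.reset_index(),
        compute_ecs=compute_ecs,
        ec_options=ec_options,
        weather_source=source,
        seed=config.seed,
    )
    return met, truth


def rice_like_config(seed: int = 2024, **overrides) -> SimulationConfig:
    """Single location, five years, 320 inbred lines (rice-series shape)."""
    defaults = dict(
        n_genotypes=320,
        p_markers=300,
        years=(2009, 2010, 2011, 2012, 2013),
        locations=("TreintaYTres",),
        v_g=0.4,
        v_w=0.25,
        v_gw=0.1,
        v_e=0.25,
        season_length=130,
        trait="grain_yield",
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def g2f_like_config(seed: int = 2024, **overrides) -> SimulationConfig:
    """Six locations x four years = 22 environments (two site-years missing)."""
    defaults = dict(
        n_genotypes=150,
        p_markers=400,
        years=(2014, 2015, 2016, 2017),
        locations=("Ames", "Champaign", "Lincoln", "Columbia", "Kingston", "Guelph"),
        v_g=0.35,
        v_w=0.25,
        v_gw=0.15,
        v_e=0.25,
        season_length=120,
        trait="grain_yield",
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


#: site-years absent from the maize-like network (24 cells -> 22 environments)
G2F_DROPPED_ENVS = ("Guelph_2014", "Kingston_2016")


def make_rice_like(seed: int = 2024, **overrides) -> tuple[METData, dict]:
    return simulate_met_data(rice_like_config(seed, **overrides))


def make_g2f_like(seed: int = 2024, **overrides) -> tuple[METData, dict]:
    return simulate_met_data(g2f_like_config(seed, **overrides),
                             drop_env_ids=G2F_DROPPED_ENVS)
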