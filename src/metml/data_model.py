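"""The MET data container: validated genotype, phenotype and environment tables.

:func:`create_met_data` is the entry point of the pipeline.  It cross-checks
the user tables (marker dosages, genetic map, phenotypes, environment
metadata), optionally computes environmental covariates from daily weather,
and returns a :class:`METData` object that every other module consumes.

Conventions
-----------
* genotypes are coded as minor-allele dosages in {0, 1, 2}, imputed beforehand;
* an environment is a ``location_year`` combination, e.g. ``Ames_2015``;
* dates are ISO-8601 (``YYYY-MM-DD``); other dialects are rejected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import weather as _weather


def make_env_id(location, year) -> str:
    return f"{location}_{int(year)}"


def _parse_iso_date(value, what: str) -> pd.Timestamp:
    try:
        return pd.to_datetime(value, format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValueError(
            f"{what}: dates must be ISO-8601 (YYYY-MM-DD), got {value!r}"
        ) from exc


# ---------------------------------------------------------------------------
# table validators
# ---------------------------------------------------------------------------

def validate_markers(markers: pd.DataFrame) -> pd.DataFrame:
    """Validate a genotype dosage matrix (rows = genotypes, columns = markers)."""
    if markers.index.name != "genotype_id":
        if "genotype_id" in markers.columns:
            markers = markers.set_index("genotype_id")
        else:
            markers = markers.copy()
            markers.index.name = "genotype_id"
    markers.index = markers.index.astype(str)
    if markers.index.duplicated().any():
        dup = markers.index[markers.index.duplicated()][0]
        raise ValueError(f"duplicate genotype_id in marker matrix: {dup!r}")
    if markers.shape[1] < 1:
        raise ValueError("marker matrix needs at least one marker")
    values = markers.to_numpy()
    if np.isnan(values.astype(float)).any():
        raise ValueError(
            "marker matrix contains missing values; genotypes must be imputed "
            "before building the MET data object"
        )
    if not np.isin(values, (0, 1, 2)).all():
        bad = values[~np.isin(values, (0, 1, 2))][0]
        raise ValueError(f"marker dosages must be coded 0/1/2; found {bad!r}")
    return markers.astype(np.int8)


def validate_map(genetic_map: pd.DataFrame, markers: pd.DataFrame) -> pd.DataFrame:
    cols = {"marker_id", "chromosome", "position"}
    if not cols.issubset(genetic_map.columns):
        raise ValueError(f"genetic map needs columns {sorted(cols)}")
    genetic_map = genetic_map.copy()
    genetic_map["marker_id"] = genetic_map["marker_id"].astype(str)
    if (genetic_map["position"] < 0).any():
        raise ValueError("map positions must be non-negative")
    map_ids = set(genetic_map["marker_id"])
    marker_ids = set(map(str, markers.columns))
    if map_ids != marker_ids:
        extra = sorted(map_ids - marker_ids)[:3]
        missing = sorted(marker_ids - map_ids)[:3]
        raise ValueError(
            f"map and marker matrix disagree (map-only: {extra}, matrix-only: {missing})"
        )
    return genetic_map


def validate_env_info(env_info: pd.DataFrame) -> pd.DataFrame:
    required = {"year", "location", "longitude", "latitude", "planting_date", "harvest_date"}
    if not required.issubset(env_info.columns):
        raise ValueError(f"env_info needs columns {sorted(required)}")
    env_info = env_info.copy()
    env_info["year"] = env_info["year"].astype(int)
    env_info["location"] = env_info["location"].astype(str)
    if "env_id" not in env_info.columns:
        env_info["env_id"] = [
            make_env_id(l, y) for l, y in zip(env_info["location"], env_info["year"])
        ]
    env_info["env_id"] = env_info["env_id"].astype(str)
    if env_info["env_id"].duplicated().any():
        dup = env_info.loc[env_info["env_id"].duplicated(), "env_id"].iloc[0]
        raise ValueError(f"duplicate environment id {dup!r} (location_year collision)")
    for col in ("planting_date", "harvest_date"):
        env_info[col] = [_parse_iso_date(v, col) for v in env_info[col]]
    if (env_info["harvest_date"] <= env_info["planting_date"]).any():
        bad = env_info.loc[env_info["harvest_date"] <= env_info["planting_date"], "env_id"].iloc[0]
        raise ValueError(f"{bad}: harvest_date must be after planting_date")
    if (env_info["latitude"].abs() > 90).any() or (env_info["longitude"].abs() > 180).any():
        raise ValueError("latitude must be in [-90, 90], longitude in [-180, 180]")
    return env_info.reset_index(drop=True)


def validate_pheno(
    pheno: pd.DataFrame,
    markers: pd.DataFrame,
    env_info: pd.DataFrame,
    require_traits: bool = True,
) -> pd.DataFrame:
    required = {"genotype_id", "year", "location"}
    if not required.issubset(pheno.columns):
        raise ValueError(f"pheno needs columns {sorted(required)}")
    pheno = pheno.copy()
    pheno["genotype_id"] = pheno["genotype_id"].astype(str)
    pheno["year"] = pheno["year"].astype(int)
    pheno["location"] = pheno["location"].astype(str)
    pheno["env_id"] = [
        make_env_id(l, y) for l, y in zip(pheno["location"], pheno["year"])
    ]
    unknown_geno = set(pheno["genotype_id"]) - set(markers.index)
    if unknown_geno:
        raise ValueError(
            f"pheno references genotype(s) absent from the marker matrix: "
            f"{sorted(unknown_geno)[:5]}"
        )
    unknown_env = set(pheno["env_id"]) - set(env_info["env_id"])
    if unknown_env:
        raise ValueError(
            f"pheno references (year, location) pairs absent from env_info: "
            f"{sorted(unknown_env)[:5]}"
        )
    traits = trait_columns(pheno)
    if require_traits and not traits:
        raise ValueError("pheno carries no trait columns")
    dup = pheno.duplicated(subset=["genotype_id", "env_id"])
    if dup.any():
        first = pheno.loc[dup, ["genotype_id", "env_id"]].iloc[0]
        raise ValueError(
            f"duplicate phenotype record for genotype {first['genotype_id']!r} "
            f"in {first['env_id']!r}"
        )
    return pheno.reset_index(drop=True)


def trait_columns(pheno: pd.DataFrame) -> list[str]:
    meta = {"genotype_id", "year", "location", "env_id"}
    return [c for c in pheno.columns if c not in meta]


# ---------------------------------------------------------------------------
# container
# ---------------------------------------------------------------------------

@dataclass
class METData:
    """Validated multi-environment-trial data bundle (output of step 1).

    Attributes
    ----------
    markers : genotype x marker dosage matrix (index ``genotype_id``).
    genetic_map : marker_id / chromosome / position table.
    pheno : one row per (genotype, environment) observation with trait columns.
    env_info : per-environment metadata (coordinates, season dates).
    ecs : environments x named day-interval covariates (may be empty until computed).
    soil : optional environments x soil-variable numeric table.
    is_test_set : when true, ``pheno`` lists prediction targets without traits.
    provenance : seeds, aggregation method and weather source per environment.
    """

    markers: pd.DataFrame
    genetic_map: pd.DataFrame
    pheno: pd.DataFrame
    env_info: pd.DataFrame
    ecs: pd.DataFrame = field(default_factory=pd.DataFrame)
    soil: pd.DataFrame | None = None
    is_test_set: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.ecs):
            unknown = set(self.ecs.index) - set(self.env_info["env_id"])
            if unknown:
                raise ValueError(f"EC matrix has rows for unknown environments: {sorted(unknown)[:5]}")
        if not self.is_test_set and len(self.pheno) == 0:
            raise ValueError("training METData must have phenotypes (or set is_test_set)")

    @property
    def env_ids(self) -> list[str]:
        return list(self.env_info["env_id"])

    @property
    def traits(self) -> list[str]:
        return trait_columns(self.pheno)

    @property
    def n_genotypes(self) -> int:
        return self.markers.shape[0]

    @property
    def n_markers(self) -> int:
        return self.markers.shape[1]


def create_met_data(
    markers: pd.DataFrame,
    genetic_map: pd.DataFrame,
    pheno: pd.DataFrame,
    env_info: pd.DataFrame,
    climate_variables: pd.DataFrame | None = None,
    raw_weather: pd.DataFrame | None = None,
    soil: pd.DataFrame | None = None,
    compute_ecs: bool = False,
    ec_options: dict | None = None,
    weather_source: _weather.WeatherSource | None = None,
    as_test_set: bool = False,
    seed: int | None = None,
) -> METData:
    """Assemble and validate a :class:`METData` object (pipeline step 1).

    Environmental covariates come from exactly one of two modes: either
    ``climate_variables`` provides a ready environments x covariates table used
    verbatim, or ``compute_ecs=True`` derives them from daily weather —
    in-field records (``raw_weather``) where available, the ``weather_source``
    provider for the remaining environments.

    Raises ``ValueError`` on referential-integrity failures (unknown genotype
    ids, missing marker values, unknown environments) and when both EC modes
    are requested at once.
    """
    if climate_variables is not None and compute_ecs:
        raise ValueError(
            "climate_variables and compute_ecs=True are mutually exclusive: "
            "either provide covariates or let the package compute them"
        )
    markers = validate_markers(markers)
    genetic_map = validate_map(genetic_map, markers)
    env_info = validate_env_info(env_info)
    pheno = validate_pheno(pheno, markers, env_info, require_traits=not as_test_set)

    ec_options = dict(ec_options or {})
    provenance: dict = {
        "seed": seed,
        "ec_source": None,
        "aggregation_method": None,
        "weather_source": {},
    }
    ecs = pd.DataFrame()
    qc_report = None
    if climate_variables is not None:
        ecs = climate_variables.copy()
        if "env_id" in ecs.columns:
            ecs = ecs.set_index("env_id")
        ecs.index = ecs.index.astype(str)
        missing = set(env_info["env_id"]) - set(ecs.index)
        if missing:
            raise ValueError(f"climate_variables lacks rows for environments: {sorted(missing)[:5]}")
        if ecs.isna().any().any():
            raise ValueError("climate_variables contains missing cells")
        provenance["ec_source"] = "provided"
        provenance["weather_source"] = {e: "provided" for e in env_info["env_id"]}
    elif compute_ecs:
        ecs, qc_report, wx_prov = _weather.get_ecs(
            env_info,
            raw_weather=raw_weather,
            source=weather_source,
            **ec_options,
        )
        provenance["ec_source"] = "computed"
        provenance["aggregation_method"] = ec_options.get("method", "fixed_number")
        provenance["weather_source"] = wx_prov

    if soil is not None:
        soil = soil.copy()
        if "env_id" in soil.columns:
            soil = soil.set_index("env_id")
        soil.index = soil.index.astype(str)

    met = METData(
        markers=markers,
        genetic_map=genetic_map,
        pheno=pheno,
        env_info=env_info,
        ecs=ecs,
        soil=soil,
        is_test_set=as_test_set,
        provenance=provenance,
    )
    met.qc_report = qc_report
    return met


# ---------------------------------------------------------------------------
# summary
# ---------------------------------------------------------------------------

@dataclass
class METDataSummary:
    n_genotypes: int
    n_markers: int
    n_environments: int
    n_years: int
    n_locations: int
    traits: list[str]
    n_ecs: int
    trait_missingness: dict[str, float]
    soil: str

    def __str__(self) -> str:
        lines = [
            "MET data summary",
            f"  genotypes:    {self.n_genotypes} ({self.n_markers} markers)",
            f"  environments: {self.n_environments} "
            f"({self.n_years} years x {self.n_locations} locations)",
            f"  covariates:   {self.n_ecs} environmental covariates",
            f"  soil:         {self.soil}",
            f"  traits:       {len(self.traits)}",
        ]
        for t in self.traits:
            lines.append(f"    {t}: {self.trait_missingness[t]:.1%} missing")
        return "\n".join(lines)


def summarize_met_data(met: METData) -> METDataSummary:
    """Counts of genotypes, environments, traits and covariates in a METData."""
    traits = met.traits
    missing = {
        t: float(met.pheno[t].isna().mean()) if len(met.pheno) else float("nan")
        for t in traits
    }
    soil = "absent" if met.soil is None or met.soil.empty else f"{met.soil.shape[1]} variables"
    return METDataSummary(
        n_genotypes=met.n_genotypes,
        n_markers=met.n_markers,
        n_environments=len(met.env_info),
        n_years=met.env_info["year"].nunique(),
        n_locations=met.env_info["location"].nunique(),
        traits=traits,
        n_ecs=met.ecs.shape[1] if len(met.ecs) else 0,
        trait_missingness=missing,
        soil=soil,
    )


# ---------------------------------------------------------------------------
# file layout
# ---------------------------------------------------------------------------

_FILES = {
    "markers": "geno.csv",
    "genetic_map": "map.csv",
    "pheno": "pheno.csv",
    "env_info": "env_info.csv",
    "ecs": "ecs.csv",
    "soil": "soil.csv",
}


def write_met_data(met: METData, directory) -> Path:
    """Write a METData to its plain-CSV directory layout (round-trip safe)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    met.markers.to_csv(directory / _FILES["markers"])
    met.genetic_map.to_csv(directory / _FILES["genetic_map"], index=False)
    pheno = met.pheno.drop(columns=["env_id"], errors="ignore")
    pheno.to_csv(directory / _FILES["pheno"], index=False)
    env_info = met.env_info.copy()
    for col in ("planting_date", "harvest_date"):
        env_info[col] = env_info[col].dt.strftime("%Y-%m-%d")
    env_info.to_csv(directory / _FILES["env_info"], index=False)
    if len(met.ecs):
        met.ecs.to_csv(directory / _FILES["ecs"], float_format="%.17g")
    if met.soil is not None and len(met.soil):
        met.soil.to_csv(directory / _FILES["soil"])
    meta = {"is_test_set": met.is_test_set, "provenance": met.provenance}
    (directory / "metadata.json").write_text(json.dumps(meta, indent=2, default=str))
    return directory


def read_met_data(directory) -> METData:
    """Re-assemble a METData from the directory layout written by :func:`write_met_data`."""
    directory = Path(directory)
    markers = pd.read_csv(directory / _FILES["markers"], index_col="genotype_id")
    markers.index = markers.index.astype(str)
    genetic_map = pd.read_csv(directory / _FILES["genetic_map"])
    pheno = pd.read_csv(directory / _FILES["pheno"])
    env_info = pd.read_csv(directory / _FILES["env_info"])
    ecs_path = directory / _FILES["ecs"]
    soil_path = directory / _FILES["soil"]
    climate = None
    if ecs_path.exists():
        climate = pd.read_csv(ecs_path, index_col="env_id")
    soil = pd.read_csv(soil_path, index_col="env_id") if soil_path.exists() else None
    meta = json.loads((directory / "metadata.json").read_text())
    met = create_met_data(
        markers,
        genetic_map,
        pheno,
        env_info,
        climate_variables=climate,
        soil=soil,
        as_test_set=meta.get("is_test_set", False),
    )
    met.provenance = meta.get("provenance", met.provenance)
    return met


def read_vcf_dosages(path) -> pd.DataFrame:
    """Read a VCF and return a genotype x marker dosage matrix (ALT allele count).

    Convenience ingestion path; requires ``cyvcf2``.  Missing genotypes are
    rejected, matching the imputed-beforehand contract.
    """
    from cyvcf2 import VCF  # local import: optional dependency

    vcf = VCF(str(path), gts012=True)  # gt_types 0/1/2 = ALT dosage, 3 = missing
    samples = list(vcf.samples)
    names, columns = [], []
    for variant in vcf:
        name = variant.ID or f"{variant.CHROM}_{variant.POS}"
        gt = variant.gt_types.copy()
        if (gt == 3).any():
            raise ValueError(f"VCF variant {name} has missing genotypes; impute first")
        names.append(name)
        columns.append(gt.astype(np.int8))
    mat = pd.DataFrame(np.column_stack(columns), index=samples, columns=names)
    mat.index.name = "genotype_id"
    return mat
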