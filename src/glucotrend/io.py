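"""Delimited-text interfaces: survey datapoint tables, covariates,
populations, the standard-population fixture, and YAML run configuration.

All tables are UTF-8 CSV with a header row; age intervals are encoded as two
integer columns ``age_lo``/``age_hi``, half-open.
"""

from __future__ import annotations

import dataclasses
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .types import PairedObservation, StandardPopulation, SurveyDatapoint

DATAPOINT_COLUMNS = [
    "study_id", "country_id", "mid_year", "sex", "age_lo", "age_hi",
    "n_examined", "prevalence", "se", "definition", "scope", "urbanicity",
    "study_urban_fraction",
]


def datapoints_to_frame(datapoints) -> pd.DataFrame:
    rows = [dataclasses.asdict(d) for d in datapoints]
    cols = DATAPOINT_COLUMNS + (
        ["primary_prevalence"]
        if rows and "primary_prevalence" in rows[0]
        else []
    )
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows)[cols]


def frame_to_datapoints(df: pd.DataFrame):
    paired = "primary_prevalence" in df.columns
    cls = PairedObservation if paired else SurveyDatapoint
    out = []
    for rec in df.to_dict("records"):
        kwargs = {k: rec[k] for k in DATAPOINT_COLUMNS}
        kwargs["mid_year"] = int(kwargs["mid_year"])
        kwargs["age_lo"] = int(kwargs["age_lo"])
        kwargs["age_hi"] = int(kwargs["age_hi"])
        kwargs["n_examined"] = int(kwargs["n_examined"])
        if paired:
            kwargs["primary_prevalence"] = float(rec["primary_prevalence"])
        out.append(cls(**kwargs))
    return out


def write_datapoints(path, datapoints) -> None:
    datapoints_to_frame(datapoints).to_csv(path, index=False)


def read_datapoints(path):
    return frame_to_datapoints(pd.read_csv(path))


def write_covariates(path, covariates: pd.DataFrame) -> None:
    covariates.to_csv(path, index=False)


def read_covariates(path) -> pd.DataFrame:
    return pd.read_csv(path)


def population_to_frame(world) -> pd.DataFrame:
    """Long-format population table from a WorldTruth."""
    from .types import AGE_GROUPS

    rows = []
    for ci, cid in enumerate(world.hierarchy.country_ids):
        for ti, yr in enumerate(world.years):
            for si, sex in enumerate(world.sexes):
                for ai, (lo, hi) in enumerate(AGE_GROUPS):
                    rows.append(
                        (cid, int(yr), sex, lo, hi, world.population[ci, ti, si, ai])
                    )
    return pd.DataFrame(
        rows, columns=["country_id", "year", "sex", "age_lo", "age_hi", "population"]
    )


def write_population(path, world) -> None:
    population_to_frame(world).to_csv(path, index=False)


def read_population(path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_standard_population(path=None) -> StandardPopulation:
    """Load standard-population weights from CSV; defaults to the packaged
    WHO world standard restricted to adults (weights renormalised >= 18)."""
    if path is None:
        ref = resources.files("glucotrend.data") / "who_standard_population_adult.csv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p)
        provenance = "WHO world standard population, adults 18+ (packaged)"
    else:
        df = pd.read_csv(path)
        provenance = str(path)
    weights = {
        (int(r.age_lo), int(r.age_hi)): float(r.weight) for r in df.itertuples()
    }
    return StandardPopulation(weights, provenance=provenance)


def load_yaml_config(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ValueError(f"config {path} must be a mapping")
    return doc


def world_config_from_dict(doc: dict):
    """Build a WorldConfig from the ``world:`` section of a config document."""
    from .synthetic import WorldConfig

    fields = {f.name for f in dataclasses.fields(WorldConfig)}
    unknown = set(doc) - fields
    if unknown:
        raise ValueError(f"unknown world config keys: {sorted(unknown)}")
    return WorldConfig(**doc)


def population_array(
    population: pd.DataFrame, countries, years, sexes, age_groups
) -> np.ndarray:
    """Pivot a long population table to a (country, year, sex, age) array."""
    idx = population.set_index(["country_id", "year", "sex", "age_lo"])[
        "population"
    ]
    out = np.zeros((len(countries), len(years), len(sexes), len(age_groups)))
    for ci, c in enumerate(countries):
        for ti, y in enumerate(years):
            for si, s in enumerate(sexes):
                for ai, (lo, _) in enumerate(age_groups):
                    out[ci, ti, si, ai] = idx.loc[(c, int(y), s, lo)]
    return out
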