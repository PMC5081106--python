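"""Configured, logged, resumable pipeline: simulate -> cross-walk -> fit ->
derive -> validate.

Every stage declares its input and output files; the run manifest records
the stage list, the configuration hash, the seed and package versions, so a
rerun with an identical configuration reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .crosswalk import filter_min_sample, fit_crosswalk, harmonise
from .io import (
    load_standard_population,
    load_yaml_config,
    read_covariates,
    read_datapoints,
    read_population,
    write_covariates,
    write_datapoints,
    write_population,
)
from .model import ModelConfig, PosteriorDraws, fit_model
from .outputs import assess_target, decompose_change, summary_table
from .synthetic import (
    WorldConfig,
    build_world,
    make_survey_plan,
    simulate_paired_observations,
    simulate_surveys,
)
from .types import PRIMARY_FPG7, HierarchySpec
from .validation import evaluate_holdout, make_holdout_split

logger = logging.getLogger(__name__)

STAGES = ("simulate", "crosswalk", "fit", "derive", "validate")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str, log_path=None):
        self.stage = stage
        self.log_path = log_path
        super().__init__(
            f"stage {stage!r} failed: {message}"
            + (f" (see log at {log_path})" if log_path else "")
        )


@dataclass
class RunConfig:
    """Pipeline run configuration; see the packaged schema documentation."""

    outdir: Path
    seed: int = 0
    reduced: bool = True
    stages: dict = field(
        default_factory=lambda: {s: True for s in STAGES}
    )
    world: dict = field(default_factory=dict)
    plan: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)
    holdout: dict = field(
        default_factory=lambda: {"scheme": "random_fraction", "fraction": 0.2}
    )

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        doc = load_yaml_config(path)
        doc.update(overrides)
        doc["outdir"] = Path(doc["outdir"])
        stages = {s: True for s in STAGES}
        stages.update(doc.get("stages", {}))
        doc["stages"] = stages
        return cls(**doc)

    def config_hash(self) -> str:
        doc = dataclasses.asdict(self)
        doc["outdir"] = str(doc["outdir"])
        return hashlib.sha256(
            json.dumps(doc, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _reduced_model_kwargs() -> dict:
    return {"chains": 2, "burnin": 300, "draws": 800}


def _reduced_plan_kwargs() -> dict:
    return {"studies_per_country": 6}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order and return the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "pipeline.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    )
    root = logging.getLogger("glucotrend")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    manifest = {
        "config_hash": config.config_hash(),
        "seed": int(config.seed),
        "version": __version__,
        "stages": [],
    }
    state: dict = {}
    try:
        for stage in STAGES:
            if not config.stages.get(stage, False):
                continue
            t0 = time.time()
            logger.info("stage %s: start", stage)
            try:
                entry = _STAGE_FUNCS[stage](config, outdir, state)
            except Exception as exc:
                raise PipelineError(stage, str(exc), log_path) from exc
            logger.info(
                "stage %s: done in %.1fs (%d outputs)",
                stage, time.time() - t0, len(entry["outputs"]),
            )
            entry["stage"] = stage
            entry["config_hash"] = config.config_hash()
            entry["seed"] = int(config.seed)
            manifest["stages"].append(entry)
        with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest
    finally:
        root.removeHandler(handler)
        handler.close()


def _stage_simulate(config: RunConfig, outdir: Path, state: dict) -> dict:
    wc = WorldConfig(**config.world)
    if config.reduced and "sexes" not in config.world:
        wc.sexes = ("female",)
    world = build_world(wc, seed=config.seed)
    plan_kwargs = dict(_reduced_plan_kwargs() if config.reduced else {})
    plan_kwargs.update(config.plan)
    plan = make_survey_plan(world, seed=config.seed + 1, **plan_kwargs)
    datapoints = simulate_surveys(world, plan, seed=config.seed + 2)

    paths = {
        "datapoints": outdir / "datapoints.csv",
        "covariates": outdir / "covariates.csv",
        "population": outdir / "population.csv",
        "hierarchy": outdir / "hierarchy.csv",
    }
    write_datapoints(paths["datapoints"], datapoints)
    write_covariates(paths["covariates"], world.covariates)
    write_population(paths["population"], world)
    pd.DataFrame(
        world.hierarchy.countries,
        columns=["country_id", "region_id", "super_region_id"],
    ).to_csv(paths["hierarchy"], index=False)

    # paired observations for every non-primary definition in the plan
    defs = sorted({s.definition for s in plan.studies if s.definition != PRIMARY_FPG7})
    for d in defs:
        paired = simulate_paired_observations(
            600, d, dmap=world.config.definition_maps[d], seed=config.seed + 3
        )
        p = outdir / f"paired_{d}.csv"
        write_datapoints(p, paired)
        paths[f"paired_{d}"] = p
    logger.info("simulated %d datapoints from %d studies", len(datapoints), len(plan.studies))
    state["world"] = world
    state["definitions"] = defs
    return {"inputs": [], "outputs": sorted(str(p) for p in paths.values())}


def _stage_crosswalk(config: RunConfig, outdir: Path, state: dict) -> dict:
    dp_path = outdir / "datapoints.csv"
    datapoints = filter_min_sample(read_datapoints(dp_path))
    defs = state.get("definitions")
    if defs is None:
        defs = sorted(
            {
                d.definition for d in datapoints
                if d.definition != PRIMARY_FPG7
            }
        )
    inputs = [str(dp_path)]
    outputs = []
    models = {}
    for d in defs:
        paired_path = outdir / f"paired_{d}.csv"
        paired = read_datapoints(paired_path)
        inputs.append(str(paired_path))
        model = fit_crosswalk(paired, d)
        models[d] = model
        mp = outdir / f"crosswalk_{d}.json"
        mp.write_text(model.to_json(), encoding="utf-8")
        outputs.append(str(mp))
    harmonised = harmonise(datapoints, models)
    hp = outdir / "harmonised.csv"
    write_datapoints(hp, harmonised)
    outputs.append(str(hp))
    logger.info(
        "harmonised %d datapoints (%d cross-walk models)", len(harmonised), len(models)
    )
    return {"inputs": inputs, "outputs": sorted(outputs)}


def _hierarchy_from_csv(path) -> HierarchySpec:
    df = pd.read_csv(path)
    return HierarchySpec(
        tuple(
            (r.country_id, r.region_id, r.super_region_id)
            for r in df.itertuples()
        )
    )


def _stage_fit(config: RunConfig, outdir: Path, state: dict) -> dict:
    inputs = [
        outdir / "harmonised.csv", outdir / "covariates.csv",
        outdir / "population.csv", outdir / "hierarchy.csv",
    ]
    datapoints = read_datapoints(inputs[0])
    covariates = read_covariates(inputs[1])
    population = read_population(inputs[2])
    hierarchy = _hierarchy_from_csv(inputs[3])
    years = sorted(covariates["year"].unique())
    kwargs = dict(_reduced_model_kwargs() if config.reduced else {})
    kwargs.update(config.model)
    mc = ModelConfig(
        hierarchy=hierarchy, year_start=int(years[0]), year_end=int(years[-1]),
        seed=config.seed + 4, **kwargs,
    )
    draws = fit_model(datapoints, covariates, population, mc)
    dz = outdir / "draws.zarr"
    draws.save(dz)
    state["draws"] = draws
    state["model_config"] = mc
    return {
        "inputs": [str(p) for p in inputs],
        "outputs": [str(dz)],
    }


def _load_draws(outdir: Path, state: dict) -> PosteriorDraws:
    if "draws" in state:
        return state["draws"]
    return PosteriorDraws.load(outdir / "draws.zarr")


def _stage_derive(config: RunConfig, outdir: Path, state: dict) -> dict:
    draws = _load_draws(outdir, state)
    weights = load_standard_population()
    summary = summary_table(draws, weights)
    sp = outdir / "summary.csv"
    summary.to_csv(sp, index=False)

    outputs = [str(sp)]
    pop = draws.population
    if pop is not None:
        y0, y1 = int(draws.years[0]), int(draws.years[-1])
        decomp = {}
        for si, sex in enumerate(draws.sexes):
            mean_prev = draws.prevalence[:, :, :, si, :].mean(axis=0)
            p0 = mean_prev[:, 0, :].ravel()
            p1 = mean_prev[:, -1, :].ravel()
            n0 = pop[:, 0, si, :].ravel()
            n1 = pop[:, -1, si, :].ravel()
            res = decompose_change(p0, p1, n0, n1)
            decomp[sex] = {
                "year0": y0, "year1": y1,
                "total_change": res.total_change,
                "growth_ageing": res.component_growth_ageing,
                "prevalence": res.component_prevalence,
                "interaction": res.component_interaction,
                "shares_pct": res.shares,
            }
        dp = outdir / "decomposition.json"
        dp.write_text(json.dumps(decomp, indent=2), encoding="utf-8")
        outputs.append(str(dp))

        targets = {}
        for sex in draws.sexes:
            ta = assess_target(draws, "world", sex, weights)
            targets[sex] = {
                "unit": "world",
                "probability_met": ta.probability_met,
                "projected_2025_mean": float(ta.projected_2025.mean()),
                "baseline_2010_mean": float(ta.baseline_2010.mean()),
            }
        tp = outdir / "target.json"
        tp.write_text(json.dumps(targets, indent=2), encoding="utf-8")
        outputs.append(str(tp))
    return {
        "inputs": [str(outdir / "draws.zarr")],
        "outputs": sorted(outputs),
    }


def _stage_validate(config: RunConfig, outdir: Path, state: dict) -> dict:
    inputs = [
        outdir / "harmonised.csv", outdir / "covariates.csv",
        outdir / "population.csv", outdir / "hierarchy.csv",
    ]
    datapoints = read_datapoints(inputs[0])
    covariates = read_covariates(inputs[1])
    population = read_population(inputs[2])
    hierarchy = _hierarchy_from_csv(inputs[3])
    train, test = make_holdout_split(
        datapoints,
        scheme=config.holdout.get("scheme", "random_fraction"),
        fraction=float(config.holdout.get("fraction", 0.2)),
        seed=config.seed + 5,
    )
    years = sorted(covariates["year"].unique())
    kwargs = dict(_reduced_model_kwargs() if config.reduced else {})
    kwargs.update(config.model)
    mc = ModelConfig(
        hierarchy=hierarchy, year_start=int(years[0]), year_end=int(years[-1]),
        seed=config.seed + 6, **kwargs,
    )
    draws = fit_model(train, covariates, population, mc)
    report = evaluate_holdout(draws, test)
    rp = outdir / "validation.json"
    rp.write_text(
        json.dumps(
            {
                "scheme": config.holdout.get("scheme", "random_fraction"),
                "fraction": float(config.holdout.get("fraction", 0.2)),
                "n_train": len(train),
                "n_test": len(test),
                "median_error_pp": report.median_error,
                "median_absolute_error_pp": report.median_absolute_error,
                "coverage_95_pct": report.coverage_95,
            },
            indent=2,
        ),
        encoding="utf-8",
    )
    resp = outdir / "validation_residuals.csv"
    report.residuals.to_csv(resp, index=False)
    return {
        "inputs": [str(p) for p in inputs],
        "outputs": [str(rp), str(resp)],
    }


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "crosswalk": _stage_crosswalk,
    "fit": _stage_fit,
    "derive": _stage_derive,
    "validate": _stage_validate,
}
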