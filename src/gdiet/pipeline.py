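"""Run orchestration: simulate -> standardize -> covariates -> fit -> series -> summarize.

A run is configured by one YAML file and one master seed; per-stage seeds are
derived deterministically, every intermediate table is written as CSV into the
run directory, and a manifest records the config hash and the hash of every
output so a rerun can be verified bit-for-bit. No output embeds a timestamp.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import numpy as np
import pandas as pd
import yaml

from . import covariates as cov_mod
from . import postprocess as post
from . import spacetime
from .grids import ANCHOR_YEARS, AgeGrid, StratumKey
from .mcmc import MCMCSettings
from .model import FitResult, fit_food
from .standardize import read_surveys, standardize_surveys
from .synthetic import DEFAULT_FOODS, SurveyPlan, WorldConfig, generate_world, write_world

logger = logging.getLogger(__name__)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(path: str) -> dict:
    with open(path) as f:
        cfg = yaml.safe_load(f) or {}
    cfg.setdefault("seed", 0)
    cfg.setdefault("outdir", "runs/demo")
    cfg.setdefault("foods", ["fruits"])
    cfg.setdefault("world", {})
    cfg.setdefault("mcmc", {})
    known = set(DEFAULT_FOODS) | {"legumes"}
    unknown = [f for f in cfg["foods"] if f not in known]
    if unknown:
        raise ValueError(f"unknown food name(s) {unknown}; known: {sorted(known)}")
    return cfg


def world_config_from(cfg: dict) -> WorldConfig:
    w = dict(cfg.get("world", {}))
    if "survey_plan" in w:
        w["survey_plan"] = SurveyPlan(**w["survey_plan"])
    if "age_edges" in w:
        w["age_grid"] = AgeGrid(tuple(w.pop("age_edges")))
    for tup in ("years", "fao_bias_range", "foods"):
        if tup in w:
            w[tup] = tuple(w[tup])
    w.setdefault("rng_seed", int(cfg["seed"]))
    fit_foods = [f for f in cfg["foods"] if f not in w.get("foods", DEFAULT_FOODS)]
    if fit_foods:
        w["foods"] = tuple(w.get("foods", DEFAULT_FOODS)) + tuple(fit_foods)
    return WorldConfig(**w)


def mcmc_settings_from(cfg: dict, stage_seed: int) -> MCMCSettings:
    m = dict(cfg.get("mcmc", {}))
    m.setdefault("rng_seed", stage_seed)
    return MCMCSettings(**m)


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 derived from the master seed."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def run_simulate(cfg: dict) -> dict[str, str]:
    outdir = cfg["outdir"]
    world = generate_world(world_config_from(cfg))
    return write_world(world, outdir)


def run_standardize(cfg: dict) -> str:
    outdir = cfg["outdir"]
    surveys = read_surveys(os.path.join(outdir, "surveys.csv"))
    std = standardize_surveys(surveys)
    path = os.path.join(outdir, "obs_std.csv")
    std.to_csv(path, index=False)
    return path


def run_covariates(cfg: dict) -> str:
    outdir = cfg["outdir"]
    fao = pd.read_csv(os.path.join(outdir, "fao.csv"))
    raw = pd.read_csv(os.path.join(outdir, "covariates.csv"))
    table, _model = cov_mod.build_covariates(fao, raw)
    path = os.path.join(outdir, "covariates_model.csv")
    table.to_csv(path, index=False)
    return path


def run_fit(cfg: dict, food: str) -> FitResult:
    outdir = cfg["outdir"]
    std = pd.read_csv(os.path.join(outdir, "obs_std.csv"))
    fao = pd.read_csv(os.path.join(outdir, "fao.csv"))
    covs = pd.read_csv(os.path.join(outdir, "covariates_model.csv"))
    pops = pd.read_csv(os.path.join(outdir, "populations.csv"))
    grid = world_config_from(cfg).age_grid
    settings = mcmc_settings_from(cfg, stage_seed(int(cfg["seed"]), f"fit:{food}"))
    result = fit_food(std, fao, covs, pops, grid, food, settings=settings)
    result.draws.to_frame().assign(food=food).to_csv(
        os.path.join(outdir, f"draws_{food}.csv"), index=False)
    return result


def run_series(cfg: dict, food: str, result: FitResult) -> str:
    outdir = cfg["outdir"]
    covs = pd.read_csv(os.path.join(outdir, "covariates_model.csv"))
    idx = result.draws.index()
    strata = sorted({k._replace(year=0) for k in result.draws.strata})
    by_year = {}
    for year in ANCHOR_YEARS:
        keys = [k._replace(year=year) for k in strata]
        mat = np.vstack([result.draws.draws[idx[k]] for k in keys])
        by_year[year] = post.PosteriorDraws(strata=keys, draws=mat)
    space = result.data.space
    s = space.slices()
    retained = result.chain.retained(result.settings)
    beta_mean = retained[:, s["beta"]].mean(axis=0)
    betas = {"ldi": float(beta_mean[space.cov_names.index("ldi")]),
             "education": float(beta_mean[space.cov_names.index("education")])}
    sds = {"ldi": float(result.data.cov_sds[space.cov_names.index("ldi")]),
           "education": float(result.data.cov_sds[space.cov_names.index("education")])}
    series = spacetime.interpolate_series(by_year[1990], by_year[2010],
                                          covariates=covs, betas=betas, cov_sds=sds)
    path = os.path.join(outdir, f"series_{food}.csv")
    spacetime.series_to_frame(series).assign(food=food).to_csv(path, index=False)
    return path


def run_summarize(cfg: dict, food: str, result: FitResult) -> str:
    outdir = cfg["outdir"]
    pops_df = pd.read_csv(os.path.join(outdir, "populations.csv"))
    pops = {StratumKey(r.country, int(r.year), int(r.age_band), r.sex): float(r.population)
            for r in pops_df.itertuples()}
    frames = [post.summarize_frame(result.draws).assign(level="stratum")]
    for year in ANCHOR_YEARS:
        idx = [i for i, k in enumerate(result.draws.strata) if k.year == year]
        sub = post.PosteriorDraws([result.draws.strata[i] for i in idx],
                                  result.draws.draws[idx])
        country = post.aggregate(sub, pops, "country")
        frames.append(post.summarize_frame(country).assign(level="country"))
        glob = post.aggregate(sub, pops, "global")
        frames.append(post.summarize_frame(glob).assign(level="global"))
    path = os.path.join(outdir, f"estimates_{food}.csv")
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def run_pipeline(config_path: str) -> str:
    """Execute every stage for every configured food; returns the run directory."""
    cfg = load_config(config_path)
    outdir = cfg["outdir"]
    os.makedirs(outdir, exist_ok=True)
    run_simulate(cfg)
    run_standardize(cfg)
    run_covariates(cfg)
    for food in cfg["foods"]:
        result = run_fit(cfg, food)
        run_series(cfg, food, result)
        run_summarize(cfg, food, result)
    manifest = {
        "config_sha256": _sha256(config_path),
        "seed": int(cfg["seed"]),
        "outputs": {name: _sha256(os.path.join(outdir, name))
                    for name in sorted(os.listdir(outdir))
                    if name.endswith(".csv")},
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as f:
        json.dump(manifest, f, indent=2, sort_keys=True)
    logger.info("pipeline complete: %s", outdir)
    return outdir
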